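"""Detector image -> q space: paint a synthetic exposure and reduce it.

Paints a detector TIFF with diffuse lobes, specular lamellar peaks,
background and Poisson noise for a known membrane stack, then runs the
reduction chain: pixel -> (θ, Ξ) -> (q_z, q_par), meridional
reflectivity profile, d-spacing estimate, and q_par line cuts.
"""

import numpy as np

from caillefit import (BeamModel, CailleParameters, DetectorGeometry,
                       FiniteSizeModel, FixtureSpec, IntensityMap,
                       build_unit_correlation_table, estimate_d_spacing,
                       extract_line_cuts, map_to_qspace, meridional_profile,
                       subtract_background, synthesize_detector_image)

params = CailleParameters(eta=0.1, xi=60.0, d=53.0)
size = FiniteSizeModel(Lr_mean=1200.0, Lr_sigma=400.0,
                       Lz_mean=530.0, Lz_sigma=106.0, d=53.0)
geometry = DetectorGeometry(distance_L=150.0, pixel_size=0.1,
                            beam_center=(95.0, 150.0), wavelength=1.5418)
spec = FixtureSpec(caille=params, size=size, geometry=geometry,
                   beam=BeamModel(sigma_q=0.002),
                   specular_orders={1: 2e5, 2: 6e4, 3: 2e4, 4: 8e3},
                   background=50.0, noise="poisson", seed=42)

print("painting the detector image ...")
unit = build_unit_correlation_table(np.geomspace(1e-5, 1e6, 3000),
                                    n_max=size.n_support)
image, truth = synthesize_detector_image(spec, unit_table=unit)
print(f"image: {image.shape[0]} x {image.shape[1]} pixels, "
      f"max {image.max():.0f} counts (true d = {truth['d']} A)")

qmap = map_to_qspace(IntensityMap(data=image.astype(float)), geometry)
profile = meridional_profile(qmap)
d_est = estimate_d_spacing(profile)
print(f"estimated repeat spacing d = {d_est:.2f} A "
      f"({100 * abs(d_est - 53) / 53:.2f}% from truth)")

q1 = 2 * np.pi / d_est
cuts = extract_line_cuts(qmap, [3 * q1, 3.5 * q1], box_pixels=3)
for cut in cuts:
    sub = subtract_background(cut)
    print(f"cut at q_z = {cut.qz_center:.4f} 1/A: "
          f"{len(cut.qpar)} points, baseline "
          f"{sub.meta['baseline']:.1f} counts subtracted")
print("The cuts are ready for the structure-factor fit "
      "(see 03_fit_line_cuts.py).")
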