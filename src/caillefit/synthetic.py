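"""Ground-truth synthetic data: line cuts and full detector images.

The generator drives the forward model (structure factor, beam smearing)
to produce line-cut datasets and paints complete detector TIFFs with
diffuse scattering, Gaussian specular peaks on the meridian, a flat
background and optional counting noise, so the reduction and fitting
modules can be exercised end to end against known truth.

The pixel -> q mapping used for painting is written out here from the
scattering geometry (meridional angle upward, azimuthal angle sideways,
q_z = 4π sin θ/λ, q_par = 4π sin(Ξ/2)/λ) and deliberately shares no code
with :mod:`caillefit.reduction`, so round-trip tests of the reduction
geometry are genuine.

The form factor |F(q_z)|² is not modeled physically — the analysis
absorbs it into per-cut scales — so any smooth positive envelope is
admissible; a constant and a damped cosine are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.interpolate import CubicSpline

from .model import (BeamModel, CailleParameters, CorrelationTable,
                    FiniteSizeModel, RadialIntegrationConfig,
                    build_unit_correlation_table, convolve_beam,
                    rescale_correlation, structure_factor_profile)
from .reduction import DetectorGeometry

__all__ = ["FixtureSpec", "make_line_cut_dataset", "synthesize_detector_image",
           "write_truth_record"]


@dataclass
class FixtureSpec:
    """Everything needed to generate a synthetic dataset with known truth.

    ``specular_orders`` maps the lamellar order n to a peak amplitude
    (counts); ``specular_sigma_qz``/``_qpar`` are the painted Gaussian
    widths in Å⁻¹.  ``envelope`` is "constant" or "damped_cosine" (period
    ``envelope_period`` Å⁻¹ in q_z), standing in for |F(q_z)|².
    ``diffuse_counts`` sets the peak diffuse intensity of the first
    requested cut.  ``noise`` is "none", "poisson" or "gaussian"
    (relative width ``noise_frac``).  The seed fixes all stochastic
    output bitwise.
    """

    caille: CailleParameters
    size: FiniteSizeModel
    geometry: DetectorGeometry
    beam: BeamModel = field(default_factory=BeamModel)
    temperature: float = 298.0
    specular_orders: dict = field(default_factory=dict)
    specular_sigma_qz: float = 0.004
    specular_sigma_qpar: float = 0.004
    envelope: str = "constant"
    envelope_period: float = 0.5
    background: float = 0.0
    diffuse_counts: float = 5000.0
    noise: str = "none"
    noise_frac: float = 0.01
    seed: int = 0

    def envelope_at(self, qz) -> np.ndarray:
        qz = np.asarray(qz, dtype=float)
        if self.envelope == "constant":
            return np.ones_like(qz)
        if self.envelope == "damped_cosine":
            return (0.55 + 0.45 * np.cos(2.0 * math.pi * qz
                                         / self.envelope_period)) \
                * np.exp(-qz / (4.0 * self.caille.q1))
        raise ValueError(f"unknown envelope {self.envelope!r}")


def _apply_noise(rng: np.random.Generator, spec: FixtureSpec,
                 expected: np.ndarray):
    """Noisy realization plus the uncertainty attached to it."""
    if spec.noise == "none":
        return expected.copy(), np.sqrt(np.maximum(expected, 1.0))
    if spec.noise == "poisson":
        return (rng.poisson(np.maximum(expected, 0.0)).astype(float),
                np.sqrt(np.maximum(expected, 1.0)))
    if spec.noise == "gaussian":
        # relative noise with a one-count floor: a literal relative sigma
        # at zero-intensity points would assign them absurd weights
        sigma = spec.noise_frac * np.maximum(expected, 1.0)
        return expected + rng.normal(0.0, 1.0, expected.shape) * sigma, sigma
    raise ValueError(f"unknown noise model {spec.noise!r}")


def make_line_cut_dataset(spec: FixtureSpec, qz_list, qpar_axis,
                          unit_table: CorrelationTable | None = None,
                          integration: RadialIntegrationConfig | None = None):
    """Forward-model line cuts at the requested q_z values.

    Returns ``(cuts, truth)`` where each cut is a dict with keys
    ``qz``, ``qpar``, ``intensity``, ``sigma``, ``expected`` and the
    truth record stores every generating parameter.
    """
    from .reduction import LineCut

    rng = np.random.default_rng(spec.seed)
    if unit_table is None:
        unit_table = build_unit_correlation_table(
            np.geomspace(1e-5, 1e6, 4000),
            n_max=max(spec.size.n_support, 2))
    corr = rescale_correlation(unit_table, spec.caille)
    qpar_axis = np.asarray(qpar_axis, dtype=float)
    qz_list = list(np.atleast_1d(qz_list))

    dq = float(np.min(np.abs(np.diff(np.sort(qpar_axis))))) if len(qpar_axis) > 1 else 1e-3
    if spec.beam.sigma_q > 0:
        dq = min(dq, spec.beam.sigma_q / 2.0)
    qmax = float(np.max(np.abs(qpar_axis))) + 6.0 * spec.beam.sigma_q
    half = np.arange(0.0, qmax + 2 * dq, dq)

    raw = []
    for qz in qz_list:
        prof = structure_factor_profile(qz, half, spec.caille, spec.size,
                                        corr, config=integration)
        full = np.concatenate([prof[:0:-1], prof])
        if spec.beam.sigma_q > 0:
            full = convolve_beam(full, spec.beam, dq)
        grid = np.concatenate([-half[:0:-1], half])
        raw.append(CubicSpline(grid, full)(qpar_axis))

    env = spec.envelope_at(np.asarray(qz_list))
    norm = spec.diffuse_counts / max(float(np.max(raw[0])) * env[0], 1e-300)
    cuts = []
    for qz, prof, e in zip(qz_list, raw, env):
        expected = norm * e * np.clip(prof, 0.0, None) + spec.background
        inten, sigma = _apply_noise(rng, spec, expected)
        cuts.append(LineCut(qz_center=float(qz), qpar=qpar_axis.copy(),
                            intensity=inten, sigma=sigma,
                            meta={"expected": expected}))
    truth = _truth_dict(spec)
    truth.update(qz_list=",".join(f"{q:.8g}" for q in qz_list),
                 normalization=norm)
    return cuts, truth


def synthesize_detector_image(spec: FixtureSpec, path=None,
                              unit_table: CorrelationTable | None = None,
                              integration: RadialIntegrationConfig | None = None):
    """Paint a full detector image and optionally write it as a TIFF.

    Per detector row the diffuse structure factor is evaluated on a
    uniform symmetric q_par grid, beam-convolved and interpolated onto
    the pixels' q_par values; specular Gaussians at q_z = n·q1 on the
    meridian, the flat background and noise are added on top.

    Returns ``(image, truth)``; ``image`` is float32 counts.
    """
    g = spec.geometry
    rng = np.random.default_rng(spec.seed)
    if unit_table is None:
        unit_table = build_unit_correlation_table(
            np.geomspace(1e-5, 1e6, 4000),
            n_max=max(spec.size.n_support, 2))
    corr = rescale_correlation(unit_table, spec.caille)

    # independent pixel -> q mapping (see module docstring)
    nrow, ncol = _detector_shape(g)
    rows = np.arange(nrow, dtype=float)
    cols = np.arange(ncol, dtype=float)
    sv = g.pixel_size * (g.beam_center[0] - rows) / g.distance_L
    sh = g.pixel_size * (cols - g.beam_center[1]) / g.distance_L
    theta = np.arctan(sv) if g.distort_qz else sv
    xi_ang = np.arctan(sh) if g.distort_qpar else sh
    qz_rows = 4.0 * math.pi * np.sin(theta) / g.wavelength
    qpar_cols = 4.0 * math.pi * np.sin(xi_ang / 2.0) / g.wavelength

    qmax = float(np.max(np.abs(qpar_cols)))
    dq = max(float(np.min(np.abs(np.diff(qpar_cols)))), 1e-6)
    if spec.beam.sigma_q > 0:
        dq = min(dq, spec.beam.sigma_q / 2.0)
    half = np.arange(0.0, qmax + 6.0 * spec.beam.sigma_q + 2 * dq, dq)
    grid = np.concatenate([-half[:0:-1], half])

    q1 = spec.caille.q1
    env = spec.envelope_at(qz_rows)
    image = np.empty((nrow, ncol))
    ref_row = int(np.argmin(np.abs(qz_rows - 3.0 * q1)))
    norm = None
    order = list(range(nrow))
    # evaluate the normalization row first so scaling is well defined
    order.remove(ref_row)
    order.insert(0, ref_row)
    for i in order:
        qz = float(qz_rows[i])
        if abs(qz) < 0.35 * q1:     # shadow of the beam stop region
            image[i] = 0.0
            continue
        prof = structure_factor_profile(qz, half, spec.caille, spec.size,
                                        corr, config=integration)
        full = np.concatenate([prof[:0:-1], prof])
        if spec.beam.sigma_q > 0:
            full = convolve_beam(full, spec.beam, dq)
        row = CubicSpline(grid, full)(qpar_cols)
        if norm is None:
            norm = spec.diffuse_counts / max(float(np.max(full))
                                             * float(env[i]), 1e-300)
        image[i] = norm * env[i] * np.clip(row, 0.0, None)

    for n_ord, amp in spec.specular_orders.items():
        dqz = (qz_rows - n_ord * q1) / spec.specular_sigma_qz
        dqp = qpar_cols / spec.specular_sigma_qpar
        image += amp * np.outer(np.exp(-0.5 * dqz ** 2),
                                np.exp(-0.5 * dqp ** 2))
    image += spec.background

    if spec.noise == "poisson":
        image = rng.poisson(np.maximum(image, 0.0)).astype(float)
    elif spec.noise == "gaussian":
        image = image + rng.normal(0.0, 1.0, image.shape) \
            * spec.noise_frac * np.maximum(image, 1e-12)
    image = image.astype(np.float32)

    truth = _truth_dict(spec)
    truth.update(normalization=norm, detector_rows=nrow, detector_cols=ncol)
    if path is not None:
        tifffile.imwrite(path, image)
        truth["tiff_path"] = str(path)
    return image, truth


def _detector_shape(g: DetectorGeometry) -> tuple[int, int]:
    """Detector extent implied by the beam center: the center must lie on
    the detector; the shape is chosen to put it at the stored pixel with
    the same margins on all sides it was given (rows: center + 10 below,
    cols: symmetric)."""
    r0, c0 = g.beam_center
    return int(round(r0)) + 11, 2 * int(round(c0)) + 1


def _truth_dict(spec: FixtureSpec) -> dict:
    p, m, g = spec.caille, spec.size, spec.geometry
    return dict(
        eta=p.eta, xi=p.xi, d=p.d, q1=p.q1,
        Lr_mean=m.Lr_mean, Lr_sigma=m.Lr_sigma,
        Lz_mean=m.Lz_mean, Lz_sigma=m.Lz_sigma,
        beam_sigma_q=spec.beam.sigma_q, temperature=spec.temperature,
        distance_L=g.distance_L, pixel_size=g.pixel_size,
        beam_center_row=g.beam_center[0], beam_center_col=g.beam_center[1],
        wavelength=g.wavelength, distort_qz=g.distort_qz,
        distort_qpar=g.distort_qpar, envelope=spec.envelope,
        background=spec.background, noise=spec.noise,
        noise_frac=spec.noise_frac, seed=spec.seed,
        diffuse_counts=spec.diffuse_counts,
    )


def write_truth_record(truth: dict, path) -> None:
    """Write the truth record as a flat key=value text file."""
    with open(path, "w") as fh:
        for key, val in truth.items():
            fh.write(f"{key} = {val}\n")
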