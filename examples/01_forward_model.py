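"""Forward model: diffuse-scattering profiles of a fluctuating stack.

Computes the smectic structure factor S(q_z, q_par) for a POPC-like
membrane stack (η = 0.1, ξ = 60 Å, d = 53 Å) at two q_z positions and
converts the Caillé parameters to the elastic moduli.  The q_par decay
of the diffuse intensity is what encodes the bending modulus.
"""

import numpy as np

from caillefit import (BeamModel, CailleParameters, FiniteSizeModel,
                       build_unit_correlation_table, convolve_beam,
                       moduli_from_caille, rescale_correlation,
                       structure_factor_profile)

params = CailleParameters(eta=0.1, xi=60.0, d=53.0)
size = FiniteSizeModel(Lr_mean=1200.0, Lr_sigma=400.0,
                       Lz_mean=10 * 53.0, Lz_sigma=2 * 53.0, d=53.0)
beam = BeamModel(sigma_q=0.002)

print("building the unit-scale correlation table ...")
unit = build_unit_correlation_table(np.geomspace(1e-5, 1e6, 3000),
                                    n_max=size.n_support)
corr = rescale_correlation(unit, params)

qpar = np.linspace(0.0, 0.25, 26)
for mult in (3.0, 3.5):
    qz = mult * params.q1
    S = structure_factor_profile(qz, qpar, params, size, corr)
    S = convolve_beam(S, beam, float(qpar[1] - qpar[0]))
    S /= S.max()
    print(f"\nq_z = {mult} q1 = {qz:.4f} 1/A  (normalized intensity)")
    for j in (0, 5, 10, 20):
        print(f"  q_par = {qpar[j]:.3f} 1/A   S = {S[j]:.4f}")

mod = moduli_from_caille(params, T=298.0)
print(f"\nCaillé parameters eta = {params.eta}, xi = {params.xi} A "
      f"correspond to:")
print(f"  bending modulus   kappa = {mod.kappa:.4g} J "
      f"= {mod.kappa_kBT:.2f} kBT")
print(f"  compression modulus   B = {mod.B:.4g} J/A^4 "
      f"= {mod.B_erg_cm4:.3g} erg/cm^4")
print("\nThe faster the q_par decay at fixed q_z, the stiffer the "
      "membrane (larger kappa).")
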