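"""Slow reference evaluation of the structure factor.

Computes S(q_z, q_par) by direct quadrature of the correlation function at
every node of a dense radial grid — no precomputed unit table, no
rescaling shortcut, no interpolation of Λ.  It exists to validate the fast
table-based pipeline and is orders of magnitude slower.
"""

from __future__ import annotations

import numpy as np
from scipy.special import j0

from ._quad import core_integrals
from .model import (CailleParameters, FiniteSizeModel, size_weight_axial,
                    size_weight_radial)

__all__ = ["structure_factor_reference"]


def structure_factor_reference(qz_values, qpar_axis, p: CailleParameters,
                               m: FiniteSizeModel, step: float = 1.0,
                               n_range: int = 1000) -> np.ndarray:
    """S on a (q_z × q_par) grid by dense direct quadrature.

    δu_n(r) is evaluated by quadrature at the target (ξ, η) for every
    radius of the uniform integration grid (1 Å steps by default up to
    the H_r support); Λ and the Hankel-type transform are then formed
    directly.  Returns an array of shape (len(qz_values), len(qpar_axis)).
    """
    qz_values = np.atleast_1d(np.asarray(qz_values, dtype=float))
    qpar = np.asarray(qpar_axis, dtype=float)
    r_int = np.arange(step, m.r_support + 0.5 * step, step)

    n_cut = min(m.n_support, n_range - 1)
    pref = 2.0 * p.eta / p.q1 ** 2
    du = np.empty((n_cut + 1, len(r_int)))
    for i, r in enumerate(r_int):
        du[:, i] = pref * core_integrals(r / p.xi, n_cut)

    Hz = np.array([size_weight_axial(n, m) for n in range(n_cut + 1)])
    Hr = size_weight_radial(r_int, m)

    out = np.empty((len(qz_values), len(qpar)))
    for k, qz in enumerate(qz_values):
        with np.errstate(under="ignore"):
            G = np.exp(-0.5 * qz * qz * du)
        n = np.arange(1, n_cut + 1)
        lam = Hz[0] * G[0] + (2.0 * Hz[1:] * np.cos(qz * n * m.d)) @ G[1:]
        core = r_int * Hr * lam
        for jq, q in enumerate(np.abs(qpar)):
            out[k, jq] = np.trapezoid(j0(q * r_int) * core, dx=step)
    return np.clip(out, 0.0, None)
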