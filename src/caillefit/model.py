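"""Caillé structure factor of a finite stack of fluctuating bilayers.

This module implements the forward model for X-ray diffuse scattering from
oriented multilamellar membrane stacks: the height–height correlation
function :math:`\\delta u_n(r)` of Caillé/discrete-smectic theory, Gaussian
finite-size weights for the coherently scattering domains, the structure
factor

.. math::

    S(q_z, q_\\parallel) = \\int_0^\\infty r\\,dr\\, H_r(r)\\,
        J_0(q_\\parallel r)\\, \\Lambda(r),

    \\Lambda(r) = \\sum_n H_z(|n|d)\\cos(q_z n d)\\,
        e^{-q_z^2 \\delta u_{|n|}(r)/2},

Gaussian beam smearing, and the conversion between the Caillé parameters
(η, ξ) and the elastic moduli (κ, B)

.. math::

    \\eta = \\frac{k_B T q_1^2}{8\\pi\\sqrt{B\\kappa}}, \\qquad
    \\xi^4 = \\kappa/B.

Lengths are in Å, scattering vectors in Å⁻¹, κ in J, B in J/Å⁴.

The correlation exponent is the cumulant (Gaussian) form
``exp(-q_z² δu/2)``: the literature sometimes prints ``exp(i q_z δu)``,
which is dimensionally inconsistent for a mean-square displacement and
would make S complex; the cumulant form is the standard result for
Gaussian-distributed height differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import exp1, j0, ndtr

from ._quad import QuadratureError, core_integral_adaptive, core_integrals

__all__ = [
    "KB", "EULER_GAMMA",
    "CailleParameters", "ElasticModuli", "FiniteSizeModel", "CorrelationTable",
    "SizeWeightTables", "BeamModel", "StructureFactorMap", "RadialIntegrationConfig",
    "QuadratureError",
    "delta_u_exact", "delta_u_asymptotic", "build_unit_correlation_table",
    "rescale_correlation", "size_weight_axial", "size_weight_radial",
    "lambda_kernel", "structure_factor_profile", "convolve_beam",
    "structure_factor_map", "moduli_from_caille", "caille_from_moduli",
]

logger = logging.getLogger(__name__)

KB = 1.380649e-23  # Boltzmann constant, J/K
EULER_GAMMA = 0.5772156649015329

#: the exact-quadrature branch of the correlation function is used below
#: these unit-scale thresholds; the asymptotic expansion elsewhere.
EXACT_N_MAX = 30
EXACT_R_MAX = 1000.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CailleParameters:
    """Fluctuation parameters of the smectic stack.

    Parameters
    ----------
    eta
        Dimensionless Caillé parameter (fluctuation amplitude), >= 0.
    xi
        In-plane correlation length (κ/B)^(1/4) in Å, > 0.
    d
        Lamellar repeat spacing in Å. Exactly one of ``d``/``q1`` is
        required; the other is derived (q1 = 2π/d).
    q1
        First-order lamellar peak position in Å⁻¹.
    """

    eta: float
    xi: float
    d: float = None          # type: ignore[assignment]
    q1: float = None         # type: ignore[assignment]

    def __post_init__(self):
        if self.d is None and self.q1 is None:
            raise ValueError("provide d or q1")
        if self.d is None:
            object.__setattr__(self, "d", 2.0 * math.pi / self.q1)
        if self.q1 is None:
            object.__setattr__(self, "q1", 2.0 * math.pi / self.d)
        if abs(self.q1 * self.d - 2.0 * math.pi) > 1e-9 * 2.0 * math.pi:
            raise ValueError("q1 * d must equal 2*pi")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.xi <= 0:
            raise ValueError("xi must be > 0")


@dataclass(frozen=True)
class ElasticModuli:
    """Bending modulus κ (J), inter-membrane compression modulus B (J/Å⁴)
    and the temperature T (K) at which they were obtained."""

    kappa: float
    B: float
    T: float

    def __post_init__(self):
        if self.kappa <= 0 or self.B <= 0 or self.T <= 0:
            raise ValueError("kappa, B and T must be > 0")

    @property
    def kappa_kBT(self) -> float:
        """κ in units of k_B T."""
        return self.kappa / (KB * self.T)

    @property
    def B_erg_cm4(self) -> float:
        """B in the conventional erg/cm⁴ units (1 J/Å⁴ = 1e39 erg/cm⁴)."""
        return self.B * 1e39


@dataclass(frozen=True)
class FiniteSizeModel:
    """Gaussian-distributed coherent-domain dimensions.

    ``Lr_mean``/``Lr_sigma`` are mean and spread of the in-plane domain
    diameter, ``Lz_mean``/``Lz_sigma`` of the stack height (all Å);
    ``d`` is the repeat spacing.
    """

    Lr_mean: float
    Lr_sigma: float
    Lz_mean: float
    Lz_sigma: float
    d: float

    def __post_init__(self):
        for name in ("Lr_mean", "Lr_sigma", "Lz_mean", "Lz_sigma", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.Lz_mean / self.d < 1:
            raise ValueError("Lz_mean must span at least one bilayer")

    @property
    def r_support(self) -> float:
        """Radius beyond which H_r is treated as exactly zero."""
        return self.Lr_mean + 6.0 * self.Lr_sigma

    @property
    def n_support(self) -> int:
        """Largest layer separation with non-negligible H_z."""
        return int(math.ceil((self.Lz_mean + 6.0 * self.Lz_sigma) / self.d))


@dataclass
class CorrelationTable:
    """δu_n(r) tabulated on a log-spaced radius grid for n = 0..n_max.

    ``scale_state`` is ``"unit"`` for the reference table computed at
    (ξ, η) = (1, 1) or the ``(xi, eta)`` tuple that has been applied.
    ``q1`` records the peak position baked into the 2η/q1² prefactor
    (1 Å⁻¹ for the unit table).
    """

    r_grid: np.ndarray
    values: np.ndarray          # shape (n_max + 1, len(r_grid)), Å²
    scale_state: object = "unit"
    q1: float = 1.0

    @property
    def n_max(self) -> int:
        return self.values.shape[0] - 1

    @property
    def is_unit(self) -> bool:
        return self.scale_state == "unit"

    def interpolate(self, n: int, r) -> np.ndarray:
        """δu_n at arbitrary radii, cubic in log r. Raises outside the grid."""
        r = np.asarray(r, dtype=float)
        if np.any(r < self.r_grid[0]) or np.any(r > self.r_grid[-1]):
            raise ValueError("radius outside the tabulated grid; "
                             "extrapolation is not supported")
        spline = CubicSpline(np.log(self.r_grid), self.values[n])
        return spline(np.log(r))


@dataclass(frozen=True)
class SizeWeightTables:
    """Precomputed finite-size weights: H_r on a radius grid (Å²) and
    H_z for layer separations 0..n_max (dimensionless)."""

    r_grid: np.ndarray
    Hr: np.ndarray
    Hz: np.ndarray

    @classmethod
    def build(cls, m: FiniteSizeModel, r_grid: np.ndarray,
              n_max: int | None = None) -> "SizeWeightTables":
        if n_max is None:
            n_max = m.n_support
        Hr = size_weight_radial(r_grid, m)
        Hz = np.array([size_weight_axial(n, m) for n in range(n_max + 1)])
        return cls(r_grid=np.asarray(r_grid, float), Hr=Hr, Hz=Hz)


@dataclass(frozen=True)
class BeamModel:
    """Gaussian beam profile of standard deviation ``sigma_q`` in Å⁻¹."""

    sigma_q: float = 0.0

    def __post_init__(self):
        if self.sigma_q < 0:
            raise ValueError("sigma_q must be >= 0")


@dataclass
class StructureFactorMap:
    """S(q_z, q_par) sampled on a rectangular grid (rows: q_z)."""

    qz_axis: np.ndarray
    qpar_axis: np.ndarray
    S: np.ndarray


@dataclass(frozen=True)
class RadialIntegrationConfig:
    """Trapezoidal radial integration for the Hankel-type transform.

    The grid runs from ``r_min`` to the smaller of ``r_max`` and the
    support of H_r, in steps of ``step`` (Å). The defaults reproduce a
    1 Å-step grid truncated where the size distribution vanishes, which
    is numerically identical to integrating to 10⁶ Å.
    """

    r_min: float = 1.0
    r_max: float = 1e6
    step: float = 1.0


# ---------------------------------------------------------------------------
# height-height correlation function
# ---------------------------------------------------------------------------

def delta_u_exact(n: int, r: float, p: CailleParameters) -> float:
    """Mean-square height difference δu_n(r) in Å² by adaptive quadrature.

    Evaluates (2η/q1²)∫₀^∞ dx [1 − J₀((r/ξ)√(2x))(√(1+x²)−x)^{2n}]
    /(x√(1+x²)).  Intended for the exact-branch regime (unit-scale
    radius below ~1000 Å or n below ~30); raises
    :class:`QuadratureError` if the internal refinement check fails.
    """
    if n < 0 or int(n) != n:
        raise ValueError("n must be a nonnegative integer")
    if r < 0:
        raise ValueError("r must be >= 0")
    core = core_integral_adaptive(r / p.xi, int(n))
    return 2.0 * p.eta / p.q1 ** 2 * core


def delta_u_asymptotic(n: int, r: float, p: CailleParameters) -> float:
    """Large-(n, r) expansion of δu_n(r) in Å².

    (4η/q1²)[γ + ln(r/ξ) + E₁(r²/(4nξ²))/2] with γ the Euler–Mascheroni
    constant; the additive γ reading is fixed by continuity against the
    exact quadrature (see docs).  n = 0 is outside the domain (the E₁
    argument diverges); route it to :func:`delta_u_exact`.
    """
    if n <= 0:
        raise ValueError("asymptotic branch requires n >= 1; "
                         "use delta_u_exact for n = 0")
    if r <= 0:
        raise ValueError("asymptotic branch requires r > 0")
    rbar = r / p.xi
    arg = rbar * rbar / (4.0 * n)
    return 4.0 * p.eta / p.q1 ** 2 * (
        EULER_GAMMA + math.log(rbar) + 0.5 * exp1(arg))


def build_unit_correlation_table(r_grid: np.ndarray | None = None,
                                 n_max: int = 1000) -> CorrelationTable:
    """Reference δu table at (ξ, η) = (1, 1), q1 = 1 Å⁻¹.

    The exact quadrature is used for n < 30 and r < 1000 Å and the
    asymptotic expansion elsewhere; the n = 0 row beyond 1000 Å is the
    exact value at the last node inside the branch continued with the
    analytic logarithmic slope δu₀(r) = δu₀(r_a) + 4 ln(r/r_a).

    The default grid is 10,000 log-spaced radii from 1e-4 to 1e6 Å and
    n = 0..1000.
    """
    if r_grid is None:
        r_grid = np.geomspace(1e-4, 1e6, 10000)
    r_grid = np.asarray(r_grid, dtype=float)
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if len(r_grid) > 1 and not np.all(np.diff(r_grid) > 0):
        raise ValueError("r_grid must be strictly increasing")

    values = np.empty((n_max + 1, len(r_grid)))
    exact_cols = r_grid < EXACT_R_MAX
    n_exact = min(EXACT_N_MAX - 1, n_max)

    for i in np.nonzero(exact_cols)[0]:
        values[:n_exact + 1, i] = 2.0 * core_integrals(r_grid[i], n_exact)

    # asymptotic rows (n >= 30) everywhere, and n = 1..29 at large r
    far_cols = ~exact_cols
    if n_max >= EXACT_N_MAX or np.any(far_cols):
        ns = np.arange(1, n_max + 1)[:, None]
        logr = np.log(r_grid)[None, :]
        with np.errstate(over="ignore", under="ignore"):
            e1 = exp1(r_grid[None, :] ** 2 / (4.0 * ns))
        asym = 4.0 * (EULER_GAMMA + logr + 0.5 * e1)
        if n_max >= EXACT_N_MAX:
            values[EXACT_N_MAX:, :] = asym[EXACT_N_MAX - 1:, :]
        if np.any(far_cols):
            values[1:n_exact + 1, far_cols] = asym[:n_exact, far_cols]

    # n = 0 continuation beyond the exact branch
    if np.any(far_cols):
        if not np.any(exact_cols):
            raise ValueError("r_grid must contain nodes below 1000 Å "
                             "to anchor the n = 0 row")
        ia = np.nonzero(exact_cols)[0][-1]
        values[0, far_cols] = (values[0, ia]
                               + 4.0 * np.log(r_grid[far_cols] / r_grid[ia]))

    return CorrelationTable(r_grid=r_grid, values=values,
                            scale_state="unit", q1=1.0)


def rescale_correlation(table: CorrelationTable,
                        p: CailleParameters) -> CorrelationTable:
    """Apply (ξ, η, q1) to a unit table: relabel radii by ξ and scale the
    values by η (q1²)⁻¹ relative to the reference. No re-quadrature."""
    if not table.is_unit:
        raise ValueError("table has already been rescaled; start from the "
                         "unit table")
    factor = p.eta * (table.q1 / p.q1) ** 2
    return CorrelationTable(
        r_grid=table.r_grid * p.xi,
        values=table.values * factor,
        scale_state=(p.xi, p.eta),
        q1=p.q1,
    )


# ---------------------------------------------------------------------------
# finite-size weights
# ---------------------------------------------------------------------------

def size_weight_axial(n: int, m: FiniteSizeModel) -> float:
    """Axial finite-size weight H_z(|n| d), dimensionless.

    Closed form of ∫_z^∞ dL N(L; L̄_z, σ_z)(L − z)/d with a normalized
    Gaussian: [(L̄ − z) Φ̄((z − L̄)/σ) + σ φ((z − L̄)/σ)]/d.
    """
    z = abs(int(n)) * m.d
    if m.Lz_sigma == 0:
        return max(m.Lz_mean - z, 0.0) / m.d
    t = (z - m.Lz_mean) / m.Lz_sigma
    surv = ndtr(-t)
    pdf = math.exp(-0.5 * t * t) / math.sqrt(2.0 * math.pi)
    return ((m.Lz_mean - z) * surv + m.Lz_sigma * pdf) / m.d


_GL64_X, _GL64_W = np.polynomial.legendre.leggauss(64)


def size_weight_radial(r, m: FiniteSizeModel) -> np.ndarray | float:
    """Radial finite-size weight H_r(r) in Å² (carries the L_r² factor).

    ∫_r^∞ dL N(L; L̄_r, σ_r) L² [arccos(r/L) − (r/L)√(1 − (r/L)²)] for
    r ≤ L, zero otherwise; Gauss–Legendre quadrature over the Gaussian
    support, hard-zeroed beyond L̄_r + 6σ_r.
    """
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_arr < 0):
        raise ValueError("r must be >= 0")
    out = np.zeros_like(r_arr)
    hi = m.Lr_mean + 8.0 * m.Lr_sigma
    live = r_arr < m.r_support
    if np.any(live):
        rl = r_arr[live]
        lo = np.maximum(rl, max(m.Lr_mean - 8.0 * m.Lr_sigma, 0.0))
        mid = 0.5 * (hi + lo)
        half = 0.5 * (hi - lo)
        L = mid[:, None] + np.outer(half, _GL64_X)       # (n_live, 64)
        wt = np.outer(half, _GL64_W)
        t = (L - m.Lr_mean) / m.Lr_sigma
        gauss = np.exp(-0.5 * t * t) / (m.Lr_sigma * math.sqrt(2.0 * math.pi))
        frac = np.clip(rl[:, None] / L, 0.0, 1.0)
        shape = np.arccos(frac) - frac * np.sqrt(np.clip(1.0 - frac * frac,
                                                         0.0, None))
        out[live] = np.einsum("ij,ij->i", wt, gauss * L * L * shape)
    return out if np.ndim(r) else float(out[0])


# ---------------------------------------------------------------------------
# structure factor
# ---------------------------------------------------------------------------

def _require_scaled(corr: CorrelationTable):
    if corr.is_unit:
        raise ValueError("correlation table is in the unit state; apply "
                         "rescale_correlation first")


def _lambda_columns(qz: float, values: np.ndarray, d: float,
                    Hz: np.ndarray) -> np.ndarray:
    """Λ at every tabulated radius column from δu columns ``values``
    (shape (n_used + 1, n_cols)); exploits evenness in n."""
    n_used = values.shape[0] - 1
    with np.errstate(under="ignore"):
        G = np.exp(-0.5 * qz * qz * values)
    lam = Hz[0] * G[0]
    if n_used >= 1:
        n = np.arange(1, n_used + 1)
        coef = 2.0 * Hz[1:n_used + 1] * np.cos(qz * n * d)
        lam = lam + coef @ G[1:]
    return lam


def lambda_kernel(r: float, qz: float, corr: CorrelationTable,
                  m: FiniteSizeModel,
                  n_range: int | None = None) -> float:
    """Λ(r) = Σ_n H_z(|n|d) cos(q_z n d) exp(−q_z² δu_|n|(r)/2).

    ``n_range`` bounds |n| (default: the conventional −1000 < n < 1000,
    further truncated to the table and to the support of H_z).
    """
    _require_scaled(corr)
    n_cut = min(corr.n_max, m.n_support, (n_range or 1000) - 1)
    du = np.array([corr.interpolate(n, r) for n in range(n_cut + 1)])
    Hz = np.array([size_weight_axial(n, m) for n in range(n_cut + 1)])
    return float(_lambda_columns(qz, du[:, None], m.d, Hz)[0])


def structure_factor_profile(qz: float, qpar_axis: Sequence[float],
                             p: CailleParameters, m: FiniteSizeModel,
                             corr: CorrelationTable,
                             config: RadialIntegrationConfig | None = None,
                             weights: SizeWeightTables | None = None,
                             n_range: int | None = None) -> np.ndarray:
    """One q_par profile of S(q_z, q_par) by trapezoidal Hankel transform.

    Λ is evaluated at the tabulated radii and cubic-interpolated (in
    log r) onto the uniform integration grid. Tiny negative results from
    integration noise are clipped to zero with a log message.
    """
    _require_scaled(corr)
    if corr.scale_state != (p.xi, p.eta):
        raise ValueError("correlation table was rescaled with different "
                         "(xi, eta) than the supplied parameters")
    cfg = config or RadialIntegrationConfig()
    qpar = np.asarray(qpar_axis, dtype=float)
    if not np.all(np.isfinite(qpar)):
        raise ValueError("qpar_axis must be finite")

    r_lo = max(cfg.r_min, corr.r_grid[0])
    r_hi = min(cfg.r_max, m.r_support, corr.r_grid[-1])
    if r_hi <= r_lo:
        raise ValueError("empty radial integration range")
    r_int = np.arange(r_lo, r_hi + 0.5 * cfg.step, cfg.step)

    n_cut = min(corr.n_max, m.n_support, (n_range or 1000) - 1)
    cols = (corr.r_grid >= r_lo / 1.0000001) & (corr.r_grid <= r_hi * 1.0000001)
    # widen by one node on each side for the spline
    idx = np.nonzero(cols)[0]
    lo_i, hi_i = max(idx[0] - 1, 0), min(idx[-1] + 1, len(corr.r_grid) - 1)
    node_r = corr.r_grid[lo_i:hi_i + 1]
    Hz = np.array([size_weight_axial(n, m) for n in range(n_cut + 1)])
    lam_nodes = _lambda_columns(qz, corr.values[:n_cut + 1, lo_i:hi_i + 1],
                                m.d, Hz)
    lam = CubicSpline(np.log(node_r), lam_nodes)(np.log(r_int))
    if not np.all(np.isfinite(lam)):
        raise ValueError("NaN in the Lambda kernel")

    if weights is not None and (len(weights.r_grid) == len(r_int)
                                and np.array_equal(weights.r_grid, r_int)):
        Hr = weights.Hr
    else:
        Hr = size_weight_radial(r_int, m)
    core = r_int * Hr * lam

    S = np.empty_like(qpar)
    block = 256
    for i in range(0, len(qpar), block):
        qb = np.abs(qpar[i:i + block])
        S[i:i + block] = np.trapezoid(j0(np.outer(qb, r_int)) * core,
                                      dx=cfg.step, axis=1)
    neg = S < 0
    if np.any(neg):
        worst = float(S.min())
        level = (logging.WARNING
                 if abs(worst) > 1e-3 * max(float(S.max()), 1e-300)
                 else logging.DEBUG)
        logger.log(level, "clipped %d negative structure-factor values "
                   "(most negative %.3e)", int(neg.sum()), worst)
        S[neg] = 0.0
    return S


def convolve_beam(profile: Sequence[float], beam: BeamModel,
                  dq: float) -> np.ndarray:
    """Smear a profile on a uniform q grid (spacing ``dq``) with a
    unit-area Gaussian of width σ_q, truncated at ±5σ_q; the kernel is
    renormalized over the in-range support at the edges."""
    y = np.asarray(profile, dtype=float)
    if beam.sigma_q < 0:
        raise ValueError("sigma_q must be >= 0")
    if dq <= 0:
        raise ValueError("dq must be > 0")
    if beam.sigma_q == 0.0:
        return y.copy()
    k = int(math.ceil(5.0 * beam.sigma_q / dq))
    if k == 0:
        return y.copy()
    offs = np.arange(-k, k + 1) * dq
    kern = np.exp(-0.5 * (offs / beam.sigma_q) ** 2)
    kern /= kern.sum()
    num = np.convolve(y, kern, mode="same")
    den = np.convolve(np.ones_like(y), kern, mode="same")
    return num / den


def structure_factor_map(qz_axis: Sequence[float], qpar_axis: Sequence[float],
                         p: CailleParameters, m: FiniteSizeModel,
                         beam: BeamModel | None = None,
                         corr: CorrelationTable | None = None,
                         unit_table: CorrelationTable | None = None,
                         config: RadialIntegrationConfig | None = None,
                         ) -> StructureFactorMap:
    """Row-wise S(q_z, q_par) map with optional beam smearing.

    Rows are independent; the result does not depend on evaluation order.
    ``corr`` may be a pre-rescaled table; otherwise ``unit_table`` (or a
    freshly built one) is rescaled to ``p``.
    """
    qz_axis = np.asarray(qz_axis, dtype=float)
    qpar = np.asarray(qpar_axis, dtype=float)
    if corr is None:
        if unit_table is None:
            unit_table = build_unit_correlation_table(
                np.geomspace(1e-4, 1e6, 4000), n_max=max(40, 2))
        corr = rescale_correlation(unit_table, p)
    if beam is not None and beam.sigma_q > 0:
        dq = np.diff(qpar)
        if dq.size and not np.allclose(dq, dq[0], rtol=1e-8):
            raise ValueError("beam convolution requires a uniform q_par grid")
    S = np.empty((len(qz_axis), len(qpar)))
    for i, qz in enumerate(qz_axis):
        row = structure_factor_profile(qz, qpar, p, m, corr, config)
        if beam is not None and beam.sigma_q > 0 and len(qpar) > 1:
            row = convolve_beam(row, beam, float(qpar[1] - qpar[0]))
        S[i] = row
    return StructureFactorMap(qz_axis=qz_axis, qpar_axis=qpar, S=S)


# ---------------------------------------------------------------------------
# moduli conversions
# ---------------------------------------------------------------------------

def moduli_from_caille(p: CailleParameters, T: float) -> ElasticModuli:
    """Invert the Caillé relations: κ = k_B T q1² ξ²/(8π η), B = κ/ξ⁴."""
    if p.eta <= 0:
        raise ValueError("eta must be > 0 to determine kappa")
    kappa = KB * T * p.q1 ** 2 * p.xi ** 2 / (8.0 * math.pi * p.eta)
    return ElasticModuli(kappa=kappa, B=kappa / p.xi ** 4, T=T)


def caille_from_moduli(mod: ElasticModuli, q1: float) -> CailleParameters:
    """η = k_B T q1²/(8π√(Bκ)), ξ = (κ/B)^(1/4)."""
    eta = KB * mod.T * q1 ** 2 / (8.0 * math.pi * math.sqrt(mod.B * mod.kappa))
    xi = (mod.kappa / mod.B) ** 0.25
    return CailleParameters(eta=eta, xi=xi, q1=q1)
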