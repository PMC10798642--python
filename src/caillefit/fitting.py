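"""Simultaneous Caillé-model fits to diffuse-scattering line cuts.

Two or more q_par line cuts at distinct q_z are fitted with the smectic
structure factor.  The nonlinear parameters are the Caillé pair (η, ξ);
one multiplicative scale per cut absorbs the form factor |F(q_z)|² and
is profiled out analytically at every step (the weighted least-squares
optimum in each scale is closed-form), so the search is two-dimensional.
On convergence (η̂, ξ̂) are converted to the bending modulus κ and the
compression modulus B at the stated temperature.

The default objective is the standard variance-weighted chi-square
χ² = Σ (s_l Y_l[k] − y_l[k])²/σ_l[k]²; ``linear_sigma_weighting=True``
divides by the first power of σ instead (a convention seen in the
literature, though it makes χ² carry units).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares, minimize

from .model import (BeamModel, CailleParameters, CorrelationTable,
                    ElasticModuli, FiniteSizeModel, RadialIntegrationConfig,
                    SizeWeightTables, build_unit_correlation_table,
                    convolve_beam, moduli_from_caille, rescale_correlation,
                    size_weight_radial, structure_factor_profile)
from .reduction import LineCut

__all__ = ["FitConfig", "FitResult", "chi_squared", "optimal_scales",
           "fit_structure_factor", "ModelEvaluator"]

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Configuration of a structure-factor fit.

    ``eta0``/``xi0`` are start values, bounded by ``eta_bounds`` (default
    (0, 2]) and ``xi_bounds`` (default [1, 1e5] Å).  ``size`` holds the
    fixed finite-size model (which also carries the d-spacing), ``beam``
    the Gaussian beam width, ``temperature`` the sample temperature in K.
    ``qpar_min`` excludes |q_par| below it from the objective (specular /
    beam-stop region; 0 disables).  ``method`` is ``"least_squares"``
    (trust-region, default) or ``"simplex"`` (Nelder–Mead fallback).
    """

    eta0: float
    xi0: float
    size: FiniteSizeModel
    beam: BeamModel = field(default_factory=BeamModel)
    temperature: float = 298.0
    eta_bounds: tuple[float, float] = (1e-6, 2.0)
    xi_bounds: tuple[float, float] = (1.0, 1e5)
    qpar_min: float = 0.0
    ftol: float = 1e-10
    xtol: float = 1e-10
    max_iterations: int = 200
    method: str = "least_squares"
    linear_sigma_weighting: bool = False
    integration: RadialIntegrationConfig = field(
        default_factory=RadialIntegrationConfig)
    n_range: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if not (self.eta_bounds[0] <= self.eta0 <= self.eta_bounds[1]):
            raise ValueError("eta0 outside bounds")
        if not (self.xi_bounds[0] <= self.xi0 <= self.xi_bounds[1]):
            raise ValueError("xi0 outside bounds")


@dataclass
class FitResult:
    """Converged fit: Caillé parameters with approximate standard errors,
    per-cut scales, derived moduli, χ² and the accepted-step trace."""

    eta: float
    xi: float
    eta_se: float
    xi_se: float
    scales: np.ndarray
    moduli: ElasticModuli
    chi2: float
    per_cut_chi2: np.ndarray
    trace: list            # (chi2, eta, xi) per accepted step
    n_evaluations: int
    converged: bool
    message: str

    @property
    def kappa(self) -> float:
        return self.moduli.kappa

    @property
    def B(self) -> float:
        return self.moduli.B


def _weights(cuts: Sequence[LineCut], linear_sigma_weighting: bool):
    w = []
    for c in cuts:
        s = np.asarray(c.sigma, dtype=float)
        if np.any(s <= 0):
            raise ValueError("sigma must be > 0 everywhere")
        w.append(1.0 / s if not linear_sigma_weighting else 1.0 / np.sqrt(s))
    return w


def chi_squared(model_cuts: Sequence[LineCut], data_cuts: Sequence[LineCut],
                scales: Sequence[float],
                linear_sigma_weighting: bool = False) -> float:
    """χ² = Σ_l Σ_k (s_l Y_l[k] − y_l[k])² / σ_l[k]² on shared q grids."""
    if len(model_cuts) != len(data_cuts) or len(scales) != len(data_cuts):
        raise ValueError("model cuts, data cuts and scales must align")
    w = _weights(data_cuts, linear_sigma_weighting)
    total = 0.0
    for mc, dc, s, wl in zip(model_cuts, data_cuts, scales, w):
        resid = (s * np.asarray(mc.intensity) - np.asarray(dc.intensity)) * wl
        total += float(resid @ resid)
    return total


def optimal_scales(model_cuts: Sequence[LineCut],
                   data_cuts: Sequence[LineCut],
                   linear_sigma_weighting: bool = False) -> np.ndarray:
    """Closed-form weighted least-squares scale per cut:
    s_l = Σ_k Y y/σ² ÷ Σ_k Y²/σ².  Raises if a cut's optimum is not
    positive (all-zero or sign-inverted model)."""
    w = _weights(data_cuts, linear_sigma_weighting)
    out = np.empty(len(model_cuts))
    for i, (mc, dc, wl) in enumerate(zip(model_cuts, data_cuts, w)):
        Y = np.asarray(mc.intensity) * wl
        y = np.asarray(dc.intensity) * wl
        denom = float(Y @ Y)
        if denom <= 0:
            raise ValueError(f"model cut {i} is identically zero")
        s = float(Y @ y) / denom
        if s <= 0:
            raise ValueError(f"optimal scale for cut {i} is not positive")
        out[i] = s
    return out


class ModelEvaluator:
    """Computes model cuts on the data's q_par abscissae for given (η, ξ).

    The structure-factor profile is evaluated on an internal uniform,
    symmetric q_par grid (fine enough to sample the beam kernel),
    beam-convolved, and cubic-interpolated onto each data grid.  The
    unit correlation table is built once and only rescaled per call.
    """

    def __init__(self, data_cuts: Sequence[LineCut], config: FitConfig,
                 unit_table: CorrelationTable | None = None):
        self.cuts = list(data_cuts)
        self.cfg = config
        m = config.size
        if unit_table is None:
            # radial coverage: need r in [step, Lr support] for any xi in
            # bounds -> unit radii down to r_min/xi_max and up to
            # support/xi_min
            unit_table = build_unit_correlation_table(
                np.geomspace(1e-5, 1e6, 4000),
                n_max=min(1000, max(m.n_support, 2)))
        self.unit_table = unit_table
        qmax = max(float(np.max(np.abs(c.qpar))) for c in self.cuts)
        spacing = min(float(np.min(np.abs(np.diff(np.sort(c.qpar)))))
                      for c in self.cuts)
        if config.beam.sigma_q > 0:
            spacing = min(spacing, config.beam.sigma_q / 2.0)
        self.dq = spacing
        half = int(math.ceil((qmax + 6.0 * config.beam.sigma_q) / spacing)) + 2
        self.qgrid = np.arange(-half, half + 1) * spacing
        grid_cfg = config.integration
        r_lo = max(grid_cfg.r_min, self.unit_table.r_grid[0] * config.xi_bounds[0])
        r_hi = min(grid_cfg.r_max, m.r_support)
        self.r_int = np.arange(r_lo, r_hi + 0.5 * grid_cfg.step, grid_cfg.step)
        self.weights = SizeWeightTables(
            r_grid=self.r_int, Hr=size_weight_radial(self.r_int, m),
            Hz=np.empty(0))

    def __call__(self, eta: float, xi: float) -> list[LineCut]:
        p = CailleParameters(eta=eta, xi=xi, d=self.cfg.size.d)
        corr = rescale_correlation(self.unit_table, p)
        half = self.qgrid[self.qgrid >= 0.0]
        out = []
        for cut in self.cuts:
            prof_half = structure_factor_profile(
                cut.qz_center, half, p, self.cfg.size, corr,
                config=self.cfg.integration, weights=self.weights,
                n_range=self.cfg.n_range)
            full = np.concatenate([prof_half[:0:-1], prof_half])
            if self.cfg.beam.sigma_q > 0:
                full = convolve_beam(full, self.cfg.beam, self.dq)
            spline = CubicSpline(self.qgrid, full)
            model_y = spline(np.clip(cut.qpar, self.qgrid[0], self.qgrid[-1]))
            out.append(LineCut(qz_center=cut.qz_center, qpar=cut.qpar,
                               intensity=np.clip(model_y, 0.0, None),
                               sigma=np.ones_like(model_y)))
        return out


def _masked(cuts: Sequence[LineCut], qpar_min: float) -> list[LineCut]:
    if qpar_min <= 0:
        return list(cuts)
    out = []
    for c in cuts:
        keep = np.abs(c.qpar) >= qpar_min
        out.append(LineCut(qz_center=c.qz_center, qpar=c.qpar[keep],
                           intensity=np.asarray(c.intensity)[keep],
                           sigma=np.asarray(c.sigma)[keep],
                           box_halfwidth=c.box_halfwidth,
                           background_subtracted=c.background_subtracted,
                           meta=dict(c.meta)))
    return out


def fit_structure_factor(data_cuts: Sequence[LineCut], config: FitConfig,
                         unit_table: CorrelationTable | None = None
                         ) -> FitResult:
    """Minimize χ² over (η, ξ) with per-cut scales profiled out.

    Requires at least two cuts at distinct q_z.  The primary optimizer is
    trust-region least squares with a numerically differenced Jacobian;
    ``config.method = "simplex"`` selects a Nelder–Mead fallback on the
    scalar χ².  Non-convergence within ``max_iterations`` returns the best
    point, flagged.
    """
    if len(data_cuts) < 2:
        raise ValueError("at least two line cuts at distinct q_z are "
                         "required to determine eta and xi")
    qz = [c.qz_center for c in data_cuts]
    if len(set(np.round(qz, 12))) < 2:
        raise ValueError("line cuts must be at distinct q_z values")

    data = _masked(data_cuts, config.qpar_min)
    evaluator = ModelEvaluator(data, config, unit_table=unit_table)
    w = _weights(data, config.linear_sigma_weighting)
    y_concat = np.concatenate([np.asarray(c.intensity) * wl
                               for c, wl in zip(data, w)])

    state = {"best": math.inf, "trace": [], "n": 0, "scales": None}

    def safe_scales(model):
        # optimal_scales raises on degenerate cuts; inside the search a
        # pathological trial point must instead yield a terrible chi2
        out = np.zeros(len(model))
        for i, (mc, dc, wl) in enumerate(zip(model, data, w)):
            Y = np.asarray(mc.intensity) * wl
            y = np.asarray(dc.intensity) * wl
            denom = float(Y @ Y)
            out[i] = max(float(Y @ y) / denom, 0.0) if denom > 0 else 0.0
        return out

    def residuals(x):
        eta, xi = float(x[0]), float(x[1])
        model = evaluator(eta, xi)
        scales = safe_scales(model)
        parts = [s * np.asarray(mc.intensity) * wl
                 for mc, s, wl in zip(model, scales, w)]
        resid = np.concatenate(parts) - y_concat
        chi2 = float(resid @ resid)
        state["n"] += 1
        if chi2 < state["best"]:
            state["best"] = chi2
            state["trace"].append((chi2, eta, xi))
            state["scales"] = scales
        return resid

    lo = np.array([config.eta_bounds[0], config.xi_bounds[0]])
    hi = np.array([config.eta_bounds[1], config.xi_bounds[1]])
    x0 = np.array([config.eta0, config.xi0])

    if config.method == "least_squares":
        res = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf",
            x_scale=np.maximum(x0, [1e-3, 1.0]),
            ftol=config.ftol, xtol=config.xtol, gtol=1e-12,
            max_nfev=max(config.max_iterations * 3, 6), diff_step=1e-4)
        xhat = res.x
        converged = bool(res.status > 0) and res.nfev < config.max_iterations * 3
        message = res.message
        jac = res.jac
    elif config.method == "simplex":
        def scalar(x):
            xc = np.clip(x, lo, hi)
            r = residuals(xc)
            penalty = 1.0 + 1e3 * float(np.sum((x - xc) ** 2))
            return float(r @ r) * penalty
        res = minimize(scalar, x0, method="Nelder-Mead",
                       options={"maxiter": config.max_iterations,
                                "xatol": 1e-8, "fatol": config.ftol})
        xhat = np.clip(res.x, lo, hi)
        converged = bool(res.success)
        message = res.message
        jac = None
    else:
        raise ValueError("method must be 'least_squares' or 'simplex'")

    resid = residuals(xhat)          # ensure state corresponds to optimum
    chi2 = float(resid @ resid)
    eta_hat, xi_hat = float(xhat[0]), float(xhat[1])
    scales = state["scales"]
    if np.any(np.isclose(xhat, lo)) or np.any(np.isclose(xhat, hi)):
        converged = False
        message = f"{message} (parameter at bound)"

    # approximate standard errors from the local quadratic expansion
    eta_se = xi_se = float("nan")
    if jac is not None:
        try:
            dof = max(len(resid) - 2 - len(data), 1)
            cov = np.linalg.inv(jac.T @ jac) * (chi2 / dof)
            eta_se, xi_se = (float(math.sqrt(cov[0, 0])),
                             float(math.sqrt(cov[1, 1])))
        except np.linalg.LinAlgError:
            pass

    model = evaluator(eta_hat, xi_hat)
    per_cut = np.array([
        chi_squared([mc], [dc], [s], config.linear_sigma_weighting)
        for mc, dc, s in zip(model, data, scales)])

    p_hat = CailleParameters(eta=eta_hat, xi=xi_hat, d=config.size.d)
    moduli = moduli_from_caille(p_hat, config.temperature)
    return FitResult(eta=eta_hat, xi=xi_hat, eta_se=eta_se, xi_se=xi_se,
                     scales=np.asarray(scales), moduli=moduli, chi2=chi2,
                     per_cut_chi2=per_cut, trace=state["trace"],
                     n_evaluations=state["n"], converged=converged,
                     message=str(message))
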