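"""Reduction of 2-D detector images to q-space profiles and line cuts.

A flat detector subtends the spherical coordinate system of reciprocal
space: equal pixel offsets are not equal angles.  Each pixel is mapped to
a meridional angle θ (vertical) and an azimuthal angle Ξ (horizontal),
either linearly (``angle = PX_size·k/L``) or with the arctangent
correction (``angle = atan(PX_size·k/L)``) that removes the flat-detector
distortion; the scattering-vector components follow as

    q_z = 4π sin(θ)/λ,   q_par = 4π sin(Ξ/2)/λ.

Intensities are never reinterpolated: cuts and profiles are taken on
pixel rows/columns and labeled with their q values.  Uncertainties are
Poisson, var = max(counts, 1), propagated as variance/m under averaging.

Conventions: row 0 is the top of the TIFF, the beam center is (row, col)
with fractional values allowed, and q_z increases upward from the beam
center.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy.signal import find_peaks

__all__ = [
    "DetectorGeometry", "IntensityMap", "QMap", "ReflectivityProfile",
    "LineCut", "load_intensity_map", "pixel_to_angles", "angles_to_q",
    "map_to_qspace", "meridional_profile", "estimate_d_spacing",
    "extract_line_cuts", "subtract_background",
]

logger = logging.getLogger(__name__)

_RAD2DEG = 360.0 / (2.0 * math.pi)


@dataclass(frozen=True)
class DetectorGeometry:
    """Instrument geometry needed to assign q values to pixels.

    distance_L and pixel_size in mm, beam_center as (row, col) in pixels
    (fractional allowed), wavelength in Å.  ``distort_qz``/``distort_qpar``
    enable the arctangent distortion correction per axis (the historical
    labels "distorted/non-distorted" refer to the raw image; the atan
    branch is the geometric truth for a flat detector).
    """

    distance_L: float
    pixel_size: float
    beam_center: tuple[float, float]
    wavelength: float
    distort_qz: bool = True
    distort_qpar: bool = True

    def __post_init__(self):
        if self.distance_L <= 0:
            raise ValueError("distance_L must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not 0.1 <= self.wavelength <= 10.0:
            raise ValueError("wavelength must be in [0.1, 10] Å")


@dataclass
class IntensityMap:
    """Linearized detector intensities with per-pixel Poisson variance."""

    data: np.ndarray
    log_scale: bool = False
    variance: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("intensity map must be 2-dimensional")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity map contains non-finite values")
        if self.variance is None:
            self.variance = np.maximum(self.data, 1.0)


@dataclass
class QMap:
    """Per-pixel q coordinates plus the untouched intensities."""

    qz: np.ndarray
    qpar: np.ndarray
    intensity: np.ndarray
    variance: np.ndarray
    geometry: DetectorGeometry


@dataclass
class ReflectivityProfile:
    """Meridional intensity scan: q_z axis (strictly increasing),
    averaged intensity and its standard error."""

    qz: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray


@dataclass
class LineCut:
    """One q_par intensity profile at fixed q_z."""

    qz_center: float
    qpar: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    box_halfwidth: int = 0
    background_subtracted: bool = False
    meta: dict = field(default_factory=dict)


def load_intensity_map(path, log_scale: bool = False) -> IntensityMap:
    """Read a grayscale TIFF; if ``log_scale``, linearize as I = 10^stored.

    Raises on multi-channel images and on negative linearized values.
    """
    stored = tifffile.imread(path)
    if stored.ndim != 2:
        raise ValueError(
            f"expected a single-channel grayscale TIFF, got shape "
            f"{stored.shape} (multi-channel/RGB input is not supported)")
    stored = stored.astype(float)
    data = np.power(10.0, stored) if log_scale else stored
    if np.any(data < 0):
        raise ValueError("negative intensities after linearization")
    return IntensityMap(data=data, log_scale=log_scale)


def pixel_to_angles(row, col, g: DetectorGeometry):
    """(θ, Ξ) in degrees for (fractional) pixel indices.

    θ grows upward from the beam center, Ξ to the right; each axis uses
    the linear or arctangent branch per the geometry's distortion flags.
    """
    kv = g.beam_center[0] - np.asarray(row, dtype=float)
    kh = np.asarray(col, dtype=float) - g.beam_center[1]
    sv = g.pixel_size * kv / g.distance_L
    sh = g.pixel_size * kh / g.distance_L
    theta = (np.arctan(sv) if g.distort_qz else sv) * _RAD2DEG
    xi = (np.arctan(sh) if g.distort_qpar else sh) * _RAD2DEG
    return theta, xi


def angles_to_q(theta, xi, wavelength: float):
    """(q_z, q_par) in Å⁻¹ from angles in degrees:
    q_z = 4π sin(θ)/λ, q_par = 4π sin(Ξ/2)/λ."""
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    th = np.deg2rad(theta)
    x2 = np.deg2rad(xi) / 2.0
    pref = 4.0 * math.pi / wavelength
    return pref * np.sin(th), pref * np.sin(x2)


def map_to_qspace(img: IntensityMap, g: DetectorGeometry) -> QMap:
    """Label every pixel with (q_z, q_par); intensities are untouched."""
    rows = np.arange(img.data.shape[0])
    cols = np.arange(img.data.shape[1])
    theta, _ = pixel_to_angles(rows, np.zeros_like(rows), g)
    _, xi = pixel_to_angles(np.zeros_like(cols), cols, g)
    qz_axis, _ = angles_to_q(theta, np.zeros_like(theta), g.wavelength)
    _, qpar_axis = angles_to_q(np.zeros_like(xi), xi, g.wavelength)
    qz = np.broadcast_to(qz_axis[:, None], img.data.shape).copy()
    qpar = np.broadcast_to(qpar_axis[None, :], img.data.shape).copy()
    return QMap(qz=qz, qpar=qpar, intensity=img.data.copy(),
                variance=np.asarray(img.variance).copy(), geometry=g)


def _center_columns(qmap: QMap, width: int) -> np.ndarray:
    ncol = qmap.intensity.shape[1]
    c0 = qmap.geometry.beam_center[1]
    order = np.argsort(np.abs(np.arange(ncol) - c0), kind="stable")
    if width > ncol:
        warnings.warn("averaging box exceeds the detector; clipped")
        width = ncol
    return np.sort(order[:width])


def meridional_profile(qmap: QMap, box_width: int = 12) -> ReflectivityProfile:
    """Mean intensity over a ``box_width``-pixel-wide box centered at
    q_par = 0, per detector row; σ by variance propagation."""
    cols = _center_columns(qmap, box_width)
    inten = qmap.intensity[:, cols].mean(axis=1)
    sig = np.sqrt(qmap.variance[:, cols].sum(axis=1)) / len(cols)
    qz = qmap.qz[:, cols[len(cols) // 2]]
    order = np.argsort(qz)
    return ReflectivityProfile(qz=qz[order], intensity=inten[order],
                               sigma=sig[order])


def estimate_d_spacing(profile: ReflectivityProfile,
                       peak_orders=None, prominence: float | None = None,
                       qz_min: float = 0.02) -> float:
    """Repeat spacing d from lamellar peak positions, d = 2π n/q_z(n).

    Peaks are local maxima above a prominence threshold (default 2% of
    the intensity range) at q_z > ``qz_min``; orders are taken from
    ``peak_orders`` or inferred from the first detected peak.
    """
    mask = profile.qz > qz_min
    y = profile.intensity[mask]
    q = profile.qz[mask]
    if len(y) < 3:
        raise ValueError("profile too short for peak detection; "
                         "enter the d-spacing manually")
    if prominence is None:
        prominence = 0.02 * (float(y.max()) - float(y.min()) + 1e-300)
    idx, _ = find_peaks(y, prominence=prominence)
    if len(idx) == 0:
        raise ValueError("no lamellar peaks found; enter the d-spacing "
                         "manually")
    # sub-pixel refinement: parabola through the peak and its neighbours
    qpk = np.empty(len(idx), dtype=float)
    for j, i in enumerate(idx):
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
            shift = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom < 0 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
            qpk[j] = q[i] + shift * 0.5 * (q[min(i + 1, len(q) - 1)]
                                           - q[max(i - 1, 0)])
        else:
            qpk[j] = q[i]
    if peak_orders is not None:
        orders = np.asarray(peak_orders, dtype=float)
        if len(orders) != len(qpk):
            raise ValueError(f"found {len(qpk)} peaks but {len(orders)} "
                             "orders were given")
    else:
        orders = np.round(qpk / qpk[0])
    return float(np.mean(2.0 * math.pi * orders / qpk))


def extract_line_cuts(qmap: QMap, qz_list, box_pixels: int = 1,
                      mode: str = "average") -> list[LineCut]:
    """Line cuts at the requested q_z values.

    ``mode="average"`` averages the ``box_pixels`` rows of the box
    (one cut per requested q_z); ``mode="per_row"`` emits one cut per
    row in the box.
    """
    if box_pixels < 1:
        raise ValueError("box_pixels must be >= 1")
    cols = np.arange(qmap.intensity.shape[1])
    ccol = int(np.argmin(np.abs(qmap.qpar[0])))
    qz_axis = qmap.qz[:, ccol]
    lo, hi = float(qz_axis.min()), float(qz_axis.max())
    cuts: list[LineCut] = []
    for qz0 in np.atleast_1d(qz_list):
        if not lo <= qz0 <= hi:
            raise ValueError(f"q_z = {qz0:g} outside the detector range "
                             f"[{lo:.4g}, {hi:.4g}] Å⁻¹")
        i0 = int(np.argmin(np.abs(qz_axis - qz0)))
        top = max(i0 - (box_pixels - 1) // 2, 0)
        rows = np.arange(top, min(top + box_pixels, len(qz_axis)))
        qpar = qmap.qpar[i0]
        if mode == "average":
            inten = qmap.intensity[rows].mean(axis=0)
            sig = np.sqrt(qmap.variance[rows].sum(axis=0)) / len(rows)
            cuts.append(LineCut(qz_center=float(qz_axis[i0]), qpar=qpar.copy(),
                                intensity=inten, sigma=sig,
                                box_halfwidth=box_pixels // 2))
        elif mode == "per_row":
            for r in rows:
                cuts.append(LineCut(qz_center=float(qz_axis[r]),
                                    qpar=qmap.qpar[r].copy(),
                                    intensity=qmap.intensity[r].copy(),
                                    sigma=np.sqrt(qmap.variance[r]),
                                    box_halfwidth=0))
        else:
            raise ValueError("mode must be 'average' or 'per_row'")
    return cuts


def subtract_background(cut: LineCut,
                        flank_fraction: float = 0.1) -> LineCut:
    """Constant-baseline background subtraction.

    The baseline is the median of the outer ``flank_fraction`` of points
    on each side (where the diffuse signal should have decayed);
    negative results are floored at zero with the count logged.  This is
    the declared rudimentary method; subtract instrumental backgrounds
    upstream for best results.
    """
    if not 0 < flank_fraction < 0.5:
        raise ValueError("flank_fraction must be in (0, 0.5)")
    npts = len(cut.intensity)
    m = max(3, int(round(flank_fraction * npts)))
    flanks = np.concatenate([cut.intensity[:m], cut.intensity[-m:]])
    baseline = float(np.median(flanks))
    if baseline > 0.5 * float(cut.intensity.max()):
        warnings.warn("baseline exceeds 50% of the peak; flanks may "
                      "overlap the signal region")
    sub = cut.intensity - baseline
    floored = int(np.sum(sub < 0))
    if floored:
        logger.info("floored %d negative points after background "
                    "subtraction (q_z = %.4g)", floored, cut.qz_center)
    meta = dict(cut.meta)
    meta.update(background_method="median-flank constant",
                baseline=baseline, flank_fraction=flank_fraction,
                floored_points=floored)
    return replace(cut, intensity=np.maximum(sub, 0.0),
                   background_subtracted=True, meta=meta)
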