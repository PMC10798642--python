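"""Plain-text I/O: 3-column cut/profile tables, truth/config records,
fit reports and result archives."""

from __future__ import annotations

import json
import zipfile
from pathlib import Path

import numpy as np

from .fitting import FitResult
from .reduction import LineCut, ReflectivityProfile

__all__ = ["write_cut", "read_cut", "write_profile", "write_map_text",
           "write_fit_report", "read_key_value", "write_key_value",
           "bundle_archive", "TABLE1_ALIASES", "normalize_key"]


def write_cut(cut: LineCut, path) -> None:
    """3-column (q_par, I, sigma) table with the cut metadata in the header."""
    header = [f"qz_center = {cut.qz_center:.10g}",
              f"box_halfwidth = {cut.box_halfwidth}",
              f"background_subtracted = {cut.background_subtracted}"]
    for k, v in cut.meta.items():
        if isinstance(v, (int, float, str, bool)):
            header.append(f"{k} = {v}")
    header.append("qpar[1/A]  intensity  sigma")
    np.savetxt(path, np.column_stack([cut.qpar, cut.intensity, cut.sigma]),
               header="\n".join(header), fmt="%.10g")


def read_cut(path) -> LineCut:
    qz_center = 0.0
    box_halfwidth = 0
    background = False
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("qz_center"):
                qz_center = float(body.split("=")[1])
            elif body.startswith("box_halfwidth"):
                box_halfwidth = int(body.split("=")[1])
            elif body.startswith("background_subtracted"):
                background = body.split("=")[1].strip() == "True"
    data = np.loadtxt(path)
    return LineCut(qz_center=qz_center, qpar=data[:, 0], intensity=data[:, 1],
                   sigma=data[:, 2], box_halfwidth=box_halfwidth,
                   background_subtracted=background)


def write_profile(profile: ReflectivityProfile, path) -> None:
    np.savetxt(path, np.column_stack([profile.qz, profile.intensity,
                                      profile.sigma]),
               header="qz[1/A]  intensity  sigma", fmt="%.10g")


def write_map_text(qz_axis, qpar_axis, S, path) -> None:
    """Plain-text matrix: first row q_par axis, first column q_z axis."""
    out = np.zeros((len(qz_axis) + 1, len(qpar_axis) + 1))
    out[0, 1:] = qpar_axis
    out[1:, 0] = qz_axis
    out[1:, 1:] = S
    np.savetxt(path, out, header="row 0: qpar axis; col 0: qz axis; "
               "body: S(qz, qpar)", fmt="%.8g")


def write_fit_report(result: FitResult, path) -> None:
    """JSON fit summary: Caillé parameters, moduli in J and k_BT, χ²,
    per-cut scales and the iteration trace."""
    payload = {
        "eta": result.eta, "eta_se": result.eta_se,
        "xi_A": result.xi, "xi_se": result.xi_se,
        "kappa_J": result.moduli.kappa,
        "kappa_kBT": result.moduli.kappa_kBT,
        "B_J_per_A4": result.moduli.B,
        "B_erg_per_cm4": result.moduli.B_erg_cm4,
        "temperature_K": result.moduli.T,
        "chi2": result.chi2,
        "per_cut_chi2": list(result.per_cut_chi2),
        "scales": list(result.scales),
        "converged": result.converged,
        "message": result.message,
        "n_evaluations": result.n_evaluations,
        "trace": [{"chi2": c, "eta": e, "xi": x} for c, e, x in result.trace],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_key_value(record: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in record.items():
            fh.write(f"{k} = {v}\n")


def read_key_value(path) -> dict:
    """Flat key = value file; values parsed as bool/int/float when possible."""
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line or "=" not in line:
            continue
        key, val = line.split("=", 1)
        out[normalize_key(key)] = _parse_scalar(val.strip())
    return out


def _parse_scalar(text: str):
    low = text.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


#: accepted config keys (normalized) -> canonical parameter names; covers
#: the descriptive labels of the web tool's parameter table.
TABLE1_ALIASES = {
    "sample_to_detector_distance": "distance_mm",
    "distance": "distance_mm",
    "distance_mm": "distance_mm",
    "detector_pixel_size": "pixel_size_mm",
    "pixel_size": "pixel_size_mm",
    "pixel_size_mm": "pixel_size_mm",
    "origin_in_x": "beam_center_col",
    "origin_in_y": "beam_center_row",
    "beam_center_row": "beam_center_row",
    "beam_center_col": "beam_center_col",
    "wavelength": "wavelength",
    "lambda": "wavelength",
    "q_cut_parameter": "qz_cuts",
    "qz_cuts": "qz_cuts",
    "pixel_to_be_averaged": "box_pixels",
    "pixels_to_be_averaged": "box_pixels",
    "box_pixels": "box_pixels",
    "distortion_in_q_par": "distort_qpar",
    "distort_qpar": "distort_qpar",
    "distortion_in_q_z": "distort_qz",
    "distort_qz": "distort_qz",
    "xi": "xi", "eta": "eta",
    "domain_size_l_r": "lr_mean", "domain_size_lr": "lr_mean",
    "lr_mean": "lr_mean",
    "domain_size_spread_s_r": "lr_sigma", "domain_size_spread_sr": "lr_sigma",
    "lr_sigma": "lr_sigma",
    "lz_mean": "lz_mean", "lz_sigma": "lz_sigma",
    "beam_width": "beam_sigma_q", "beam_sigma_q": "beam_sigma_q",
    "d_spacing": "d", "d": "d",
    "temperature": "temperature",
    "log_scale": "log_scale",
    "background": "background",
    "qpar_min": "qpar_min",
}


def normalize_key(key: str) -> str:
    """Case-insensitive, spaces/dashes to underscores."""
    return (key.strip().lower().replace(" ", "_").replace("-", "_")
            .replace("*", "").replace("(", "").replace(")", ""))


def bundle_archive(paths, archive_path) -> None:
    """Zip the given files (stored under their basenames)."""
    with zipfile.ZipFile(archive_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for p in paths:
            p = Path(p)
            if p.is_file():
                zf.write(p, arcname=p.name)
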