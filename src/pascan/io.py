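"""File I/O: CSV spectra and calibration tables, JSON reports/models, images.

Numeric CSV fields are written with 17 significant digits so write-then-read
round-trips float64 values bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acquisition import PAImage, Spectrum
from .chemometrics import CalibrationSet, PLSRModel
from .evaluation import EvaluationReport
from .site_selection import SiteSelection
from .synthetic_skin import make_wavenumber_grid

__all__ = [
    "write_spectrum_csv", "read_spectrum_csv",
    "write_calibration_csv", "read_calibration_csv",
    "write_image_text", "read_image_text", "write_image_png",
    "write_report_json", "read_report_json",
    "write_site_selection_json",
    "write_plsr_model_json", "read_plsr_model_json",
    "read_pulse_energy_csv",
    "load_config_file", "dump_config_file",
]

_FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# -- spectra ----------------------------------------------------------------

def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    df = pd.DataFrame(
        {"wavenumber_cm-1": spectrum.grid.points, "value": spectrum.values}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectrum_csv(path, normalized: bool = False) -> Spectrum:
    df = _read_csv(path, required=("wavenumber_cm-1", "value"))
    nu = df["wavenumber_cm-1"].to_numpy()
    step = float(np.mean(np.diff(nu)))
    grid = make_wavenumber_grid(float(nu[0]), float(nu[-1]) + step, step)
    return Spectrum(grid=grid, values=df["value"].to_numpy(), normalized=normalized)


# -- calibration sets -------------------------------------------------------

def write_calibration_csv(calset: CalibrationSet, path) -> None:
    """First column reference_glucose_mg_dl, one column per wavenumber."""
    if calset.grid is None:
        raise ValueError("calibration set needs a wavenumber grid for CSV export")
    columns = {"reference_glucose_mg_dl": calset.y}
    for j, nu in enumerate(calset.grid.points):
        columns[_fmt(nu)] = calset.X[:, j]
    pd.DataFrame(columns).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_calibration_csv(path) -> CalibrationSet:
    df = _read_csv(path, required=("reference_glucose_mg_dl",))
    y = df["reference_glucose_mg_dl"].to_numpy()
    nu = np.array([float(c) for c in df.columns[1:]])
    if nu.size < 2:
        raise ValueError(f"{path}: calibration CSV needs at least two wavenumber columns")
    step = float(np.mean(np.diff(nu)))
    grid = make_wavenumber_grid(float(nu[0]), float(nu[-1]) + step, step)
    return CalibrationSet(X=df.iloc[:, 1:].to_numpy(), y=y, grid=grid)


def _read_csv(path, required=()):
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed CSV ({err})") from err
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


# -- images -----------------------------------------------------------------

def write_image_text(image: PAImage, path) -> None:
    header = (
        f"pixel_pitch_um: {_fmt(image.pixel_pitch)}\n"
        f"origin_um: {_fmt(image.origin[0])} {_fmt(image.origin[1])}\n"
        f"wavenumber_cm-1: {_fmt(image.wavenumber)}"
    )
    np.savetxt(path, image.values, fmt=_FLOAT_FMT, header=header)


def read_image_text(path) -> PAImage:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, rest = line[1:].strip().partition(":")
            meta[key.strip()] = rest.split()
    values = np.loadtxt(path)
    return PAImage(
        values=np.atleast_2d(values),
        pixel_pitch=float(meta["pixel_pitch_um"][0]),
        origin=(float(meta["origin_um"][0]), float(meta["origin_um"][1])),
        wavenumber=float(meta["wavenumber_cm-1"][0]),
    )


def write_image_png(image: PAImage, path) -> None:
    """Min-max scaled grayscale PNG export (display only, lossy)."""
    import matplotlib.image

    v = image.values
    span = v.max() - v.min()
    scaled = (v - v.min()) / span if span > 0 else np.zeros_like(v)
    matplotlib.image.imsave(path, scaled, cmap="gray", vmin=0.0, vmax=1.0)


# -- reports, sites, models -------------------------------------------------

def write_report_json(report: EvaluationReport, path) -> None:
    Path(path).write_text(report.to_json())


def read_report_json(path) -> EvaluationReport:
    return EvaluationReport.from_json(Path(path).read_text())


def write_site_selection_json(selection: SiteSelection, path) -> None:
    Path(path).write_text(json.dumps(selection.to_dict(), indent=2))


def write_plsr_model_json(model: PLSRModel, path) -> None:
    payload = {
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "T": model.T.tolist(),
        "q": model.q.tolist(),
        "b": model.b.tolist(),
        "n_lv": model.n_lv,
    }
    Path(path).write_text(json.dumps(payload))


def read_plsr_model_json(path) -> PLSRModel:
    d = json.loads(Path(path).read_text())
    return PLSRModel(
        x_mean=np.array(d["x_mean"]),
        y_mean=float(d["y_mean"]),
        W=np.array(d["W"]),
        P=np.array(d["P"]),
        T=np.array(d["T"]),
        q=np.array(d["q"]),
        b=np.array(d["b"]),
        n_lv=int(d["n_lv"]),
    )


def read_pulse_energy_csv(path) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Load a tabulated pulse-energy curve (wavenumber_cm-1, energy_nJ)."""
    df = _read_csv(path, required=("wavenumber_cm-1", "energy_nJ"))
    return tuple(df["wavenumber_cm-1"]), tuple(df["energy_nJ"])


# -- configs ----------------------------------------------------------------

def load_config_file(path) -> dict:
    """Load a YAML or JSON config mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def dump_config_file(config: dict, path) -> None:
    text = (
        json.dumps(config, indent=2)
        if str(path).endswith(".json")
        else yaml.safe_dump(config, sort_keys=False)
    )
    Path(path).write_text(text)
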