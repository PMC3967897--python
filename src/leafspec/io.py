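"""Readers and writers for the delimited text interchange formats.

Spectra tables are comma-separated UTF-8 with a ``plant_id`` first
column (optionally a ``leaf_id`` second column for per-leaf input) and
integer-nanometre wavelength headers.  Raw sphere sets and mask
calibrations use the same layout with a ``signal`` column.  Trait tables
carry one plant per row with unit-suffixed headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SphereMeasurement, SpectralMatrix, WavelengthAxis
from .mask import MaskCalibration
from .traits import validate_trait_table

SPHERE_SIGNALS = ("sample", "white", "stray", "panel")
CALIBRATION_SIGNALS = ("masked_white", "masked_black", "true_white", "true_black")


def _band_columns(df: pd.DataFrame, reserved) -> list:
    cols = [c for c in df.columns if c not in reserved]
    try:
        [float(c) for c in cols]
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header: {exc}") from exc
    return cols


def read_spectra(path, kind: str) -> SpectralMatrix:
    """Read a per-plant spectra table."""
    df = pd.read_csv(path)
    return SpectralMatrix.from_dataframe(df, kind)


def write_spectra(s: SpectralMatrix, path) -> None:
    s.to_dataframe().to_csv(path, index=False)


def read_leaf_spectra(path) -> tuple[pd.DataFrame, WavelengthAxis]:
    """Read a per-leaf table (plant_id, leaf_id, bands...) for averaging."""
    df = pd.read_csv(path)
    for col in ("plant_id", "leaf_id"):
        if col not in df.columns:
            raise ValueError(f"per-leaf table must have a {col!r} column")
    cols = _band_columns(df, ("plant_id", "leaf_id"))
    axis = WavelengthAxis(np.array([float(c) for c in cols]))
    return df, axis


def read_sphere_set(path) -> dict[str, SphereMeasurement]:
    """Read raw sphere radiances for many leaves from one table.

    Expected columns: ``plant_id``, optional ``leaf_id``, ``signal`` in
    {sample, white, stray}, plus wavelength headers; one additional row
    with ``signal == 'panel'`` holds the panel's absolute reflectance.
    Returns a mapping from "plant_id/leaf_id" to a measurement.
    """
    df = pd.read_csv(path)
    if "signal" not in df.columns:
        raise ValueError("raw sphere table must have a 'signal' column")
    has_leaf = "leaf_id" in df.columns
    reserved = ("plant_id", "leaf_id", "signal") if has_leaf else ("plant_id", "signal")
    cols = _band_columns(df, reserved)
    axis = WavelengthAxis(np.array([float(c) for c in cols]))

    panel_rows = df[df["signal"] == "panel"]
    if len(panel_rows) != 1:
        raise ValueError("raw sphere table needs exactly one 'panel' row")
    panel = panel_rows[cols].to_numpy(dtype=float)[0]

    out: dict[str, SphereMeasurement] = {}
    body = df[df["signal"] != "panel"]
    keys = ["plant_id", "leaf_id"] if has_leaf else ["plant_id"]
    for group_key, grp in body.groupby(keys, sort=False):
        label = "/".join(str(k) for k in (group_key if isinstance(group_key, tuple)
                                          else (group_key,)))
        signals = {}
        for want in ("sample", "white", "stray"):
            rows = grp[grp["signal"] == want]
            if len(rows) != 1:
                raise ValueError(
                    f"measurement {label!r} needs exactly one {want!r} row")
            signals[want] = rows[cols].to_numpy(dtype=float)[0]
        out[label] = SphereMeasurement(
            axis=axis, sample_radiance=signals["sample"],
            white_radiance=signals["white"], stray_radiance=signals["stray"],
            panel_reflectance=panel,
        )
    return out


def read_mask_calibration(path) -> MaskCalibration:
    """Read the four-reference mask-calibration table."""
    df = pd.read_csv(path)
    if "signal" not in df.columns:
        raise ValueError("calibration table must have a 'signal' column")
    cols = _band_columns(df, ("plant_id", "signal"))
    axis = WavelengthAxis(np.array([float(c) for c in cols]))
    vectors = {}
    for want in CALIBRATION_SIGNALS:
        rows = df[df["signal"] == want]
        if len(rows) != 1:
            raise ValueError(f"calibration table needs exactly one {want!r} row")
        vectors[want] = rows[cols].to_numpy(dtype=float)[0]
    return MaskCalibration(axis=axis, **vectors)


def read_trait_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["plant_id"] = df["plant_id"].astype(str)
    return validate_trait_table(df)


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
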