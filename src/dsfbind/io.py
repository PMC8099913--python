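"""Reading and writing melting-curve tables and sample sheets.

The curve file is a plain CSV with one ``Temperature`` column (°C) and one
column per capillary.  The sample sheet is a small YAML file mapping each
data column to its total ligand concentration and carrying the study-level
settings::

    P0: 8uM            # protein concentration (SI-suffixed or molar float)
    signal_type: Ratio # F330 | F350 | Ratio
    window: [30, 70]   # optional analysis window in °C
    dcp: fit           # 'fit' or a fixed value in kcal/(mol K)
    t_grid: 40:60:1    # optional isothermal scan grid lo:hi:step in °C
    curves:
      apo: 0
      c01: 2mM
      c02: 1mM

Concentrations accept SI suffixes (pM, nM, uM/µM, mM, M) or plain molar
numbers.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
import yaml

from .curves import BindingStudy, MeltingCurve, SIGNAL_TYPES

__all__ = [
    "parse_concentration",
    "format_concentration",
    "read_sheet",
    "read_curves",
    "write_study",
]

logger = logging.getLogger(__name__)

_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}
_CONC_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(M|mM|uM|µM|nM|pM)?\s*$")

TEMPERATURE_COLUMN = "Temperature"


def parse_concentration(value) -> float:
    """Parse '2mM', '610nM', '1.5e-6' ... into molar units."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _CONC_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse concentration {value!r}")
    num, unit = m.groups()
    return float(num) * (_UNITS[unit] if unit else 1.0)


def format_concentration(molar: float) -> str:
    """Molar value to a compact SI-suffixed string (for sheets we write)."""
    if molar == 0:
        return "0"
    for unit, scale in (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9),
                        ("pM", 1e-12)):
        if abs(molar) >= scale:
            return f"{molar / scale:.12g}{unit}"
    return f"{molar:.12g}"


def read_sheet(sheet_path) -> dict:
    """Load and validate a sample sheet."""
    with open(sheet_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "curves" not in raw or "P0" not in raw:
        raise ValueError("sample sheet must define at least 'P0' and 'curves'")
    sheet = dict(raw)
    sheet["P0"] = parse_concentration(raw["P0"])
    if sheet["P0"] <= 0:
        raise ValueError("P0 must be positive")
    sheet["signal_type"] = raw.get("signal_type", "Ratio")
    if sheet["signal_type"] not in SIGNAL_TYPES:
        raise ValueError(f"signal_type must be one of {SIGNAL_TYPES}")
    sheet["curves"] = {str(k): parse_concentration(v)
                       for k, v in raw["curves"].items()}
    if any(v < 0 for v in sheet["curves"].values()):
        raise ValueError("ligand concentrations must be non-negative")
    if "window" in raw and raw["window"] is not None:
        window = raw["window"]
        if isinstance(window, str):
            lo, hi = window.split(":")
            window = (float(lo), float(hi))
        sheet["window"] = (float(window[0]), float(window[1]))
    return sheet


def read_curves(curves_path, sheet_path) -> tuple[BindingStudy, dict]:
    """Read a curve CSV plus its sample sheet into a validated study.

    Rows with any non-finite value are dropped (with a logged count);
    duplicate or non-monotone temperatures and unmapped columns are hard
    errors.
    """
    sheet = read_sheet(sheet_path)
    df = pd.read_csv(curves_path)
    if TEMPERATURE_COLUMN not in df.columns:
        raise ValueError(f"curve file lacks a {TEMPERATURE_COLUMN!r} column")

    data_cols = [c for c in df.columns if c != TEMPERATURE_COLUMN]
    mapped = set(sheet["curves"])
    missing = sorted(mapped - set(data_cols))
    if missing:
        raise ValueError(f"sample sheet references missing column(s): {missing}")
    unmapped = sorted(set(data_cols) - mapped)
    if unmapped:
        raise ValueError(f"data column(s) not mapped in the sample sheet: {unmapped}")

    finite = np.isfinite(df.to_numpy(dtype=float)).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        logger.info("dropped %d row(s) with non-finite values", dropped)
    df = df.loc[finite]

    t = df[TEMPERATURE_COLUMN].to_numpy(dtype=float)
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate temperatures in curve file")
    if np.any(np.diff(t) < 0):
        raise ValueError("temperature column must be strictly increasing")

    curves = [
        MeltingCurve(t_celsius=t, y=df[col].to_numpy(dtype=float), l0=l0,
                     label=col, signal_type=sheet["signal_type"])
        for col, l0 in sheet["curves"].items()
    ]
    study = BindingStudy(curves=curves, p0=sheet["P0"],
                         window=sheet.get("window"))
    return study, sheet


def write_study(study: BindingStudy, curves_path, sheet_path, **sheet_extra):
    """Write a study in the curve-CSV + sample-sheet format (round-trips
    through :func:`read_curves`)."""
    data = {TEMPERATURE_COLUMN: study.t_celsius}
    labels = []
    for i, c in enumerate(study.curves):
        label = c.label or f"c{i:02d}"
        labels.append(label)
        data[label] = c.y
    pd.DataFrame(data).to_csv(curves_path, index=False)

    sheet = {
        "P0": format_concentration(study.p0),
        "signal_type": study.signal_type,
        "window": list(study.window),
        "curves": {lab: format_concentration(c.l0)
                   for lab, c in zip(labels, study.curves)},
    }
    sheet.update(sheet_extra)
    with open(sheet_path, "w") as fh:
        yaml.safe_dump(sheet, fh, sort_keys=False)
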