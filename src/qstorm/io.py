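"""Localization-table and image I/O.

Localization tables travel as a ThunderSTORM-compatible CSV dialect: a
header row with the columns ``"frame","x [nm]","y [nm]","sigma [nm]",
"intensity [photon]","uncertainty [nm]"``; ground-truth columns are
prefixed ``gt_``; unknown extra columns are preserved.  Numeric cells are
written with 6 significant digits so write -> read -> write round-trips
byte-identically.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .photophysics import LOCALIZATION_COLUMNS

__all__ = ["read_localizations", "write_localizations", "write_image", "read_image"]

#: canonical internal name -> ThunderSTORM header
CSV_HEADERS = {
    "frame": "frame",
    "x_nm": "x [nm]",
    "y_nm": "y [nm]",
    "sigma_nm": "sigma [nm]",
    "photons": "intensity [photon]",
    "uncertainty_nm": "uncertainty [nm]",
}
_HEADER_TO_INTERNAL = {v: k for k, v in CSV_HEADERS.items()}
MANDATORY = ["frame", "x [nm]", "y [nm]", "intensity [photon]"]


def _format(value, column: str) -> str:
    if column == "frame":
        return str(int(value))
    return format(float(value), ".6g")


def write_localizations(table: pd.DataFrame, path) -> None:
    """Write a localization table in the ThunderSTORM CSV dialect.

    Canonical columns come first in fixed order; truth columns are emitted
    with a ``gt_`` prefix; any other columns follow verbatim.
    """
    cols = [c for c in LOCALIZATION_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    headers = [
        CSV_HEADERS.get(c, "gt_truth_id" if c == "truth_id" else c) for c in cols + extra
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(headers)
        for row in table[cols + extra].itertuples(index=False):
            writer.writerow(
                [
                    _format(v, c) if isinstance(v, (int, float, np.floating, np.integer)) else v
                    for v, c in zip(row, cols + extra)
                ]
            )


def read_localizations(path) -> pd.DataFrame:
    """Read a ThunderSTORM-dialect CSV into the canonical table.

    Raises on missing mandatory columns; non-numeric cells are reported with
    their row number.  Unknown extra columns are kept as-is; ``gt_``-prefixed
    truth columns are preserved.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    missing = [h for h in MANDATORY if h not in raw.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory column(s) {missing}")
    out = {}
    for header in raw.columns:
        name = _HEADER_TO_INTERNAL.get(header, header)
        if name == "gt_truth_id":
            name = "truth_id"
        col = raw[header]
        numeric = pd.to_numeric(col, errors="coerce")
        bad = col[numeric.isna() & col.notna()]
        if len(bad) == 0:
            out[name] = numeric
        elif name in CSV_HEADERS or name == "truth_id":
            raise ValueError(
                f"{path.name}: non-numeric value {bad.iloc[0]!r} in column "
                f"{header!r} at data row {int(bad.index[0]) + 1}"
            )
        else:
            out[name] = col  # free-text extra column
    table = pd.DataFrame(out)
    if "frame" in table:
        table["frame"] = table["frame"].astype(int)
    if (table.get("photons", pd.Series(dtype=float)) <= 0).any():
        raise ValueError(f"{path.name}: photon counts must be positive")
    return table


def write_image(image, path) -> None:
    """Write an intensity grid as 32-bit float TIFF with pixel metadata."""
    from .render import SRImage

    if isinstance(image, SRImage):
        tifffile.imwrite(
            path,
            image.pixels.astype(np.float32),
            metadata={"pixel_nm": image.pixel_nm, "provenance": image.provenance},
        )
    else:
        tifffile.imwrite(path, np.asarray(image).astype(np.float32))


def write_stack(stack: np.ndarray, path) -> None:
    """Write a camera-frame stack as multi-page 16-bit unsigned TIFF."""
    tifffile.imwrite(path, np.clip(stack, 0, 65535).astype(np.uint16))


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)
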