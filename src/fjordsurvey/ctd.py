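"""Reading and summarising CTD casts.

The ROV carries a CTD with pH, oxygen and chlorophyll-fluorescence sensors
sampling continuously during each dive. This module parses the cast tables,
computes per-site range / mean +/- SD statistics over a depth window, and grids
records into simple site-by-depth-bin mean sections (a plain bin-average
replacement for contour plotting).

pH is taken as reported by the NBS-buffer-calibrated sensor; no scale
conversion is attempted. Missing values (e.g. a failed salinity cell) stay
missing end to end and are reported as absent, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, FormatError

__all__ = [
    "PARAMETERS",
    "SiteSummary",
    "read_ctd_table",
    "read_pangaea_table",
    "site_summary",
    "grid_section",
]

#: physico-chemical parameters carried through the pipeline
PARAMETERS = ["salinity", "temperature_C", "pH", "oxygen_umol_l", "fluorescence"]

MANDATORY = ["site", "depth_m"]


@dataclass
class SiteSummary:
    """Range and mean +/- SD of each parameter at one site over a depth window.

    ``stats`` maps parameter name -> dict(min, max, mean, sd, n); parameters
    with no non-missing records are absent from the mapping.
    """

    site: str
    depth_min_m: float
    depth_max_m: float
    n_records: int
    stats: Mapping[str, dict] = field(default_factory=dict)


def _standardise(df: pd.DataFrame, source: str) -> pd.DataFrame:
    for col in MANDATORY:
        if col not in df.columns:
            raise FormatError(f"CTD table {source} is missing mandatory column '{col}'")
    out = pd.DataFrame({"site": df["site"].astype(str)})
    if "transect" in df.columns:
        out["transect"] = df["transect"].astype(str)
    for col in ["depth_m"] + PARAMETERS:
        if col in df.columns:
            out[col] = pd.to_numeric(df[col], errors="coerce")
    if out["depth_m"].notna().any() and (out["depth_m"].dropna() < 0).any():
        raise DataError(f"negative depth in CTD table {source}")
    return out


def read_ctd_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited CTD table into the pipeline's column convention.

    ``column_map`` maps file column names to pipeline names (``site``,
    ``depth_m``, and any of :data:`PARAMETERS`, optionally ``transect``).
    Unparseable numeric cells (e.g. ``NA``) become missing values; row count
    and order are preserved.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    return _standardise(df, str(path))


def read_pangaea_table(path: str | Path, column_map: Mapping[str, str]) -> pd.DataFrame:
    """Read a tab-separated table in the PANGAEA text dialect.

    These exports open with a metadata block delimited by ``/*`` ... ``*/``
    followed by a tab-separated header line. ``column_map`` maps the file's
    header names onto the pipeline convention as in :func:`read_ctd_table`.
    """
    import io

    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines(keepends=True)
    start = 0
    if lines and lines[0].lstrip().startswith("/*"):
        for i, ln in enumerate(lines):
            if ln.rstrip().endswith("*/"):
                start = i + 1
                break
        else:
            raise FormatError(f"unterminated metadata block in {path}")
    df = pd.read_csv(io.StringIO("".join(lines[start:])), sep="\t", dtype=str, keep_default_na=False)
    df = df.rename(columns=dict(column_map))
    return _standardise(df, str(path))


def site_summary(
    records: pd.DataFrame,
    site: str,
    depth_range_m: tuple[float, float] | None = None,
    parameters: Sequence[str] = tuple(PARAMETERS),
) -> SiteSummary:
    """Per-site statistics over a depth window (range, mean, sample SD).

    SD uses the n-1 denominator. Parameters that are entirely missing for the
    site (e.g. a dead salinity sensor) are omitted from the result rather than
    reported as zero.
    """
    sel = records[records["site"] == site]
    if depth_range_m is not None:
        lo, hi = depth_range_m
        sel = sel[(sel["depth_m"] >= lo) & (sel["depth_m"] <= hi)]
    if sel.empty:
        raise DataError(f"no CTD records for site '{site}' in the requested depth range")
    stats: dict[str, dict] = {}
    for par in parameters:
        if par not in sel.columns:
            continue
        vals = sel[par].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        stats[par] = {
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n": int(vals.size),
        }
    return SiteSummary(
        site=site,
        depth_min_m=float(sel["depth_m"].min()),
        depth_max_m=float(sel["depth_m"].max()),
        n_records=int(len(sel)),
        stats=stats,
    )


def grid_section(
    records: pd.DataFrame,
    parameter: str,
    depth_bin_m: float = 10.0,
    site_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Bin-average one parameter into a site x depth-bin grid.

    Rows are sites (in ``site_order`` if given, else order of appearance),
    columns are bin centres; cells with no records are NaN.
    """
    if depth_bin_m <= 0:
        raise ConfigurationError(f"depth bin width must be > 0, got {depth_bin_m}")
    if records.empty or parameter not in records.columns:
        raise DataError(f"no records / no column '{parameter}' to grid")
    sites = list(site_order) if site_order is not None else list(dict.fromkeys(records["site"]))
    df = records[["site", "depth_m", parameter]].dropna(subset=["depth_m"]).copy()
    df["bin_centre"] = (np.floor(df["depth_m"] / depth_bin_m) + 0.5) * depth_bin_m
    grid = df.pivot_table(index="site", columns="bin_centre", values=parameter, aggfunc="mean")
    grid = grid.reindex(index=sites)
    grid = grid.reindex(columns=sorted(grid.columns))
    return grid
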