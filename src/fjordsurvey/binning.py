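"""Aggregation of frame-level quantities into per-site 10-m depth intervals.

Surfaces (area analysed, available substrate, coral cover) are summed within a
bin; coral patch size, abundance, shape and the CTD parameters are averaged —
matching how the study summarises each variable. Bins are half-open
``[10k, 10(k+1))`` labelled by their centre; bins with no frames are omitted.

Substrate usage per bin is the fraction of settleable rock colonised:
``% used = 100 * coral cover / available substrate`` computed from the summed
areas, guaranteeing a value in [0, 100].

Abundance defaults to the mean coral count per retained frame in the bin
(coral-free frames count as zero, preserving the zero-inflation of the raw
data); ``abundance_per="patch_frame"`` restricts the mean to patch-bearing
frames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ctd import PARAMETERS
from .errors import ConfigurationError, DataError

__all__ = ["join_ctd_to_frames", "bin_frames", "percent_used"]

CTD_MEAN_PARAMS = ["temperature_C", "salinity", "pH", "oxygen_umol_l"]


def join_ctd_to_frames(frames: pd.DataFrame, ctd: pd.DataFrame) -> pd.DataFrame:
    """Attach the nearest-depth CTD record (same site and, when available,
    same transect) to every frame."""
    out = frames.copy()
    for par in CTD_MEAN_PARAMS:
        out[par] = np.nan
    by_transect = "transect" in ctd.columns
    keys = ["site", "transect"] if by_transect else ["site"]
    groups = {k: g.sort_values("depth_m") for k, g in ctd.groupby(keys, sort=False)}
    for key, frame_idx in out.groupby(keys, sort=False).groups.items():
        g = groups.get(key)
        if g is None:
            continue
        depths = g["depth_m"].to_numpy(dtype=float)
        fdepths = out.loc[frame_idx, "ctd_depth_m"].to_numpy(dtype=float)
        pos = np.searchsorted(depths, fdepths)
        pos = np.clip(pos, 1, depths.size - 1) if depths.size > 1 else np.zeros_like(pos)
        left, right = depths[pos - 1], depths[np.minimum(pos, depths.size - 1)]
        nearest = np.where(np.abs(fdepths - left) <= np.abs(right - fdepths), pos - 1, pos)
        nearest = np.clip(nearest, 0, depths.size - 1)
        for par in CTD_MEAN_PARAMS:
            if par in g.columns:
                out.loc[frame_idx, par] = g[par].to_numpy(dtype=float)[nearest]
    return out


def percent_used(patch_size_m2: float, available_substrate_m2: float) -> float:
    """Fraction (in percent) of available substrate colonised by corals."""
    if available_substrate_m2 > 0:
        return 100.0 * patch_size_m2 / available_substrate_m2
    if patch_size_m2 > 0:
        raise DataError("coral cover reported on zero available substrate")
    return float("nan")  # 0/0: undefined, reported missing


def bin_frames(
    frames: pd.DataFrame,
    annotations: pd.DataFrame,
    ctd: pd.DataFrame | None = None,
    geoframes: pd.DataFrame | None = None,
    shapes: pd.DataFrame | None = None,
    bin_width_m: float = 10.0,
    abundance_per: str = "frame",
) -> pd.DataFrame:
    """Per site x depth-interval summary of surfaces, corals and environment.

    Parameters
    ----------
    frames, annotations
        Frame metadata and per-frame annotations (inner-joined on frame_id).
        When ``geoframes`` is given only retained frames enter the binning.
    ctd
        Optional cast records; their nearest-depth values are averaged per bin.
    shapes
        Optional measured-coral table with a ``shape`` column.
    bin_width_m
        Interval width (10 m in the study design).
    abundance_per
        ``"frame"`` (default) or ``"patch_frame"`` — the abundance denominator.
    """
    if bin_width_m <= 0:
        raise ConfigurationError(f"bin width must be > 0, got {bin_width_m}")
    if abundance_per not in ("frame", "patch_frame"):
        raise ConfigurationError(f"unknown abundance denominator '{abundance_per}'")

    df = frames.merge(annotations, on="frame_id", how="inner")
    if geoframes is not None:
        retained = set(geoframes.loc[geoframes["retained"], "frame_id"])
        df = df[df["frame_id"].isin(retained)]
    if df.empty:
        return pd.DataFrame()
    depths = df["ctd_depth_m"].to_numpy(dtype=float)
    if np.any(depths < 0) or np.any(~np.isfinite(depths)):
        raise DataError("frame depths must be finite and >= 0")

    if ctd is not None:
        df = join_ctd_to_frames(df, ctd)
    df = df.copy()
    df["bin_lower_m"] = np.floor(df["ctd_depth_m"] / bin_width_m) * bin_width_m

    if shapes is not None and not shapes.empty:
        frame_shape = shapes.groupby("frame_id")["shape"].mean()
        df["mean_shape"] = df["frame_id"].map(frame_shape)
        frame_nshape = shapes.groupby("frame_id")["shape"].size()
        df["n_shape"] = df["frame_id"].map(frame_nshape).fillna(0)
    else:
        df["mean_shape"] = np.nan
        df["n_shape"] = 0

    rows = []
    for (site, lower), g in df.groupby(["site", "bin_lower_m"], sort=True):
        total_available = float(g["available_substrate_m2"].sum())
        total_covered = float(g["coral_covered_m2"].sum())
        with_patch = g[g["coral_covered_m2"] > 0]
        if abundance_per == "frame":
            abundance = float(g["coral_count"].mean())
        else:
            abundance = float(with_patch["coral_count"].mean()) if not with_patch.empty else np.nan
        n_shapes = float(g["n_shape"].sum())
        shape_mean = (
            float((g["mean_shape"] * g["n_shape"]).sum() / n_shapes) if n_shapes > 0 else np.nan
        )
        row = {
            "site": site,
            "bin_lower_m": float(lower),
            "bin_upper_m": float(lower) + bin_width_m,
            "bin_centre_m": float(lower) + bin_width_m / 2.0,
            "n_frames": int(len(g)),
            "surface_analysed_m2": float(g["analysed_area_m2"].sum()),
            "available_substrate_m2": total_available,
            "coral_covered_m2": total_covered,
            "patch_size_m2": float(with_patch["coral_covered_m2"].mean())
            if not with_patch.empty else np.nan,
            "abundance": abundance,
            "shape_mean": shape_mean,
            "pct_used": percent_used(total_covered, total_available),
        }
        for par in CTD_MEAN_PARAMS:
            row[par] = float(g[par].mean()) if par in g.columns else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
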