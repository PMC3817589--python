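"""Coral and substrate quantities from retained frames and their annotations.

The unit of observation is the annotated video frame. A *patch* is the coral
aggregation within a single frame (frame-level granularity: disjoint clusters
inside one frame are still one patch). A *bank* is a patch run extending over
at least three consecutive retained frames of the same transect. *Coral shape*
is length divided by mid-length width of an individually measured coral;
corals counted but not measurable (oblique view, occlusion) contribute to
abundance only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

__all__ = [
    "read_annotations",
    "read_frames",
    "read_measured",
    "validate_annotations",
    "filter_to_retained",
    "collect_patches",
    "detect_banks",
    "shape_metrics",
]

ANNOTATION_COLUMNS = [
    "frame_id", "analysed_area_m2", "available_substrate_m2",
    "coral_covered_m2", "coral_count",
]
FRAME_COLUMNS = ["frame_id", "site", "transect", "timestamp_s", "echo_distance_m", "ctd_depth_m"]


def _read_table(path: str | Path, mandatory: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in mandatory:
        if col not in df.columns:
            raise FormatError(f"{path} is missing mandatory column '{col}'")
    for col in numeric:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_frames(path: str | Path) -> pd.DataFrame:
    return _read_table(path, ["frame_id", "site", "transect"],
                       ["timestamp_s", "echo_distance_m", "ctd_depth_m"])


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, ANNOTATION_COLUMNS, ANNOTATION_COLUMNS[1:])
    df["coral_count"] = df["coral_count"].fillna(0).astype(int)
    validate_annotations(df)
    return df


def read_measured(path: str | Path) -> pd.DataFrame:
    return _read_table(path, ["frame_id", "length_m", "width_m"], ["length_m", "width_m"])


def validate_annotations(annotations: pd.DataFrame) -> None:
    """Enforce area nesting and count/cover consistency per frame."""
    a = annotations
    bad = a[(a["coral_covered_m2"] > a["available_substrate_m2"] + 1e-9)
            | (a["available_substrate_m2"] > a["analysed_area_m2"] + 1e-9)]
    if not bad.empty:
        raise DataError(f"area nesting violated for frame(s) {bad['frame_id'].tolist()[:5]}")
    bad = a[(a["coral_count"] == 0) & (a["coral_covered_m2"] > 0)]
    if not bad.empty:
        raise DataError(f"coral cover without corals on frame(s) {bad['frame_id'].tolist()[:5]}")
    if (a["coral_count"] < 0).any():
        raise DataError("negative coral count")


def filter_to_retained(annotations: pd.DataFrame, geoframes: pd.DataFrame) -> pd.DataFrame:
    """Keep only annotations of frames that survived overlap exclusion."""
    retained = set(geoframes.loc[geoframes["retained"], "frame_id"])
    return annotations[annotations["frame_id"].isin(retained)].reset_index(drop=True)


def collect_patches(annotations: pd.DataFrame, geoframes: pd.DataFrame) -> pd.DataFrame:
    """One patch per retained, coral-bearing frame (area and count copied over).

    Annotations referencing excluded or unknown frames are an error: patches
    are only defined on the de-duplicated frame set.
    """
    retained = set(geoframes.loc[geoframes["retained"], "frame_id"])
    stray = set(annotations["frame_id"]) - retained
    if stray:
        raise DataError(
            f"annotation(s) reference excluded/unknown frame(s): {sorted(stray)[:5]}"
        )
    with_coral = annotations[annotations["coral_covered_m2"] > 0]
    patches = pd.DataFrame({
        "patch_id": [f"patch-{fid}" for fid in with_coral["frame_id"]],
        "frame_id": with_coral["frame_id"].to_numpy(),
        "area_m2": with_coral["coral_covered_m2"].to_numpy(dtype=float),
        "coral_count": with_coral["coral_count"].to_numpy(dtype=int),
    })
    return patches.reset_index(drop=True)


def detect_banks(patches: pd.DataFrame, geoframes: pd.DataFrame, min_run: int = 3) -> pd.DataFrame:
    """Maximal runs of >= ``min_run`` consecutive patch-bearing retained frames.

    Adjacency is consecutive position in acquisition order within a
    (site, transect) lane after overlap exclusion; a single coral-free frame
    breaks a run. Each retained frame belongs to at most one bank.
    """
    patch_frames = set(patches["frame_id"])
    banks = []
    bank_no = 0
    retained = geoframes[geoframes["retained"]]
    for (site, transect), lane in retained.groupby(["site", "transect"], sort=False):
        run: list[str] = []
        for fid in lane["frame_id"]:
            if fid in patch_frames:
                run.append(fid)
                continue
            if len(run) >= min_run:
                bank_no += 1
                banks.append((f"bank-{bank_no:03d}", site, transect, list(run), len(run)))
            run = []
        if len(run) >= min_run:
            bank_no += 1
            banks.append((f"bank-{bank_no:03d}", site, transect, list(run), len(run)))
    return pd.DataFrame(banks, columns=["bank_id", "site", "transect",
                                        "member_frame_ids", "n_frames"])


def shape_metrics(measured: pd.DataFrame) -> pd.DataFrame:
    """Length/width ratio per measured coral; raises on non-positive dimensions."""
    if measured.empty:
        return pd.DataFrame(columns=["frame_id", "length_m", "width_m", "shape"])
    bad = measured[(measured["length_m"] <= 0) | (measured["width_m"] <= 0)]
    if not bad.empty:
        raise DataError(
            f"non-positive coral dimension on frame(s) {bad['frame_id'].unique().tolist()[:5]}"
        )
    out = measured.copy()
    out["shape"] = out["length_m"] / out["width_m"]
    return out
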