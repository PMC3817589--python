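"""Photogrammetric scaling and placement of video-transect frames.

Each frame extracted from the ROV's forward-looking camera is scaled from the
echo-sounder range (camera-to-wall distance) under a pinhole model with the
optical axis perpendicular to the substrate: a frame at range *d* with
horizontal/vertical angles of view *h*, *v* covers

    width  = 2 d tan(h / 2),    height = 2 d tan(v / 2).

Frames are then placed in a synthetic fjord coordinate system — depth (positive
down) on the y axis, an arbitrary along-fjord x axis with one vertical "lane"
per (site, transect) — georeferenced via standard six-parameter ESRI
worldfiles, and de-duplicated by greedy exclusion of frames overlapping
already-retained ones in the same lane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .errors import DataError, FormatError, GeometryError

__all__ = [
    "CameraModel",
    "Worldfile",
    "frame_extent",
    "place_frames",
    "exclude_overlaps",
    "worldfile_for",
    "write_worldfile",
    "parse_worldfile",
    "write_worldfiles",
]

#: geoframe table columns produced by :func:`place_frames`
GEOFRAME_COLUMNS = [
    "frame_id", "site", "transect", "width_m", "height_m",
    "x_m", "y_m", "pixel_size_x_m", "pixel_size_y_m", "retained",
]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: angles of view in degrees and sensor pixel counts."""

    hfov_deg: float
    vfov_deg: float
    pixel_width: int = 1920
    pixel_height: int = 1080

    def __post_init__(self) -> None:
        for fov in (self.hfov_deg, self.vfov_deg):
            if not 0.0 < fov < 180.0:
                raise GeometryError(f"angle of view must be in (0, 180) deg, got {fov}")
        if self.pixel_width <= 0 or self.pixel_height <= 0:
            raise GeometryError("pixel counts must be positive")


@dataclass(frozen=True)
class Worldfile:
    """Six-parameter affine raster placement (ESRI .pgw order A, D, B, E, C, F)."""

    A: float  # pixel x-size (m)
    D: float  # row rotation (0: axis aligned)
    B: float  # column rotation (0: axis aligned)
    E: float  # negative pixel y-size (m), y-up map space
    C: float  # x of the centre of the upper-left pixel (m)
    F: float  # y of the centre of the upper-left pixel (m)


def frame_extent(distance_m: float, camera: CameraModel) -> tuple[float, float]:
    """Physical footprint (width_m, height_m) of a frame shot at ``distance_m``.

    Assumes the substrate plane is perpendicular to the optical axis, which the
    survey protocol enforces by adapting the vehicle pitch.
    """
    if distance_m <= 0:
        raise GeometryError(f"echo-sounder distance must be > 0, got {distance_m}")
    width = 2.0 * distance_m * math.tan(math.radians(camera.hfov_deg) / 2.0)
    height = 2.0 * distance_m * math.tan(math.radians(camera.vfov_deg) / 2.0)
    return width, height


def place_frames(
    frames: pd.DataFrame,
    camera: CameraModel,
    site_order: Sequence[str],
    lane_spacing_factor: float = 1.5,
) -> pd.DataFrame:
    """Scale and place frames into per-(site, transect) lanes.

    Parameters
    ----------
    frames
        Frame metadata with columns ``frame_id, site, transect,
        echo_distance_m, ctd_depth_m`` in acquisition order.
    camera
        Camera model used to scale every frame.
    site_order
        Site codes ordered along the fjord axis; lanes are laid out in this
        order, down transect before up, so transects sit next to each other
        without overlapping.
    lane_spacing_factor
        Lane pitch as a multiple of the widest frame (>1 guarantees lane
        disjointness).

    Returns
    -------
    DataFrame with :data:`GEOFRAME_COLUMNS`; ``y_m`` is the CTD depth
    (positive down) and ``retained`` is initialised True.
    """
    if frames.empty:
        return pd.DataFrame(columns=GEOFRAME_COLUMNS)
    unknown = set(frames["site"]) - set(site_order)
    if unknown:
        raise DataError(f"site code(s) not in site_order: {sorted(unknown)}")

    dist = frames["echo_distance_m"].to_numpy(dtype=float)
    if np.any(dist <= 0):
        raise GeometryError("echo-sounder distances must be > 0")
    half_h = math.tan(math.radians(camera.hfov_deg) / 2.0)
    half_v = math.tan(math.radians(camera.vfov_deg) / 2.0)
    width = 2.0 * dist * half_h
    height = 2.0 * dist * half_v

    lane_keys = [
        (site, transect)
        for site in site_order
        for transect in ("down", "up")
        if ((frames["site"] == site) & (frames["transect"] == transect)).any()
    ]
    spacing = lane_spacing_factor * float(width.max())
    lane_x = {key: (i + 0.5) * spacing for i, key in enumerate(lane_keys)}

    out = pd.DataFrame(
        {
            "frame_id": frames["frame_id"].to_numpy(),
            "site": frames["site"].to_numpy(),
            "transect": frames["transect"].to_numpy(),
            "width_m": width,
            "height_m": height,
            "x_m": [lane_x[(s, t)] for s, t in zip(frames["site"], frames["transect"])],
            "y_m": frames["ctd_depth_m"].to_numpy(dtype=float),
            "pixel_size_x_m": width / camera.pixel_width,
            "pixel_size_y_m": height / camera.pixel_height,
            "retained": True,
        }
    )
    if np.any(out["y_m"].to_numpy() < 0):
        raise DataError("frame CTD depth must be >= 0")
    return out


def _rect(row) -> Polygon:
    return box(
        row.x_m - row.width_m / 2.0,
        row.y_m - row.height_m / 2.0,
        row.x_m + row.width_m / 2.0,
        row.y_m + row.height_m / 2.0,
    )


def exclude_overlaps(geoframes: pd.DataFrame, overlap_tolerance_m2: float = 0.0) -> pd.DataFrame:
    """Greedy in-order retention of non-overlapping frames within each lane.

    Frames are visited in acquisition (row) order; a frame is retained iff the
    intersection area of its rectangle with the union of previously retained
    rectangles in the same (site, transect) lane is at most
    ``overlap_tolerance_m2``. Returns a copy with the ``retained`` flag set.
    """
    geo = geoframes.copy()
    retained = np.ones(len(geo), dtype=bool)
    for _, lane_idx in geo.groupby(["site", "transect"], sort=False).groups.items():
        union: Polygon | None = None
        for i in lane_idx:
            rect = _rect(geo.loc[i])
            if union is not None and rect.intersection(union).area > overlap_tolerance_m2:
                retained[geo.index.get_loc(i)] = False
            else:
                union = rect if union is None else union.union(rect)
    geo["retained"] = retained
    return geo


def _fmt(value: float) -> str:
    # fixed (non-scientific) notation, 17 significant digits (enough to
    # round-trip a double exactly); plain "0.0" for zeros
    if value == 0.0:
        return "0.0"
    return np.format_float_positional(value, precision=17, unique=False, fractional=False, trim="k")


def worldfile_for(geo_row) -> Worldfile:
    """Worldfile parameters for one placed frame.

    Map space is y-up (worldfile convention), so the frame centre (x, depth)
    maps to (x, -depth) and the pixel y-size E is negative. C/F address the
    *centre* of the upper-left pixel.
    """
    A = geo_row.pixel_size_x_m
    E = -geo_row.pixel_size_y_m
    if A <= 0 or E >= 0:
        raise GeometryError("pixel sizes must be positive (zero pixel counts?)")
    C = geo_row.x_m - geo_row.width_m / 2.0 + A / 2.0
    F = -geo_row.y_m + geo_row.height_m / 2.0 + E / 2.0
    return Worldfile(A=A, D=0.0, B=0.0, E=E, C=C, F=F)


def write_worldfile(geo_row) -> str:
    """Render a placed frame's worldfile as the standard six-line text."""
    wf = worldfile_for(geo_row)
    return "\n".join(_fmt(v) for v in (wf.A, wf.D, wf.B, wf.E, wf.C, wf.F)) + "\n"


def parse_worldfile(text: str) -> Worldfile:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if len(lines) != 6:
        raise FormatError(f"worldfile must have exactly 6 lines, got {len(lines)}")
    return Worldfile(*(float(ln) for ln in lines))


def write_worldfiles(geoframes: pd.DataFrame, out_dir: str | Path, retained_only: bool = True) -> list[Path]:
    """Write one ``<frame_id>.pgw`` sidecar per (retained) frame; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    rows = geoframes[geoframes["retained"]] if retained_only else geoframes
    for row in rows.itertuples(index=False):
        path = out_dir / f"{row.frame_id}.pgw"
        path.write_text(write_worldfile(row), encoding="utf-8")
        paths.append(path)
    return paths
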