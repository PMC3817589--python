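"""Seeded synthetic fjord surveys with known ground truth.

Emulates the structure of an ROV video-transect study of the cold-water coral
*Desmophyllum dianthus* in a stratified Patagonian fjord: seven sites along the
fjord axis, a down and an up vertical transect per site, frames captured on a
regular cadence, a co-registered CTD stream, a four-layer water column (brackish
surface layer, subsurface pH/oxygen dip, intermediate oceanic water, deep basin
water with the lowest pH and oxygen), and a configurable step drop in coral
abundance below a break depth (default 275 m, the middle of the 270-280 m band
where the field pattern changes).

The generator is the test bed for every downstream stage: its ground truth
records the true break depth and the exact per-depth-bin expected abundance so
that recovery can be checked statistically.

Abundance model
---------------
The expected number of corals in a frame is ``density x available_substrate``
where density (individuals per m^2 of settleable rock) is constant above the
break and divided by ``abundance_drop_factor`` below it. Counts are drawn from
a zero-inflated negative binomial: a frame holds corals with probability
``occupancy_mean``, and occupied frames draw an overdispersed count whose mean
is inflated by ``1/occupancy_mean`` so the unconditional expectation is
unchanged. Field aggregation is patchy, which motivates both the
overdispersion and the zero inflation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ctd import PARAMETERS
from .errors import ConfigurationError
from .georef import CameraModel

__all__ = [
    "FjordConfig",
    "WaterMassPreset",
    "SurveyDataset",
    "default_presets",
    "generate_ctd_casts",
    "generate_survey",
    "write_survey",
]

# Table-of-sites defaults: seven stations from fjord mouth to head with their
# maximum dive depths (m).
DEFAULT_SITES = ("LL", "CL", "NT", "SW", "CH", "PG", "RB")
DEFAULT_MAX_DEPTHS = (198.0, 115.0, 422.0, 209.0, 282.0, 355.0, 216.0)

DEFAULT_NOISE_SD = {
    "salinity": 0.15,
    "temperature_C": 0.10,
    "pH": 0.02,
    "oxygen_umol_l": 3.0,
    "fluorescence": 0.05,
}


@dataclass(frozen=True)
class WaterMassPreset:
    """One layer of the water column: base values at the layer top + linear
    within-layer gradients (per metre of depth)."""

    layer_id: int
    depth_top_m: float
    depth_bottom_m: float
    values: Mapping[str, float]
    gradients: Mapping[str, float] = field(default_factory=dict)

    def value_at(self, parameter: str, depth_m) -> np.ndarray:
        base = self.values[parameter]
        grad = self.gradients.get(parameter, 0.0)
        return base + grad * (np.asarray(depth_m, dtype=float) - self.depth_top_m)


def default_presets(max_depth_m: float = 480.0) -> list[WaterMassPreset]:
    """Four layers tiling [0, max_depth_m].

    Layer 1: brackish low-salinity surface layer (upper 7 m), warm, high pH and
    oxygen. Layer 4: subsurface dip in pH and oxygen below the halocline.
    Layer 2: intermediate oceanic water, near-uniform. Layer 3: deep basin
    water below 300 m with the highest salinity and the lowest pH and oxygen
    (minima near pH 7.71 and 91 umol/l oxygen at the bottom).
    """
    return [
        WaterMassPreset(
            layer_id=1, depth_top_m=0.0, depth_bottom_m=7.0,
            values={"salinity": 20.0, "temperature_C": 16.0, "pH": 8.35,
                    "oxygen_umol_l": 270.0, "fluorescence": 2.0},
            gradients={"salinity": 1.5, "temperature_C": -0.5, "oxygen_umol_l": 1.0},
        ),
        WaterMassPreset(
            layer_id=4, depth_top_m=7.0, depth_bottom_m=25.0,
            values={"salinity": 31.2, "temperature_C": 12.5, "pH": 8.25,
                    "oxygen_umol_l": 250.0, "fluorescence": 1.0},
            gradients={"salinity": 0.05, "temperature_C": -0.08, "pH": -0.017,
                       "oxygen_umol_l": -4.5, "fluorescence": -0.05},
        ),
        WaterMassPreset(
            layer_id=2, depth_top_m=25.0, depth_bottom_m=300.0,
            values={"salinity": 32.2, "temperature_C": 11.0, "pH": 7.92,
                    "oxygen_umol_l": 165.0, "fluorescence": 0.1},
            gradients={"salinity": 0.002, "temperature_C": -0.002,
                       "pH": -0.0003, "oxygen_umol_l": -0.06},
        ),
        WaterMassPreset(
            layer_id=3, depth_top_m=300.0, depth_bottom_m=max(max_depth_m, 300.0) + 1.0,
            values={"salinity": 32.8, "temperature_C": 10.4, "pH": 7.77,
                    "oxygen_umol_l": 108.0, "fluorescence": 0.05},
            gradients={"temperature_C": 0.001, "pH": -0.00033, "oxygen_umol_l": -0.09},
        ),
    ]


@dataclass(frozen=True)
class FjordConfig:
    """All knobs of the synthetic survey; defaults mirror the study design."""

    n_sites: int = 7
    site_codes: Sequence[str] = DEFAULT_SITES
    max_depths_m: Sequence[float] = DEFAULT_MAX_DEPTHS
    site_spacing_km: float = 6.5
    halocline_depth_m: float = 7.0
    break_depth_m: float = 275.0
    abundance_drop_factor: float = 5.0
    coral_density_per_m2: float = 100.0   # ind. per m^2 available substrate, above break
    dispersion: float = 2.0               # negative-binomial size (smaller = patchier)
    frames_per_metre: float = 1.0
    echo_distance_mean_m: float = 1.0
    echo_distance_sd_m: float = 0.2
    substrate_fraction_mean: float = 0.3
    substrate_fraction_conc: float = 0.35  # beta concentration; <1 gives rock-or-sediment bimodality
    substrate_patch_scale_m: float = 10.0  # vertical scale of rock/sediment patchiness
    occupancy_mean: float = 0.6           # probability a frame holds any corals
    coral_footprint_m2: float = 0.002     # planar area of one individual
    measurable_fraction: float = 0.3      # corals usable for length/width measurement
    length_log_mean: float = math.log(0.06)
    length_log_sd: float = 0.4
    shape_log_mean: float = math.log(3.0)  # length/width ratio, lognormal
    shape_log_sd: float = 0.5
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    salinity_na_sites: Sequence[str] = ()  # sites whose salinity is blanked (sensor failure)
    seed: int = 0

    def __post_init__(self):
        codes = tuple(self.site_codes)[: self.n_sites]
        depths = tuple(self.max_depths_m)[: self.n_sites]
        if len(codes) < self.n_sites:
            codes = codes + tuple(f"S{i+1}" for i in range(len(codes), self.n_sites))
        if len(depths) < self.n_sites:
            depths = depths + tuple(
                DEFAULT_MAX_DEPTHS[i % len(DEFAULT_MAX_DEPTHS)]
                for i in range(len(depths), self.n_sites)
            )
        object.__setattr__(self, "site_codes", codes)
        object.__setattr__(self, "max_depths_m", depths)
        self.validate()

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.break_depth_m <= self.halocline_depth_m:
            raise ConfigurationError("break_depth_m must exceed halocline_depth_m")
        if self.abundance_drop_factor < 1.0:
            raise ConfigurationError("abundance_drop_factor must be >= 1")
        if self.echo_distance_mean_m <= 0:
            raise ConfigurationError("echo_distance_mean_m must be > 0")
        for name in ("substrate_fraction_mean", "occupancy_mean", "measurable_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.frames_per_metre <= 0:
            raise ConfigurationError("frames_per_metre must be > 0")


@dataclass
class SurveyDataset:
    """A complete synthetic survey plus the truth it was drawn from."""

    frames: pd.DataFrame       # frame_id, site, transect, timestamp_s, echo_distance_m, ctd_depth_m
    annotations: pd.DataFrame  # frame_id, analysed/available/covered areas, coral_count
    measured: pd.DataFrame     # frame_id, length_m, width_m
    ctd: pd.DataFrame          # site, transect, depth_m, parameters
    ground_truth: dict


def _check_presets(presets: Sequence[WaterMassPreset], max_depth: float) -> list[WaterMassPreset]:
    layers = sorted(presets, key=lambda p: p.depth_top_m)
    if not layers or layers[0].depth_top_m > 0:
        raise ConfigurationError("presets must start at the surface (depth 0)")
    for upper, lower in zip(layers, layers[1:]):
        if not math.isclose(upper.depth_bottom_m, lower.depth_top_m):
            raise ConfigurationError(
                f"presets gap/overlap between {upper.depth_bottom_m} and {lower.depth_top_m} m"
            )
    if layers[-1].depth_bottom_m < max_depth:
        raise ConfigurationError(
            f"presets end at {layers[-1].depth_bottom_m} m but casts reach {max_depth} m"
        )
    return layers


def _profile(layers: Sequence[WaterMassPreset], depths: np.ndarray) -> dict[str, np.ndarray]:
    """Noise-free parameter profiles at the given depths (piecewise by layer)."""
    out = {p: np.empty_like(depths, dtype=float) for p in PARAMETERS}
    for layer in layers:
        # half-open [top, bottom); deepest layer also owns its bottom edge
        mask = (depths >= layer.depth_top_m) & (depths < layer.depth_bottom_m)
        if layer is layers[-1]:
            mask |= depths >= layer.depth_bottom_m
        for p in PARAMETERS:
            out[p][mask] = layer.value_at(p, depths[mask])
    return out


def generate_ctd_casts(
    config: FjordConfig,
    presets: Sequence[WaterMassPreset] | None = None,
    transects: Sequence[str] = ("down",),
    records_per_metre: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One CTD record stream per site and transect at >= 1 record per metre.

    Values are the layer preset mean plus Gaussian noise with per-parameter SD
    ``config.noise_sd``; depth is monotone non-decreasing within a down-cast
    (non-increasing within an up-cast).
    """
    layers = _check_presets(presets or default_presets(max(config.max_depths_m)),
                            max(config.max_depths_m))
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    step = 1.0 / max(records_per_metre, 1.0)
    rows = []
    for site, max_depth in zip(config.site_codes, config.max_depths_m):
        depths = np.arange(0.5, max_depth, step)
        for transect in transects:
            d = depths if transect == "down" else depths[::-1]
            prof = _profile(layers, d)
            rec = {"site": site, "transect": transect, "depth_m": d}
            for p in PARAMETERS:
                sd = config.noise_sd.get(p, 0.0)
                noise = rng.normal(0.0, sd, size=d.size) if sd > 0 else 0.0
                rec[p] = prof[p] + noise
            df = pd.DataFrame(rec)
            if site in config.salinity_na_sites:
                df["salinity"] = np.nan
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


def _truncated_normal(rng, mean, sd, size):
    vals = rng.normal(mean, sd, size=size)
    while np.any(vals <= 0):
        bad = vals <= 0
        vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return vals


def expected_frame_area_m2(config: FjordConfig, camera: CameraModel) -> float:
    """E[frame footprint] under the truncated-normal echo-distance model.

    Truncation at zero is negligible for the default mean/SD, so E[d^2] is
    taken as mean^2 + sd^2.
    """
    tan_h = math.tan(math.radians(camera.hfov_deg) / 2.0)
    tan_v = math.tan(math.radians(camera.vfov_deg) / 2.0)
    e_d2 = config.echo_distance_mean_m ** 2 + config.echo_distance_sd_m ** 2
    return 4.0 * tan_h * tan_v * e_d2


def generate_survey(
    config: FjordConfig,
    presets: Sequence[WaterMassPreset] | None = None,
    camera: CameraModel | None = None,
) -> SurveyDataset:
    """Draw a complete survey: frames, annotations, measured corals, CTD, truth.

    Frames are laid on a regular depth grid (``frames_per_metre``) from just
    below the surface to each site's maximum depth, once descending and once
    ascending; the ascending transect revisits the same depths (it is placed in
    its own lane downstream). The 10-s frame cadence maps to the depth grid via
    an assumed constant winch speed, recorded in ``timestamp_s``.
    """
    config.validate()
    camera = camera or CameraModel(hfov_deg=60.0, vfov_deg=40.0)
    rng = np.random.default_rng(config.seed)
    ctd = generate_ctd_casts(config, presets, transects=("down", "up"), rng=rng)

    step = 1.0 / config.frames_per_metre
    frame_rows, ann_rows, meas_rows = [], [], []
    tan_h = math.tan(math.radians(camera.hfov_deg) / 2.0)
    tan_v = math.tan(math.radians(camera.vfov_deg) / 2.0)

    for site, max_depth in zip(config.site_codes, config.max_depths_m):
        depths_down = np.arange(max(1.0, config.halocline_depth_m), max_depth, step)
        # rock/sediment patchiness lives at a larger-than-frame vertical scale:
        # one substrate fraction per depth cell, shared by both transects, so
        # available substrate is decoupled from the frame footprint
        n_cells = int(max_depth // config.substrate_patch_scale_m) + 1
        cell_frac = rng.beta(
            config.substrate_fraction_mean * config.substrate_fraction_conc,
            (1.0 - config.substrate_fraction_mean) * config.substrate_fraction_conc,
            size=n_cells,
        )
        for transect, depths in (("down", depths_down), ("up", depths_down[::-1])):
            n = depths.size
            dist = _truncated_normal(rng, config.echo_distance_mean_m,
                                     config.echo_distance_sd_m, n)
            width = 2.0 * dist * tan_h
            height = 2.0 * dist * tan_v
            analysed = width * height
            frac = cell_frac[(depths // config.substrate_patch_scale_m).astype(int)]
            available = frac * analysed
            density = np.where(
                depths < config.break_depth_m,
                config.coral_density_per_m2,
                config.coral_density_per_m2 / config.abundance_drop_factor,
            )
            mean_count = density * available
            occupied = rng.random(n) < config.occupancy_mean
            counts = np.zeros(n, dtype=int)
            if occupied.any():
                mu = mean_count[occupied] / config.occupancy_mean
                k = config.dispersion
                counts[occupied] = rng.negative_binomial(k, k / (k + mu))
            cover_noise = rng.lognormal(0.0, 0.3, size=n)
            covered = np.minimum(available, counts * config.coral_footprint_m2 * cover_noise)
            covered[counts == 0] = 0.0

            ids = [f"{site}-{transect}-{i:04d}" for i in range(n)]
            frame_rows.append(pd.DataFrame({
                "frame_id": ids, "site": site, "transect": transect,
                "timestamp_s": 10.0 * np.arange(n),
                "echo_distance_m": dist, "ctd_depth_m": depths,
            }))
            ann_rows.append(pd.DataFrame({
                "frame_id": ids, "analysed_area_m2": analysed,
                "available_substrate_m2": available,
                "coral_covered_m2": covered, "coral_count": counts,
            }))
            # measurable individuals: a binomial subset, capped to keep tables small
            n_meas = rng.binomial(np.minimum(counts, 30), config.measurable_fraction)
            for fid, m in zip(ids, n_meas):
                if m == 0:
                    continue
                length = rng.lognormal(config.length_log_mean, config.length_log_sd, size=m)
                shape = rng.lognormal(config.shape_log_mean, config.shape_log_sd, size=m)
                meas_rows.append(pd.DataFrame({
                    "frame_id": fid, "length_m": length, "width_m": length / shape,
                }))

    frames = pd.concat(frame_rows, ignore_index=True)
    annotations = pd.concat(ann_rows, ignore_index=True)
    measured = (pd.concat(meas_rows, ignore_index=True)
                if meas_rows else pd.DataFrame(columns=["frame_id", "length_m", "width_m"]))

    ground_truth = _ground_truth(config, camera, frames)
    return SurveyDataset(frames=frames, annotations=annotations, measured=measured,
                         ctd=ctd, ground_truth=ground_truth)


def _ground_truth(config: FjordConfig, camera: CameraModel, frames: pd.DataFrame) -> dict:
    """Exact expected per-10-m-bin abundance given the deterministic depth grid."""
    e_avail = expected_frame_area_m2(config, camera) * config.substrate_fraction_mean
    depths = frames["ctd_depth_m"].to_numpy()
    density = np.where(depths < config.break_depth_m,
                       config.coral_density_per_m2,
                       config.coral_density_per_m2 / config.abundance_drop_factor)
    expected = pd.Series(density * e_avail).groupby(np.floor(depths / 10.0) * 10.0 + 5.0).mean()
    return {
        "seed": config.seed,
        "break_depth_m": config.break_depth_m,
        "abundance_drop_factor": config.abundance_drop_factor,
        "density_above_per_m2": config.coral_density_per_m2,
        "density_below_per_m2": config.coral_density_per_m2 / config.abundance_drop_factor,
        "expected_available_per_frame_m2": e_avail,
        "expected_abundance_per_bin": {f"{c:.1f}": float(v) for c, v in expected.items()},
    }


def write_survey(dataset: SurveyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write ctd.csv, frames.csv, annotations.csv, measured.csv and the
    ground_truth.json sidecar (UTF-8, one header line each)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ctd": out / "ctd.csv",
        "frames": out / "frames.csv",
        "annotations": out / "annotations.csv",
        "measured": out / "measured.csv",
        "ground_truth": out / "ground_truth.json",
    }
    dataset.ctd.to_csv(paths["ctd"], index=False)
    dataset.frames.to_csv(paths["frames"], index=False)
    dataset.annotations.to_csv(paths["annotations"], index=False)
    dataset.measured.to_csv(paths["measured"], index=False)
    paths["ground_truth"].write_text(
        json.dumps(dataset.ground_truth, indent=2, sort_keys=True), encoding="utf-8"
    )
    return paths
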