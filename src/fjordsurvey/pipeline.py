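"""One-shot orchestration: simulate -> georef -> quantify -> bin -> test/regress.

A run is fully determined by its :class:`RunConfig` (a flat key-value mapping,
loadable from YAML): re-running with the same config and seed reproduces every
output byte for byte. Each stage writes its table into the run directory and
the statistical results land in ``stats.json`` plus a human-readable
``report.txt``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from . import binning, georef, quantify, stats, synthetic
from .errors import FjordSurveyError

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("fjordsurvey")

RESPONSES = ("abundance", "pct_used")
PREDICTORS = ("pH", "oxygen_umol_l", "temperature_C", "salinity", "available_substrate_m2")


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run; defaults mirror the study
    design (7 sites, 10-m bins, break band 270-280 m, B = 10,000)."""

    out_dir: str = "run"
    seed: int = 0
    # synthetic survey
    n_sites: int = 7
    break_depth_m: float = 275.0
    abundance_drop_factor: float = 5.0
    occupancy_mean: float = 0.6
    substrate_fraction_mean: float = 0.5
    frames_per_metre: float = 1.0
    echo_distance_mean_m: float = 1.0
    echo_distance_sd_m: float = 0.2
    salinity_na_sites: Sequence[str] = ()
    # camera
    hfov_deg: float = 60.0
    vfov_deg: float = 40.0
    pixel_width: int = 1920
    pixel_height: int = 1080
    # analysis
    bin_width_m: float = 10.0
    B: int = 10_000
    exclude_surface: bool = False
    halocline_depth_m: float = 10.0
    abundance_per: str = "frame"
    overlap_tolerance_m2: float = 0.0
    write_worldfiles: bool = False

    def fjord_config(self) -> synthetic.FjordConfig:
        return synthetic.FjordConfig(
            n_sites=self.n_sites,
            break_depth_m=self.break_depth_m,
            abundance_drop_factor=self.abundance_drop_factor,
            occupancy_mean=self.occupancy_mean,
            substrate_fraction_mean=self.substrate_fraction_mean,
            frames_per_metre=self.frames_per_metre,
            echo_distance_mean_m=self.echo_distance_mean_m,
            echo_distance_sd_m=self.echo_distance_sd_m,
            salinity_na_sites=tuple(self.salinity_na_sites),
            seed=self.seed,
        )

    def camera(self) -> georef.CameraModel:
        return georef.CameraModel(self.hfov_deg, self.vfov_deg,
                                  self.pixel_width, self.pixel_height)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a flat YAML mapping; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FjordSurveyError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the stats dict also written to stats.json."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    camera = config.camera()
    fjord = config.fjord_config()

    log.info("stage simulate: seed=%d, %d sites", config.seed, fjord.n_sites)
    dataset = synthetic.generate_survey(fjord, camera=camera)
    synthetic.write_survey(dataset, out)

    log.info("stage georef: %d frames", len(dataset.frames))
    geo = georef.place_frames(dataset.frames, camera, list(fjord.site_codes))
    geo = georef.exclude_overlaps(geo, config.overlap_tolerance_m2)
    geo.to_csv(out / "geoframes.csv", index=False)
    if config.write_worldfiles:
        georef.write_worldfiles(geo, out / "worldfiles")
    log.info("stage georef: retained %d / %d frames", int(geo["retained"].sum()), len(geo))

    log.info("stage quantify")
    annotations = quantify.filter_to_retained(dataset.annotations, geo)
    patches = quantify.collect_patches(annotations, geo)
    banks = quantify.detect_banks(patches, geo)
    shapes = quantify.shape_metrics(
        dataset.measured[dataset.measured["frame_id"].isin(annotations["frame_id"])]
        .reset_index(drop=True)
    )
    patches.to_csv(out / "patches.csv", index=False)
    banks.assign(member_frame_ids=banks["member_frame_ids"].map(";".join)).to_csv(
        out / "banks.csv", index=False)
    shapes.to_csv(out / "shapes.csv", index=False)

    log.info("stage bin: width %.0f m", config.bin_width_m)
    bins = binning.bin_frames(
        dataset.frames, annotations, ctd=dataset.ctd, geoframes=geo, shapes=shapes,
        bin_width_m=config.bin_width_m, abundance_per=config.abundance_per,
    )
    bins.to_csv(out / "bins.csv", index=False)

    log.info("stage stats: break %.0f m, B=%d", config.break_depth_m, config.B)
    break_result = stats.test_break(
        bins, break_depth_m=config.break_depth_m, B=config.B, seed=config.seed,
    )
    regressions = []
    for response in RESPONSES:
        for predictor in PREDICTORS:
            for exclude in (False, True):
                try:
                    r = stats.regress(bins, response, predictor,
                                      exclude_surface=exclude,
                                      halocline_depth_m=config.halocline_depth_m)
                except FjordSurveyError as err:
                    log.warning("regression %s ~ %s skipped: %s", response, predictor, err)
                    continue
                regressions.append({
                    "response": r.response, "predictor": predictor,
                    "adjusted_r2": r.adjusted_r2, "r2": r.r2,
                    "slope": r.slopes[predictor], "n": r.n,
                    "surface_excluded": r.surface_excluded,
                })

    result = {
        "config": {f.name: (list(v) if isinstance(v := getattr(config, f.name), tuple) else v)
                   for f in dataclasses.fields(config)},
        "n_frames": int(len(dataset.frames)),
        "n_retained": int(geo["retained"].sum()),
        "n_patches": int(len(patches)),
        "n_banks": int(len(banks)),
        "break_test": dataclasses.asdict(break_result),
        "regressions": regressions,
    }
    result = _round_floats(result)
    (out / "stats.json").write_text(
        json.dumps(result, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    (out / "report.txt").write_text(_report(result), encoding="utf-8")
    return result


def _report(result: dict) -> str:
    bt = result["break_test"]
    lines = [
        "fjordsurvey pipeline report",
        "===========================",
        f"frames: {result['n_frames']} total, {result['n_retained']} retained after overlap exclusion",
        f"patches: {result['n_patches']}, banks (>=3 consecutive frames): {result['n_banks']}",
        "",
        f"abundance above vs below {bt['break_depth_m']:.0f} m "
        f"(n = {bt['n_above']} / {bt['n_below']} bins):",
        f"  mean difference        {bt['statistic']:.3f} corals per frame",
        f"  Wilcoxon rank-sum      W = {bt['wilcoxon_W']:.1f}, p = {bt['wilcoxon_p']:.3g} "
        f"({bt['wilcoxon_method']})",
        f"  permutation (B={bt['B']})  p = {bt['perm_p']:.3g}",
        "",
        "regressions (adjusted r^2):",
    ]
    for r in result["regressions"]:
        tag = "excl. surface" if r["surface_excluded"] else "whole column "
        lines.append(
            f"  {r['response']:<10} ~ {r['predictor']:<24} {tag}  "
            f"adj r2 = {r['adjusted_r2']: .3f}  (n = {r['n']})"
        )
    return "\n".join(lines) + "\n"
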