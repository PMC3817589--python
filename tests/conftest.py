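import numpy as np
import pandas as pd
import pytest

import fjordsurvey as fs


@pytest.fixture(scope="session")
def camera():
    return fs.CameraModel(hfov_deg=60.0, vfov_deg=40.0, pixel_width=1920, pixel_height=1080)


@pytest.fixture(scope="session")
def small_config():
    """Two-site survey, one site reaching below the 275 m break."""
    return fs.FjordConfig(
        n_sites=2, site_codes=("A", "B"), max_depths_m=(120.0, 360.0),
        frames_per_metre=0.5, seed=20260930,
    )


@pytest.fixture(scope="session")
def survey(small_config):
    return fs.generate_survey(small_config)


@pytest.fixture(scope="session")
def geoframes(survey, small_config, camera):
    geo = fs.place_frames(survey.frames, camera, list(small_config.site_codes))
    return fs.exclude_overlaps(geo)


def make_frames(depths, site="A", transect="down", echo=1.0):
    """Minimal frame-metadata table at the given depths."""
    depths = np.asarray(depths, dtype=float)
    return pd.DataFrame({
        "frame_id": [f"{site}-{transect}-{i:04d}" for i in range(depths.size)],
        "site": site,
        "transect": transect,
        "timestamp_s": 10.0 * np.arange(depths.size),
        "echo_distance_m": echo,
        "ctd_depth_m": depths,
    })


def make_annotations(frame_ids, analysed=1.0, available=0.5, covered=0.0, count=0):
    n = len(frame_ids)
    return pd.DataFrame({
        "frame_id": list(frame_ids),
        "analysed_area_m2": np.broadcast_to(analysed, n).astype(float),
        "available_substrate_m2": np.broadcast_to(available, n).astype(float),
        "coral_covered_m2": np.broadcast_to(covered, n).astype(float),
        "coral_count": np.broadcast_to(count, n).astype(int),
    })
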