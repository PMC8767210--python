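"""Shared fixtures: small simulated cohorts and processed deployments.

Everything is generated programmatically and seeded; the heavier
artifacts are session-scoped so the cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirounga import dive_processing as dp
from mirounga import synthetic_data as sd
from mirounga import track_processing as tp


@pytest.fixture(scope="session")
def small_cohort():
    cfg = sd.scaled_config(
        seed=7, trip_days=8.0, n_per_strategy={"male": 2, "female_pb": 2, "female_pm": 1}
    )
    return sd.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def processed(small_cohort):
    """Filtered/smoothed tracks and classified dives for every deployment."""
    cfg = small_cohort.config
    colony = (cfg.geometry.colony_lat, cfg.geometry.colony_lon)
    hourly = {}
    dives = {}
    for dep in small_cohort.deployments:
        fx = small_cohort.fixes[small_cohort.fixes["deployment_id"] == dep.deployment_id]
        clean = tp.sda_filter(fx)
        h = tp.smooth_track(clean, colony=colony)
        hourly[dep.deployment_id] = h
        dives[dep.deployment_id] = dp.process_deployment(
            small_cohort.dive_series[dep.deployment_id],
            hourly=h,
            seafloor_fn=cfg.geometry.seafloor_depth_m,
        )
    return {"hourly": hourly, "dives": dives, "cohort": small_cohort}


def make_series(depths, dt=8.0):
    """Depth samples -> the DataFrame shape the dive pipeline expects."""
    depths = np.asarray(depths, dtype=float)
    return pd.DataFrame({"time_s": np.arange(len(depths)) * dt, "depth_m": depths})
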