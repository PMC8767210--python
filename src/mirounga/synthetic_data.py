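"""Seeded simulation of elephant-seal biologging cohorts.

Every analysis stage in this package is exercised on data produced here:
ARGOS-style position fixes with class-dependent error, time-depth-recorder
series built from four dive archetypes (transit V-dives, pelagic foraging
dives with bottom wiggles and diel depth modulation, benthic flat-bottom
dives tracking a synthetic seafloor, drift dives with a slow monotonic
segment), departure/arrival body-composition records, a tag-fate cohort
with transmission-quality and resight histories, and a simple vector
geography (colony, straight shelf isobath, rectangular ecoregions).

Ground truth (true paths, true dive types, true behavioural states, true
mass gains, true fates) is retained alongside the observables so that the
processing stages can be tested as closed loops.

Movement is a two-state (directed transit / area-restricted search)
correlated walk in a local planar projection about the colony; the
2 km h-1 foraging-speed rule used downstream is meaningful because ARS
hours are slow and transit hours are fast by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .geometry import AzimuthalEquidistant, solar_zenith_deg

ARGOS_CLASSES = ["3", "2", "1", "0", "A", "B"]

#: Standard telemetry-practice positional error s.d. per ARGOS class, km.
DEFAULT_ARGOS_ERROR_SD_KM = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 4.0, "A": 6.0, "B": 10.0}

DEFAULT_CLASS_WEIGHTS = {"3": 0.10, "2": 0.15, "1": 0.20, "0": 0.15, "A": 0.20, "B": 0.20}

DIVE_TYPES = ["transit", "pelagic_foraging", "benthic_foraging", "drift"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class DiveArchetypeSpec:
    """Parameters of one dive archetype.

    Depths in m, durations in min; ``wiggle_count_sd = 0`` yields exactly
    ``wiggle_count_mean`` bottom excursions per dive.
    """

    depth_mean_m: float
    depth_sd_m: float
    duration_mean_min: float
    duration_sd_min: float
    bottom_fraction: float
    wiggle_count_mean: float = 0.0
    wiggle_count_sd: float = 0.0
    wiggle_amplitude_m: float = 8.0
    diel_depth_offset_m: float = 0.0
    drift_rate_m_s: float = 0.12
    drift_fraction: float = 0.5


def _default_archetypes() -> dict:
    return {
        "transit": DiveArchetypeSpec(350.0, 80.0, 12.0, 2.0, 0.0),
        "pelagic_foraging": DiveArchetypeSpec(
            550.0, 50.0, 23.0, 3.0, 0.45, 18.0, 3.0, 8.0, diel_depth_offset_m=100.0
        ),
        # depth taken from the seafloor at the dive location, not from here
        "benthic_foraging": DiveArchetypeSpec(250.0, 20.0, 20.0, 3.0, 0.55, 17.0, 3.0, 8.0),
        "drift": DiveArchetypeSpec(220.0, 30.0, 20.0, 3.0, 0.0),
    }


@dataclass
class StrategySpec:
    """Movement, diving and body-composition profile of one foraging strategy."""

    sex: str
    trip: str  # post_breeding | post_moult
    n: int
    trip_days_mean: float
    trip_days_sd: float
    transit_speed_kmh: float
    foraging_range_km: float
    patch_bearing_deg: float  # bearing of the main patch from the colony
    n_patches: int
    # dive archetype mixture by behavioural state
    ars_dive_mix: dict
    transit_dive_mix: dict
    departure_mass_mean_kg: float
    departure_mass_sd_kg: float
    mass_gain_mean_kg: float
    mass_gain_sd_kg: float
    adipose_gain_fraction: float
    # males feed just inshore of the shelf edge; the patch is then placed
    # foraging_range_km up the coast, ~15-20 km east of the isobath
    patch_on_shelf: bool = False
    # per-strategy dive archetype overrides (e.g. males dive shallower)
    archetype_overrides: dict = field(default_factory=dict)


def _default_strategies() -> dict:
    # Trip durations, departure masses and mass gains follow the reported
    # cohort conditions for each strategy (means +/- s.d.).
    return {
        "male": StrategySpec(
            sex="male",
            trip="post_breeding",
            n=4,
            trip_days_mean=124.0,
            trip_days_sd=21.0,
            transit_speed_kmh=5.5,
            foraging_range_km=850.0,
            patch_bearing_deg=0.0,  # north, up the coast
            n_patches=1,
            ars_dive_mix={"benthic_foraging": 0.70, "pelagic_foraging": 0.13, "drift": 0.10, "transit": 0.07},
            transit_dive_mix={"transit": 0.72, "drift": 0.14, "pelagic_foraging": 0.14},
            departure_mass_mean_kg=1074.19,
            departure_mass_sd_kg=194.29,
            mass_gain_mean_kg=458.44,
            mass_gain_sd_kg=218.25,
            adipose_gain_fraction=0.45,
            patch_on_shelf=True,
            archetype_overrides={
                "pelagic_foraging": DiveArchetypeSpec(
                    405.0, 70.0, 23.5, 3.0, 0.47, 19.0, 2.0, 8.0, diel_depth_offset_m=42.0
                )
            },
        ),
        "female_pb": StrategySpec(
            sex="female",
            trip="post_breeding",
            n=10,
            trip_days_mean=76.0,
            trip_days_sd=13.0,
            transit_speed_kmh=5.5,
            foraging_range_km=1800.0,
            patch_bearing_deg=300.0,
            n_patches=2,
            ars_dive_mix={"pelagic_foraging": 0.75, "benthic_foraging": 0.04, "drift": 0.11, "transit": 0.10},
            # the outbound/return legs cross the shelf: a few benthic dives there
            transit_dive_mix={"transit": 0.57, "pelagic_foraging": 0.21, "drift": 0.14, "benthic_foraging": 0.08},
            departure_mass_mean_kg=334.72,
            departure_mass_sd_kg=48.95,
            mass_gain_mean_kg=76.06,
            mass_gain_sd_kg=31.22,
            adipose_gain_fraction=0.55,
        ),
        "female_pm": StrategySpec(
            sex="female",
            trip="post_moult",
            n=4,
            trip_days_mean=220.0,
            trip_days_sd=20.0,
            transit_speed_kmh=5.5,
            foraging_range_km=2600.0,
            patch_bearing_deg=290.0,
            n_patches=3,
            ars_dive_mix={"pelagic_foraging": 0.72, "benthic_foraging": 0.04, "drift": 0.14, "transit": 0.10},
            transit_dive_mix={"transit": 0.56, "pelagic_foraging": 0.21, "drift": 0.15, "benthic_foraging": 0.08},
            departure_mass_mean_kg=281.46,
            departure_mass_sd_kg=36.34,
            mass_gain_mean_kg=232.82,
            mass_gain_sd_kg=53.27,
            adipose_gain_fraction=0.55,
            archetype_overrides={
                "pelagic_foraging": DiveArchetypeSpec(
                    545.0, 40.0, 27.0, 2.0, 0.44, 17.0, 2.0, 8.0, diel_depth_offset_m=120.0
                )
            },
        ),
    }


@dataclass
class FateSpec:
    """Per-sex tag-fate probabilities (cohort-level conditions)."""

    death_prob: dict = field(default_factory=lambda: {"male": 0.44, "female": 0.12})
    tag_failure_prob: dict = field(default_factory=lambda: {"male": 0.21, "female": 0.13})
    resight_prob_after_failure: float = 0.5


@dataclass
class GeometrySpec:
    """Colony, a straight 200 m shelf isobath, and rectangular ecoregions.

    The shelf isobath runs along a meridian so distances to it are
    checkable by hand; the seafloor is a flat shelf east of the isobath
    ramping into an abyssal plain west of it.
    """

    colony_lat: float = 37.0
    colony_lon: float = -122.0
    shelf_lon: float = -123.0
    shelf_lat_range: tuple = (28.0, 55.0)
    shelf_depth_m: float = 250.0
    abyssal_depth_m: float = 3800.0
    abyssal_ramp_km: float = 60.0
    # name -> (lat_min, lat_max, lon_min, lon_max); non-overlapping
    ecoregions: dict = field(
        default_factory=lambda: {
            "California Current": (25.0, 42.0, -135.0, -112.0),
            "Subarctic Pacific": (42.0, 62.0, -180.0, -112.0),
            "North Central Pacific": (25.0, 42.0, -180.0, -135.0),
        }
    )

    def shelf_polyline(self):
        lats = np.linspace(self.shelf_lat_range[0], self.shelf_lat_range[1], 55)
        lons = np.full_like(lats, self.shelf_lon)
        return lats, lons

    def seafloor_depth_m(self, lat, lon):
        """Seafloor depth at a position (m, positive down)."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        km_per_deg = 111.195 * np.cos(np.radians(lat))
        west_km = (self.shelf_lon - lon) * km_per_deg  # >0 offshore of the isobath
        frac = np.clip(west_km / self.abyssal_ramp_km, 0.0, 1.0)
        return self.shelf_depth_m + frac * (self.abyssal_depth_m - self.shelf_depth_m)

    def ecoregion_geojson(self) -> dict:
        feats = []
        for name, (la0, la1, lo0, lo1) in self.ecoregions.items():
            ring = [[lo0, la0], [lo1, la0], [lo1, la1], [lo0, la1], [lo0, la0]]
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"name": name},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    def shelf_geojson(self) -> dict:
        lats, lons = self.shelf_polyline()
        return {
            "type": "Feature",
            "properties": {"name": "200 m isobath", "depth_m": 200},
            "geometry": {
                "type": "LineString",
                "coordinates": [[float(lo), float(la)] for la, lo in zip(lats, lons)],
            },
        }


@dataclass
class SimConfig:
    """Full simulation configuration; same seed implies identical output."""

    seed: int = 0
    start_date: str = "2010-03-01"
    strategies: dict = field(default_factory=_default_strategies)
    archetypes: dict = field(default_factory=_default_archetypes)
    fate: FateSpec = field(default_factory=FateSpec)
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    argos_error_sd_km: dict = field(default_factory=lambda: dict(DEFAULT_ARGOS_ERROR_SD_KM))
    argos_class_weights: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    mean_fix_interval_h: float = 1.5
    outlier_rate: float = 0.02
    outlier_shift_km: float = 120.0
    dive_sampling_interval_s: float = 8.0
    depth_noise_sd_m: float = 1.0
    surface_drift_amplitude_m: float = 0.0
    surface_interval_mean_min: float = 2.2
    surface_interval_sd_min: float = 0.4
    ars_speed_kmh: float = 0.8
    pup_mass_kg: float = 36.0
    days_ashore_max: float = 8.0

    def validate(self) -> None:
        for name, s in self.strategies.items():
            if s.n < 0:
                raise ValueError(f"strategy {name}: n must be non-negative")
            for mix in (s.ars_dive_mix, s.transit_dive_mix):
                if abs(sum(mix.values()) - 1.0) > 1e-9:
                    raise ValueError(f"strategy {name}: dive mix must sum to 1")
        for d in (self.fate.death_prob, self.fate.tag_failure_prob):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("fate probabilities must be in [0, 1]")
        if not 1.0 <= self.dive_sampling_interval_s <= 8.0:
            raise ValueError("dive sampling interval must be in [1 s, 8 s]")
        if self.geometry.shelf_lat_range[0] >= self.geometry.shelf_lat_range[1]:
            raise ValueError("malformed shelf geometry")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_plain(dataclasses.asdict(self)), fh, sort_keys=False)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def scaled_config(seed: int = 0, trip_days: float | None = 6.0, n_per_strategy: dict | None = None) -> SimConfig:
    """A down-scaled configuration for desk-scale runs.

    Trip durations (and foraging ranges, proportionally) are shortened while
    every behavioural parameter — speeds, dive archetypes, error models,
    fate probabilities — keeps its default value.
    """
    cfg = SimConfig(seed=seed)
    if trip_days is not None:
        # scale every strategy's range by one factor (the farthest strategy
        # spends ~55% of the trip in transit) so the male < post-breeding <
        # post-moult range ordering survives the scaling
        max_range = max(s.foraging_range_km for s in cfg.strategies.values())
        speed = min(s.transit_speed_kmh for s in cfg.strategies.values())
        budget_km = trip_days * 24.0 * speed / 2.0 * 0.55
        factor = min(1.0, budget_km / max_range)
    for name, s in cfg.strategies.items():
        if trip_days is not None:
            s.trip_days_sd = max(0.5, s.trip_days_sd * trip_days / s.trip_days_mean)
            s.trip_days_mean = trip_days
            s.foraging_range_km = s.foraging_range_km * factor
        if n_per_strategy and name in n_per_strategy:
            s.n = int(n_per_strategy[name])
    return cfg


def planted_config(seed: int = 0, trip_days: float = 6.0,
                   n_per_strategy: dict | None = None) -> SimConfig:
    """Three planted strategies at generous separation, for recovery tests.

    The default configuration mirrors the published cohort, where the two
    female strategies differ subtly; this variant pushes the strategy
    parameter sets far apart (dive depths 300/550/800 m, durations
    14/22/32 min, distinct wiggle rates, drift depths and ranges) so that
    a clustering pipeline that works must recover exactly three groups.
    """
    cfg = scaled_config(seed=seed, trip_days=trip_days, n_per_strategy=n_per_strategy)
    planted = {
        "male": {
            "pelagic_foraging": DiveArchetypeSpec(300.0, 30.0, 14.0, 1.5, 0.55, 10.0, 1.5, 8.0, 30.0),
            "benthic_foraging": DiveArchetypeSpec(250.0, 20.0, 20.0, 2.0, 0.55, 17.0, 2.0, 8.0),
            "drift": DiveArchetypeSpec(140.0, 15.0, 14.0, 1.5, 0.0),
        },
        "female_pb": {
            "pelagic_foraging": DiveArchetypeSpec(550.0, 40.0, 22.0, 2.0, 0.45, 18.0, 2.0, 8.0, 90.0),
            "benthic_foraging": DiveArchetypeSpec(250.0, 20.0, 13.0, 1.5, 0.45, 9.0, 1.5, 8.0),
            "drift": DiveArchetypeSpec(260.0, 20.0, 20.0, 2.0, 0.0),
        },
        "female_pm": {
            "pelagic_foraging": DiveArchetypeSpec(800.0, 50.0, 32.0, 2.5, 0.35, 26.0, 2.5, 8.0, 150.0),
            "benthic_foraging": DiveArchetypeSpec(250.0, 20.0, 30.0, 2.5, 0.35, 25.0, 2.5, 8.0),
            "drift": DiveArchetypeSpec(380.0, 25.0, 26.0, 2.5, 0.0),
        },
    }
    for name, overrides in planted.items():
        cfg.strategies[name].archetype_overrides = overrides
        if name != "male":
            # plenty of shelf benthic dives so the benthic day/night cells
            # are well-estimated for every animal
            cfg.strategies[name].transit_dive_mix = {
                "transit": 0.47, "pelagic_foraging": 0.20, "drift": 0.13,
                "benthic_foraging": 0.20,
            }
    return cfg


# ---------------------------------------------------------------------------
# dive series
# ---------------------------------------------------------------------------


def _triangle_wiggles(n: int, count: int) -> np.ndarray:
    """Unit wiggle waveform: ``count`` shallow-ward excursions, 0 at both ends."""
    if count <= 0 or n < 2 * count + 1:
        return np.zeros(n)
    x = np.linspace(0.0, count, n)
    return np.abs(((x % 1.0) * 2.0) - 1.0) * -1.0 + 1.0  # 0..1..0 per period


def _dive_profile(dtype: str, spec: DiveArchetypeSpec, dt: float, rng, depth_override=None,
                  is_day: bool = True, max_depth_m: float | None = None) -> np.ndarray:
    """Depth samples (m) of one dive, surface-to-surface exclusive."""
    dur_s = max(60.0, rng.normal(spec.duration_mean_min, spec.duration_sd_min) * 60.0)
    if depth_override is not None:
        depth = float(depth_override)
    else:
        depth = max(30.0, rng.normal(spec.depth_mean_m, spec.depth_sd_m))
        if dtype == "pelagic_foraging" and spec.diel_depth_offset_m:
            depth += (0.5 if is_day else -0.5) * spec.diel_depth_offset_m
        if max_depth_m is not None:
            depth = min(depth, max_depth_m)
    if dtype == "transit":
        # fixed 1.3 m/s vertical rate so V-dives never mimic a slow drift;
        # floor keeps even the shallowest V-dive clearly above the 32 s rule
        dur_s = max(66.0, 2.0 * depth / 1.3)
        n = max(5, int(round(dur_s / dt)))
        t = np.linspace(0.0, 1.0, n)
        return np.interp(t, [0.0, 0.5, 1.0], [0.0, depth, 0.0])
    n = max(5, int(round(dur_s / dt)))
    t = np.linspace(0.0, 1.0, n)
    if dtype == "drift":
        t_desc = 0.5 * (1.0 - spec.drift_fraction)
        d_end = depth + spec.drift_rate_m_s * (spec.drift_fraction * dur_s)
        return np.interp(t, [0.0, t_desc, t_desc + spec.drift_fraction, 1.0], [0.0, depth, d_end, 0.0])
    # flat-bottomed foraging dive with wiggles
    bf = spec.bottom_fraction
    edge = 0.5 * (1.0 - bf)
    prof = np.interp(t, [0.0, edge, 1.0 - edge, 1.0], [0.0, depth, depth, 0.0])
    bottom = (t >= edge) & (t <= 1.0 - edge)
    nk = int(bottom.sum())
    if spec.wiggle_count_sd > 0:
        count = max(0, int(round(rng.normal(spec.wiggle_count_mean, spec.wiggle_count_sd))))
    else:
        count = int(round(spec.wiggle_count_mean))
    # a wiggle needs >= 6 samples to be resolved at the TDR sampling rate;
    # more would alias into an apparently flat (or slowly drifting) bottom
    if spec.wiggle_count_sd > 0:
        count = min(count, nk // 6)
    prof[bottom] -= spec.wiggle_amplitude_m * _triangle_wiggles(nk, count)
    return prof


def simulate_dive_series(
    archetype_mix: dict,
    duration_h: float,
    sampling_interval_s: float = 8.0,
    archetypes: dict | None = None,
    seed: int = 0,
    depth_noise_sd_m: float = 0.0,
    seafloor_depth_m: float | None = None,
    surface_interval_min: float = 2.2,
    is_day=None,
    start_time: np.datetime64 | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a depth time series from a mixture of dive archetypes.

    Parameters
    ----------
    archetype_mix
        Mapping dive type -> probability; must sum to 1.
    duration_h
        Length of the series, hours.
    sampling_interval_s
        TDR sampling interval, seconds (1-8 s).
    seafloor_depth_m
        Seafloor under the series; benthic dives track it.  ``None`` makes
        benthic dives use their archetype depth.
    is_day
        ``None``, a bool, or a callable of elapsed seconds returning a bool;
        drives the pelagic diel depth offset.

    Returns
    -------
    (series, truth)
        ``series``: columns ``time_s`` (and ``timestamp`` if ``start_time``
        given), ``depth_m``.  ``truth``: one row per dive with start/end
        sample times, type and the generated wiggle count.
    """
    if not 1.0 <= sampling_interval_s <= 8.0:
        raise ValueError("sampling interval must be in [1 s, 8 s]")
    if abs(sum(archetype_mix.values()) - 1.0) > 1e-9:
        raise ValueError("archetype weights must sum to 1")
    archetypes = archetypes or _default_archetypes()
    rng = np.random.default_rng(seed)
    dt = float(sampling_interval_s)
    total_n = int(duration_h * 3600.0 / dt)
    types = list(archetype_mix)
    probs = np.array([archetype_mix[k] for k in types])

    depths = np.zeros(total_n)
    truth_rows = []
    i = int(round(60.0 / dt))  # lead-in minute at the surface
    while i < total_n:
        dtype = types[rng.choice(len(types), p=probs)]
        spec = archetypes[dtype]
        elapsed = i * dt
        day = is_day(elapsed) if callable(is_day) else (True if is_day is None else bool(is_day))
        override = seafloor_depth_m if (dtype == "benthic_foraging" and seafloor_depth_m is not None) else None
        prof = _dive_profile(dtype, spec, dt, rng, depth_override=override, is_day=day)
        if i + len(prof) >= total_n:
            break
        depths[i : i + len(prof)] = prof
        truth_rows.append(
            {
                "start_s": i * dt,
                "end_s": (i + len(prof) - 1) * dt,
                "dive_type": dtype,
                "max_depth_m": float(prof.max()),
                "wiggle_count": int(round(spec.wiggle_count_mean)) if spec.wiggle_count_sd == 0 else np.nan,
                "is_day": day,
            }
        )
        si_s = max(30.0, rng.normal(surface_interval_min, 0.4) * 60.0)
        i += len(prof) + int(round(si_s / dt))

    if depth_noise_sd_m > 0:
        depths = depths + rng.normal(0.0, depth_noise_sd_m, total_n)
    depths = np.maximum(depths, 0.0)
    series = pd.DataFrame({"time_s": np.arange(total_n) * dt, "depth_m": depths})
    if start_time is not None:
        series["timestamp"] = np.datetime64(start_time) + series["time_s"].astype("timedelta64[s]")
    return series, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------


def _simulate_path(strategy: StrategySpec, trip_h: int, cfg: SimConfig, rng) -> pd.DataFrame:
    """Hourly true path in the colony-centred plane; returns lat/lon + state.

    Two-state correlated walk: directed transit toward a sequence of patch
    centres (and home), and slow high-turning area-restricted search (ARS)
    while on a patch.
    """
    geom = cfg.geometry
    proj = AzimuthalEquidistant(geom.colony_lat, geom.colony_lon)
    bearing = np.radians(strategy.patch_bearing_deg)
    if strategy.patch_on_shelf:
        lat_p = geom.colony_lat + 0.8 * strategy.foraging_range_km / 111.195
        lon_p = geom.shelf_lon + 0.20  # ~15-18 km inshore of the isobath
        px, py = proj.to_xy(lat_p, lon_p)
        main = np.array([float(px), float(py)])
        scatter = np.array([4.0, strategy.foraging_range_km * 0.06])  # along-shelf
    else:
        main = np.array([np.sin(bearing), np.cos(bearing)]) * strategy.foraging_range_km
        scatter = np.full(2, strategy.foraging_range_km * 0.12)
    patches = [main]
    for _ in range(strategy.n_patches - 1):
        patches.append(main + rng.normal(0.0, 1.0, 2) * scatter)
    # travel time out/back plus inter-patch hops at transit speed
    hop = sum(
        float(np.linalg.norm(patches[k + 1] - patches[k])) for k in range(len(patches) - 1)
    )
    travel_h = (2.0 * float(np.linalg.norm(main)) + hop) / strategy.transit_speed_kmh
    dwell_total = max(6.0 * len(patches), trip_h - travel_h * 1.15)
    dwell_each = dwell_total / len(patches)

    pos = np.zeros(2)
    heading = bearing
    rows = []
    phase_targets = list(patches) + [np.zeros(2)]
    phase = 0
    dwell_left = 0.0
    state = "transit"
    for h in range(trip_h):
        rows.append((pos[0], pos[1], state))
        if state == "transit":
            target = phase_targets[phase]
            to_t = target - pos
            dist = np.linalg.norm(to_t)
            if dist < 15.0:
                if phase < len(patches):
                    state = "ars"
                    dwell_left = dwell_each * rng.uniform(0.85, 1.15)
                else:
                    # home: hold position at the colony until trip end
                    pos = pos * 0.0
                    state = "done"
                continue
            desired = np.arctan2(to_t[0], to_t[1])
            heading = desired + rng.normal(0.0, 0.15)
            speed = max(0.5, rng.normal(strategy.transit_speed_kmh, 0.6))
        elif state == "ars":
            dwell_left -= 1.0
            if dwell_left <= 0.0:
                phase += 1
                state = "transit"
                continue
            heading = heading + rng.normal(0.0, 1.8)
            speed = max(0.05, rng.normal(cfg.ars_speed_kmh, 0.35))
        else:  # done: hauled out / at colony
            speed = 0.0
        step = min(speed, strategy.transit_speed_kmh * 2.0)
        pos = pos + np.array([np.sin(heading), np.cos(heading)]) * step
    xy = np.array([(r[0], r[1]) for r in rows])
    lat, lon = proj.to_latlon(xy[:, 0], xy[:, 1])
    return pd.DataFrame(
        {
            "hour": np.arange(trip_h),
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
            "lat": lat,
            "lon": lon,
            "state": [r[2] for r in rows],
        }
    )


def _simulate_argos(path: pd.DataFrame, start: np.datetime64, cfg: SimConfig, rng,
                    deployment_id: str) -> pd.DataFrame:
    """Noisy ARGOS fixes along a true hourly path."""
    trip_h = len(path)
    t = 0.1
    times = []
    while t < trip_h - 0.1:
        times.append(t)
        t += max(0.2, rng.exponential(cfg.mean_fix_interval_h))
    times = np.array(times)
    xt = np.interp(times, path["hour"], path["x_km"])
    yt = np.interp(times, path["hour"], path["y_km"])
    classes = rng.choice(
        ARGOS_CLASSES, size=len(times), p=[cfg.argos_class_weights[c] for c in ARGOS_CLASSES]
    )
    sd = np.array([cfg.argos_error_sd_km[c] for c in classes])
    x = xt + rng.normal(0.0, sd)
    y = yt + rng.normal(0.0, sd)
    # alternate (mirror) solutions: independent error of the same class
    ax = xt + rng.normal(0.0, sd)
    ay = yt + rng.normal(0.0, sd)
    out = rng.random(len(times)) < cfg.outlier_rate
    theta = rng.uniform(0.0, 2.0 * np.pi, len(times))
    shift = cfg.outlier_shift_km * rng.uniform(0.8, 2.0, len(times))
    x = np.where(out, x + shift * np.cos(theta), x)
    y = np.where(out, y + shift * np.sin(theta), y)
    proj = AzimuthalEquidistant(cfg.geometry.colony_lat, cfg.geometry.colony_lon)
    lat, lon = proj.to_latlon(x, y)
    alat, alon = proj.to_latlon(ax, ay)
    ts = start + (times * 3600.0).astype("timedelta64[s]")
    return pd.DataFrame(
        {
            "deployment_id": deployment_id,
            "timestamp": ts,
            "lc": classes,
            "lat": lat,
            "lon": lon,
            "alt_lat": alat,
            "alt_lon": alon,
            "is_outlier": out,
        }
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass
class Deployment:
    deployment_id: str
    sex: str
    trip: str
    strategy: str
    year: int
    start: np.datetime64
    trip_days: float


@dataclass
class SimulatedCohort:
    """Everything one simulation run produces, observables plus ground truth."""

    config: SimConfig
    deployments: list
    fixes: pd.DataFrame  # all ARGOS fixes
    true_paths: dict  # deployment_id -> hourly truth DataFrame
    dive_series: dict  # deployment_id -> depth DataFrame
    dive_truth: dict  # deployment_id -> per-dive truth DataFrame
    body: pd.DataFrame
    fates: pd.DataFrame
    transmissions: dict  # deployment_id -> daily best-class record
    resights: dict  # deployment_id -> list of resight dates

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fixes.to_csv(outdir / "argos_fixes.csv", index=False)
        self.body.to_csv(outdir / "body_composition.csv", index=False)
        self.fates.to_csv(outdir / "tag_fates.csv", index=False)
        pd.concat(
            [df.assign(deployment_id=k) for k, df in self.dive_series.items()],
            ignore_index=True,
        ).to_csv(outdir / "depth_series.csv", index=False)
        with open(outdir / "geometry.geojson", "w") as fh:
            gj = self.config.geometry.ecoregion_geojson()
            gj["features"].append(self.config.geometry.shelf_geojson())
            json.dump(gj, fh)
        self.config.to_yaml(outdir / "sim_config.yaml")


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Simulate a full cohort under ``config`` (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    start0 = np.datetime64(config.start_date + "T00:00:00")

    deployments = []
    fixes_all = []
    true_paths = {}
    dive_series = {}
    dive_truth = {}
    body_rows = []
    fate_rows = []
    transmissions = {}
    resights = {}
    idx = 0
    for sname, strat in config.strategies.items():
        for k in range(strat.n):
            did = f"{sname}_{k:03d}"
            year = 2006 + (idx % 10)
            trip_days = max(2.0, rng.normal(strat.trip_days_mean, strat.trip_days_sd))
            start = start0 + np.timedelta64(int(rng.integers(0, 30)) * 24 * 3600, "s")
            trip_h = int(trip_days * 24)
            path = _simulate_path(strat, trip_h, config, rng)
            path["timestamp"] = start + (path["hour"].to_numpy() * 3600).astype("timedelta64[s]")
            true_paths[did] = path
            fixes_all.append(_simulate_argos(path, start, config, rng, did))

            series, truth = _dive_series_for_path(path, strat, config, rng, start)
            dive_series[did] = series
            dive_truth[did] = truth

            # body composition: truth gain, measured arrival after onshore fasting
            dep_mass = max(80.0, rng.normal(strat.departure_mass_mean_kg, strat.departure_mass_sd_kg))
            gain = rng.normal(strat.mass_gain_mean_kg, strat.mass_gain_sd_kg)
            gain = max(gain, -0.2 * dep_mass)
            adipose = gain * strat.adipose_gain_fraction
            lean = gain - adipose
            days_ashore = rng.uniform(0.0, config.days_ashore_max)
            pup = config.pup_mass_kg if (strat.sex == "female" and strat.trip == "post_moult") else 0.0
            arrival_true = dep_mass + gain
            measured = _apply_onshore_loss(arrival_true, strat.sex, strat.trip, days_ashore, config) - pup
            body_rows.append(
                {
                    "deployment_id": did,
                    "sex": strat.sex,
                    "trip": strat.trip,
                    "departure_mass_kg": dep_mass,
                    "arrival_mass_measured_kg": measured,
                    "days_ashore": days_ashore,
                    "pup_mass_kg": pup,
                    "adipose_fraction_of_gain": strat.adipose_gain_fraction,
                    "trip_days": trip_days,
                    "true_mass_gain_kg": gain,
                    "true_adipose_gain_kg": adipose,
                    "true_lean_gain_kg": lean,
                }
            )

            fate_row, trans, res = _simulate_fate(did, strat, trip_days, year, config, rng, path, start)
            fate_rows.append(fate_row)
            transmissions[did] = trans
            resights[did] = res
            deployments.append(Deployment(did, strat.sex, strat.trip, sname, year, start, trip_days))
            idx += 1

    return SimulatedCohort(
        config=config,
        deployments=deployments,
        fixes=pd.concat(fixes_all, ignore_index=True),
        true_paths=true_paths,
        dive_series=dive_series,
        dive_truth=dive_truth,
        body=pd.DataFrame(body_rows),
        fates=pd.DataFrame(fate_rows),
        transmissions=transmissions,
        resights=resights,
    )


def _individual_archetypes(strat, cfg, rng) -> tuple[dict, float]:
    """Per-animal dive parameters: individuals differ in depth, duration,
    bottom fraction, wiggle rate and how tightly benthic dives hug the
    seafloor, around their strategy's means."""
    out = {}
    for dtype in DIVE_TYPES:
        base = strat.archetype_overrides.get(dtype, cfg.archetypes[dtype])
        out[dtype] = dataclasses.replace(
            base,
            depth_mean_m=base.depth_mean_m * rng.normal(1.0, 0.05),
            duration_mean_min=base.duration_mean_min * rng.normal(1.0, 0.05),
            bottom_fraction=float(np.clip(base.bottom_fraction + rng.normal(0.0, 0.02), 0.0, 0.65)),
            wiggle_count_mean=max(3.0, base.wiggle_count_mean + rng.normal(0.0, 1.5))
            if base.wiggle_count_mean > 0
            else 0.0,
        )
    benthic_frac = rng.uniform(0.955, 0.985)
    return out, benthic_frac


def _dive_series_for_path(path, strat, cfg, rng, start):
    """Depth series over the whole trip; archetype mix follows the hourly state."""
    geom = cfg.geometry
    dt = cfg.dive_sampling_interval_s
    indiv, benthic_frac = _individual_archetypes(strat, cfg, rng)
    trip_h = len(path)
    total_n = int(trip_h * 3600.0 / dt)
    depths = np.zeros(total_n)
    truth_rows = []
    archetypes = cfg.archetypes
    state = path["state"].to_numpy()
    lat = path["lat"].to_numpy()
    lon = path["lon"].to_numpy()
    hours = path["hour"].to_numpy(float)
    i = int(round(60.0 / dt))
    while i < total_n:
        h = min(int(i * dt / 3600.0), trip_h - 1)
        if state[h] == "done":
            break
        mix = strat.ars_dive_mix if state[h] == "ars" else strat.transit_dive_mix
        types = list(mix)
        dtype = types[rng.choice(len(types), p=np.array([mix[t] for t in types]))]
        spec = indiv[dtype]
        # approximate dive-midpoint position (the classifier georeferences
        # dives at their midpoints, so the seafloor must be looked up there)
        mid_h = min(i * dt / 3600.0 + spec.duration_mean_min / 120.0, hours[-1])
        lat_mid = float(np.interp(mid_h, hours, lat))
        lon_mid = float(np.interp(mid_h, hours, lon))
        ts = start + np.timedelta64(int(i * dt), "s")
        day = bool(solar_zenith_deg(ts, lat_mid, lon_mid) <= 90.0)
        override = None
        sf = float(geom.seafloor_depth_m(lat_mid, lon_mid))
        cap = None
        if dtype == "benthic_foraging":
            # benthic foraging happens on the flat shelf; over the slope or
            # abyss the seal dives pelagically instead
            if sf > geom.shelf_depth_m * 1.15:
                dtype = "pelagic_foraging"
                spec = indiv[dtype]
            else:
                override = sf * benthic_frac * rng.uniform(0.995, 1.005)
        if override is None and sf < 1500.0:
            # over the shelf and slope, non-benthic dives stay well clear of
            # the seafloor so depth never mimics a benthic profile
            cap = (0.4 if dtype == "drift" else 0.5) * sf
        prof = _dive_profile(dtype, spec, dt, rng, depth_override=override, is_day=day,
                             max_depth_m=cap)
        if i + len(prof) >= total_n:
            break
        depths[i : i + len(prof)] = prof
        truth_rows.append(
            {
                "start_s": i * dt,
                "end_s": (i + len(prof) - 1) * dt,
                "dive_type": dtype,
                "max_depth_m": float(prof.max()),
                "is_day": day,
                "state": state[h],
            }
        )
        si = max(30.0, rng.normal(cfg.surface_interval_mean_min, cfg.surface_interval_sd_min) * 60.0)
        i += len(prof) + int(round(si / dt))
    if cfg.depth_noise_sd_m > 0:
        depths = depths + rng.normal(0.0, cfg.depth_noise_sd_m, total_n)
    if cfg.surface_drift_amplitude_m > 0:
        drift = cfg.surface_drift_amplitude_m * np.sin(
            2.0 * np.pi * np.arange(total_n) * dt / (72.0 * 3600.0)
        )
        depths = depths + drift
    depths = np.maximum(depths, 0.0)
    series = pd.DataFrame({"time_s": np.arange(total_n) * dt, "depth_m": depths})
    series["timestamp"] = start + series["time_s"].astype("timedelta64[s]")
    return series, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# onshore loss (shared with bioenergetics, duplicated here would drift —
# import lazily to avoid a cycle)
# ---------------------------------------------------------------------------


def _apply_onshore_loss(mass, sex, trip, days, cfg):
    from . import bioenergetics as be

    if sex == "female":
        return be.apply_female_onshore_loss(mass, days)
    phase = "breeding" if trip == "post_moult" else "moult"
    return be.apply_male_onshore_loss(mass, phase, days)


# ---------------------------------------------------------------------------
# tag fates
# ---------------------------------------------------------------------------


def _quality_series(n_days: int, rng) -> list:
    w = [DEFAULT_CLASS_WEIGHTS[c] for c in ARGOS_CLASSES]
    return list(rng.choice(ARGOS_CLASSES, size=n_days, p=np.array(w) / sum(w)))


def _degrading_tail(classes: list, tail: int) -> list:
    """Overwrite the final ``tail`` days with a monotone class decline."""
    n = len(classes)
    tail = min(tail, n)
    steps = np.linspace(0, len(ARGOS_CLASSES) - 1, tail).round().astype(int)
    classes[n - tail :] = [ARGOS_CLASSES[s] for s in steps]
    return classes


def _palindrome_classes(n_days: int) -> list:
    """Trend-free daily classes: a palindrome has Kendall S identically 0."""
    base = [ARGOS_CLASSES[i % len(ARGOS_CLASSES)] for i in range((n_days + 1) // 2)]
    mirror = base[: n_days // 2][::-1]
    return base + mirror


def _simulate_fate(did, strat, trip_days, year, cfg, rng, path, start):
    sex = strat.sex
    u = rng.random()
    p_die = cfg.fate.death_prob[sex]
    p_fail = cfg.fate.tag_failure_prob[sex]
    n_days = max(3, int(trip_days))
    if u < p_die:
        outcome = "died"
        stop_frac = rng.uniform(0.25, 0.95)
    elif u < p_die + p_fail:
        outcome = "tag_failure"
        stop_frac = rng.uniform(0.25, 0.95)
    else:
        outcome = "survived_returned"
        stop_frac = 1.0
    last_day = max(2, int(round(stop_frac * n_days)))
    classes = _quality_series(last_day, rng)
    res = []
    if outcome == "died":
        classes = _palindrome_classes(last_day)
    elif outcome == "tag_failure":
        if rng.random() < cfg.fate.resight_prob_after_failure:
            res = [str((start + np.timedelta64(400, "D")).astype("datetime64[D]"))]
        else:
            classes = _degrading_tail(classes, 30)
    else:
        res = [str((start + np.timedelta64(int(trip_days) + 1, "D")).astype("datetime64[D]"))]
    hour = min(len(path) - 1, int(last_day * 24))
    row = {
        "deployment_id": did,
        "sex": sex,
        "trip": strat.trip,
        "year": year,
        "true_outcome": outcome,
        "trip_days": n_days,
        "last_transmission_day": last_day,
        "last_lat": float(path["lat"].iloc[hour]),
        "last_lon": float(path["lon"].iloc[hour]),
    }
    trans = pd.DataFrame(
        {
            "day": np.arange(last_day),
            "best_class": classes,
        }
    )
    return row, trans, res


# ---------------------------------------------------------------------------
# the published-cohort fixture
# ---------------------------------------------------------------------------


@dataclass
class CohortFixtureSpec:
    """Per-sex accounting of a tagged cohort.

    ``stopped`` tags divide exactly into mechanical ``failures`` and
    ``deaths``; the default numbers mirror the published 217-deployment
    accounting (39 males: 25 stopped = 8 failures + 17 deaths; 178 females:
    46 stopped = 24 failures + 22 deaths).
    """

    male_deployments: int = 39
    male_stopped: int = 25
    male_failures: int = 8
    male_deaths: int = 17
    female_deployments: int = 178
    female_stopped: int = 46
    female_failures: int = 24
    female_deaths: int = 22

    def validate(self) -> None:
        for sex in ("male", "female"):
            dep = getattr(self, f"{sex}_deployments")
            stop = getattr(self, f"{sex}_stopped")
            fail = getattr(self, f"{sex}_failures")
            die = getattr(self, f"{sex}_deaths")
            if fail + die != stop:
                raise ValueError(f"{sex}: failures + deaths must equal stopped")
            if stop > dep:
                raise ValueError(f"{sex}: stopped cannot exceed deployments")


def make_reference_cohort_fixture(spec: CohortFixtureSpec | None = None):
    """Deterministic 217-deployment cohort for tag-fate attribution.

    Constructed so the attribution rules recover the spec counts exactly:
    survivors transmit until return and are resighted; half the mechanical
    failures are resighted in a later season, the other half show a
    monotone location-class decline over their final 30 days; deaths stop
    at sea with a trend-free (palindromic) class record and no resight.

    Returns ``(cohort_table, transmissions, resights)`` where
    ``cohort_table`` is one row per deployment (sex, trip, year, trip_days,
    last_transmission_day) and the other two are keyed by deployment id.
    """
    spec = spec or CohortFixtureSpec()
    spec.validate()
    rows = []
    transmissions = {}
    resights = {}
    for sex in ("male", "female"):
        dep = getattr(spec, f"{sex}_deployments")
        fail = getattr(spec, f"{sex}_failures")
        die = getattr(spec, f"{sex}_deaths")
        stop = getattr(spec, f"{sex}_stopped")
        trip_days = 124 if sex == "male" else 110
        for k in range(dep):
            did = f"{sex}_{k:03d}"
            year = 2006 + (k % 10)
            trip = "post_breeding" if k % 2 == 0 else "post_moult"
            if k < die:
                last_day = 40 + (k % 50)
                classes = _palindrome_classes(last_day)
                res = []
            elif k < die + fail:
                last_day = 45 + (k % 40)
                if (k - die) < fail // 2:
                    classes = _palindrome_classes(last_day)
                    res = [f"{year + 1}-02-01"]
                else:
                    classes = _degrading_tail(_palindrome_classes(last_day), 30)
                    res = []
            else:
                last_day = trip_days
                classes = _palindrome_classes(last_day)
                res = [f"{year}-12-01"]
            rows.append(
                {
                    "deployment_id": did,
                    "sex": sex,
                    "trip": trip,
                    "year": year,
                    "trip_days": trip_days,
                    "last_transmission_day": last_day,
                }
            )
            transmissions[did] = pd.DataFrame({"day": np.arange(last_day), "best_class": classes})
            resights[did] = res
    return pd.DataFrame(rows), transmissions, resights
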