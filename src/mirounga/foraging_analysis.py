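"""Trip-level foraging variables: feeding detection, spatial labels and
the 31-variable behavioural profile of each deployment.

An hourly position is a foraging location when the transit speed is
below 2 km/h *and* at least one pelagic- or benthic-foraging dive is
georeferenced to that hour.  From the flagged hours the module derives
the proportion of time feeding, the trip typology (focused vs
throughout), the majority ecoregion, habitat class, mean distance to the
200 m shelf isobath and the 95% UD foraging area, and assembles them —
together with day/night dive metrics for both foraging dive types — into
one row per deployment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape

from .geometry import AzimuthalEquidistant, haversine_km, point_to_polyline_km
from .space_overlap import kde_ud, ud_region


@dataclass
class ForagingParams:
    max_foraging_speed_kmh: float = 2.0
    ecoregion_majority_fraction: float = 0.50
    focused_max_stray_locations: int = 5
    shelf_isobath_m: float = 200.0
    kde_cell_km: float = 2.0
    ud_level: float = 0.95
    apex_distance_fraction: float = 0.90  # "farthest point" plateau definition
    nearshelf_km: float = 30.0
    coastal_fraction: float = 0.90
    open_ocean_fraction: float = 0.10

    def __post_init__(self):
        if self.max_foraging_speed_kmh <= 0:
            raise ValueError("speed threshold must be positive")
        if not 0.0 < self.ecoregion_majority_fraction <= 1.0:
            raise ValueError("majority fraction must be in (0, 1]")
        if not 0.0 < self.ud_level < 1.0:
            raise ValueError("UD level must be in (0, 1)")


FORAGING_DIVE_TYPES = ("pelagic_foraging", "benthic_foraging")


def detect_foraging_locations(
    hourly: pd.DataFrame, dives: pd.DataFrame, params: ForagingParams | None = None
) -> pd.DataFrame:
    """Flag hourly positions as foraging (slow transit + foraging dive).

    Each dive is binned to its nearest hourly position by midpoint time;
    a position is foraging iff its speed is under the threshold and at
    least one pelagic- or benthic-foraging dive falls in its hour.
    """
    params = params or ForagingParams()
    out = hourly.copy().reset_index(drop=True)
    slow = out["speed_kmh"].to_numpy(float) < params.max_foraging_speed_kmh
    has_forage = np.zeros(len(out), dtype=bool)
    if len(dives) and "mid_timestamp" in dives.columns:
        fdives = dives[dives["dive_type"].isin(FORAGING_DIVE_TYPES)]
        if len(fdives):
            ts = out["timestamp"].to_numpy().astype("datetime64[s]").astype(float)
            mid = fdives["mid_timestamp"].to_numpy().astype("datetime64[s]").astype(float)
            idx = np.clip(np.round((mid - ts[0]) / 3600.0).astype(int), 0, len(out) - 1)
            has_forage[np.unique(idx)] = True
    out["is_foraging"] = slow & has_forage
    return out


def proportion_time_feeding(flags: pd.DataFrame) -> float:
    """Foraging hours over total at-sea hours."""
    if len(flags) == 0:
        raise ValueError("no positions")
    return float(flags["is_foraging"].mean())


def classify_trip_typology(
    flags: pd.DataFrame, colony: tuple, params: ForagingParams | None = None
) -> str:
    """"focused" when feeding concentrates at the trip apex.

    The apex ("farthest point") segment is the set of hours whose distance
    from the colony is at least 90% of the trip maximum; a trip is focused
    when fewer than five foraging locations fall outside it.
    """
    params = params or ForagingParams()
    forage = flags[flags["is_foraging"]]
    if forage.empty:
        return "none"
    dist = haversine_km(flags["lat"].to_numpy(float), flags["lon"].to_numpy(float),
                        colony[0], colony[1])
    apex = dist >= params.apex_distance_fraction * dist.max()
    stray = int((~apex[flags["is_foraging"].to_numpy(bool)]).sum())
    return "focused" if stray < params.focused_max_stray_locations else "throughout"


def assign_ecoregion(
    flags: pd.DataFrame, ecoregions, params: ForagingParams | None = None
) -> str:
    """Region holding >= 50% of foraging locations, else "multiple".

    ``ecoregions`` is a GeoJSON FeatureCollection (dict) of non-overlapping
    polygons with a ``name`` property, or a mapping name -> shapely
    geometry.  Locations outside every polygon count as "open/unassigned".
    """
    params = params or ForagingParams()
    if isinstance(ecoregions, dict) and ecoregions.get("type") == "FeatureCollection":
        polys = {
            f["properties"].get("name", f"region_{i}"): shape(f["geometry"])
            for i, f in enumerate(ecoregions["features"])
            if f["geometry"]["type"] in ("Polygon", "MultiPolygon")
        }
    else:
        polys = dict(ecoregions)
    forage = flags[flags["is_foraging"]]
    if forage.empty:
        return "none"
    counts = {name: 0 for name in polys}
    counts["open/unassigned"] = 0
    for lat, lon in zip(forage["lat"], forage["lon"]):
        pt = Point(lon, lat)
        for name, poly in polys.items():
            if poly.covers(pt):
                counts[name] += 1
                break
        else:
            counts["open/unassigned"] += 1
    total = len(forage)
    best = max(counts, key=counts.get)
    if counts[best] / total >= params.ecoregion_majority_fraction:
        return best
    return "multiple"


def distance_to_shelf(lat, lon, shelf_lats, shelf_lons) -> float:
    """Great-circle distance (km) from a position to the shelf-edge polyline."""
    return point_to_polyline_km(lat, lon, shelf_lats, shelf_lons)


def foraging_area_km2(
    flags: pd.DataFrame, params: ForagingParams | None = None
) -> float:
    """95% UD contour area (km^2) of the foraging locations.

    Gaussian KDE in a local azimuthal-equidistant plane at the locations'
    centroid, 2 km cells, Silverman bandwidth.  Undefined (NaN) below 10
    locations.
    """
    params = params or ForagingParams()
    forage = flags[flags["is_foraging"]]
    if len(forage) < 10:
        return float("nan")
    lat0 = float(forage["lat"].mean())
    lon0 = float(forage["lon"].mean())
    proj = AzimuthalEquidistant(lat0, lon0)
    x, y = proj.to_xy(forage["lat"].to_numpy(float), forage["lon"].to_numpy(float))
    grid = kde_ud(np.column_stack([x, y]), cell_sizes=params.kde_cell_km,
                  bandwidth="silverman")
    _, area = ud_region(grid, params.ud_level)
    return float(area)


def habitat_type(
    shelf_distances_km: np.ndarray, params: ForagingParams | None = None
) -> str:
    """coastal / coastal-open ocean / open ocean from on-shelf fractions.

    On/near shelf means within 30 km of the shelf edge; coastal trips have
    >= 90% of foraging locations on/near shelf, open-ocean trips <= 10%.
    """
    params = params or ForagingParams()
    d = np.asarray(shelf_distances_km, dtype=float)
    if d.size == 0:
        return "none"
    frac = float((d <= params.nearshelf_km).mean())
    if frac >= params.coastal_fraction:
        return "coastal"
    if frac <= params.open_ocean_fraction:
        return "open ocean"
    return "coastal/open ocean"


# ---------------------------------------------------------------------------
# the 31-variable trip summary
# ---------------------------------------------------------------------------

_METRICS = {
    "max_depth_m": "max_depth_m",
    "duration_min": "duration_min",
    "bottom_time_min": "bottom_time_min",
    "post_dive_interval_min": "post_dive_interval_min",
    "n_excursions": "n_excursions",
    "efficiency": "efficiency",
}

TRIP_SUMMARY_VARIABLES = (
    ["shelf_distance_km", "proportion_time_feeding", "foraging_area_km2",
     "prop_transit", "prop_pelagic_foraging", "prop_drift", "prop_benthic_foraging"]
    + [
        f"{m}_{diel}_{ab}"
        for ab in ("pfd", "bfd")
        for diel in ("day", "night")
        for m in _METRICS
    ]
)


def trip_summary(
    deployment_id: str,
    sex: str,
    trip: str,
    hourly_flags: pd.DataFrame,
    dives: pd.DataFrame,
    colony: tuple,
    shelf_lats,
    shelf_lons,
    ecoregions,
    params: ForagingParams | None = None,
) -> dict:
    """Assemble the 31 behavioural variables plus labels for one deployment.

    Missing day/night cells (e.g. a seal with no night benthic dives) are
    NaN; the four dive-type proportions always sum to 1 when any dives
    exist.
    """
    params = params or ForagingParams()
    row: dict = {"deployment_id": deployment_id, "sex": sex, "trip": trip}
    forage = hourly_flags[hourly_flags["is_foraging"]]
    if len(forage):
        dists = np.array(
            [distance_to_shelf(la, lo, shelf_lats, shelf_lons)
             for la, lo in zip(forage["lat"], forage["lon"])]
        )
        row["shelf_distance_km"] = float(dists.mean())
        row["habitat"] = habitat_type(dists, params)
    else:
        row["shelf_distance_km"] = np.nan
        row["habitat"] = "none"
    row["proportion_time_feeding"] = proportion_time_feeding(hourly_flags)
    row["foraging_area_km2"] = foraging_area_km2(hourly_flags, params)
    row["trip_typology"] = classify_trip_typology(hourly_flags, colony, params)
    row["ecoregion"] = assign_ecoregion(hourly_flags, ecoregions, params)

    n = len(dives)
    for dtype, col in [
        ("transit", "prop_transit"),
        ("pelagic_foraging", "prop_pelagic_foraging"),
        ("drift", "prop_drift"),
        ("benthic_foraging", "prop_benthic_foraging"),
    ]:
        row[col] = float((dives["dive_type"] == dtype).mean()) if n else np.nan

    for ab, dtype in (("pfd", "pelagic_foraging"), ("bfd", "benthic_foraging")):
        for diel in ("day", "night"):
            sub = dives[(dives["dive_type"] == dtype) & (dives["diel"] == diel)] if n else dives
            for m, col in _METRICS.items():
                key = f"{m}_{diel}_{ab}"
                row[key] = float(sub[col].mean()) if len(sub) else np.nan
    return row


def trip_summary_table(rows: list[dict]) -> pd.DataFrame:
    """Stack per-deployment summaries; columns ordered as published."""
    df = pd.DataFrame(rows)
    ordered = ["deployment_id", "sex", "trip", "trip_typology", "ecoregion", "habitat"]
    ordered += [c for c in TRIP_SUMMARY_VARIABLES if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]
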