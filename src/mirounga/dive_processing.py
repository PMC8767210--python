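"""Dive detection, metrics, four-type classification and diel assignment.

A dive is an excursion below a surface threshold retained when it lasts
more than 32 s and exceeds 15 m depth.  The bottom phase is the deepest
contiguous stretch beyond 80% of the maximum depth; vertical excursions
("wiggles", the prey-capture-attempt proxy) are shallow-ward runs within
the bottom phase whose amplitude clears a 5 m threshold.  Dives are
classified hierarchically into drift, benthic foraging, pelagic foraging
and transit types, georeferenced onto the smoothed hourly track, and
assigned day or night from the solar zenith angle at the dive midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import solar_zenith_deg


@dataclass
class DiveDetectionParams:
    subsample_interval_s: float = 8.0
    min_duration_s: float = 32.0
    min_depth_m: float = 15.0
    surface_threshold_m: float = 2.0
    zero_offset_window_h: float = 2.0

    def __post_init__(self):
        if self.min_duration_s <= self.subsample_interval_s:
            raise ValueError("min duration must exceed the sampling interval")
        for v in (self.min_depth_m, self.surface_threshold_m):
            if v <= 0:
                raise ValueError("thresholds must be positive")


@dataclass
class ClassifierParams:
    bottom_depth_fraction: float = 0.80
    wiggle_threshold_m: float = 5.0
    benthic_tolerance: float = 0.10
    drift_min_fraction: float = 0.4
    drift_max_rate_m_s: float = 0.4
    transit_max_bottom_fraction: float = 0.15
    day_zenith_deg: float = 90.0  # 96 for the civil-twilight convention

    def __post_init__(self):
        for v in (
            self.bottom_depth_fraction,
            self.benthic_tolerance,
            self.drift_min_fraction,
            self.transit_max_bottom_fraction,
        ):
            if not 0.0 < v < 1.0:
                raise ValueError("fractions must be in (0, 1)")
        if self.wiggle_threshold_m <= 0 or self.drift_max_rate_m_s <= 0:
            raise ValueError("thresholds must be positive")


def subsample_depth(series: pd.DataFrame, target_interval_s: float = 8.0) -> pd.DataFrame:
    """Thin a depth series to the target interval by keeping every k-th sample."""
    t = series["time_s"].to_numpy(float)
    if len(t) < 2:
        return series.reset_index(drop=True)
    src = float(np.median(np.diff(t)))
    ratio = target_interval_s / src
    k = int(round(ratio))
    if abs(ratio - k) > 1e-6 or k < 1:
        raise ValueError(
            f"source interval {src} s does not divide target {target_interval_s} s"
        )
    return series.iloc[::k].reset_index(drop=True)


def zero_offset_correct(series: pd.DataFrame, params: DiveDetectionParams | None = None) -> pd.DataFrame:
    """Remove slow pressure-sensor drift at the surface.

    Subtracts a rolling estimate of the surface mode (the minimum depth in
    a centred window, default 2 h) so that true surface readings sit at
    0 m before dive detection.
    """
    params = params or DiveDetectionParams()
    t = series["time_s"].to_numpy(float)
    d = series["depth_m"].to_numpy(float)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else params.subsample_interval_s
    win = max(3, int(params.zero_offset_window_h * 3600.0 / dt))
    surf = (
        pd.Series(d).rolling(win, center=True, min_periods=1).min().to_numpy()
    )
    out = series.copy()
    out["depth_m"] = np.maximum(d - surf, 0.0)
    return out


def detect_dives(series: pd.DataFrame, params: DiveDetectionParams | None = None) -> list[dict]:
    """Find dives: submergences beyond the surface threshold passing both
    the 32 s duration and 15 m depth retention rules.

    Returns a list of segment dicts with sample indices, times and the
    post-dive surface interval (time to the next retained dive's start).
    """
    params = params or DiveDetectionParams()
    t = series["time_s"].to_numpy(float)
    d = series["depth_m"].to_numpy(float)
    if not np.all(np.isfinite(d)):
        raise ValueError("depths must be finite")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    under = d > params.surface_threshold_m
    if not under.any():
        return []
    edges = np.diff(under.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if under[0]:
        starts.insert(0, 0)
    if under[-1]:
        ends.append(len(d))
    segs = []
    for s, e in zip(starts, ends):
        dur = t[e - 1] - t[s]
        if dur > params.min_duration_s and d[s:e].max() > params.min_depth_m:
            segs.append(
                {
                    "i_start": int(s),
                    "i_end": int(e),
                    "start_s": float(t[s]),
                    "end_s": float(t[e - 1]),
                    "duration_min": float(dur) / 60.0,
                }
            )
    for k in range(len(segs)):
        if k + 1 < len(segs):
            segs[k]["post_dive_interval_min"] = (segs[k + 1]["start_s"] - segs[k]["end_s"]) / 60.0
        else:
            segs[k]["post_dive_interval_min"] = np.nan
    return segs


def _bottom_phase(depth: np.ndarray, frac: float) -> np.ndarray:
    """Boolean mask of the longest contiguous run deeper than frac*max."""
    thr = frac * depth.max()
    deep = depth >= thr
    best = (0, 0)
    i = 0
    n = len(deep)
    while i < n:
        if deep[i]:
            j = i
            while j < n and deep[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    mask = np.zeros(n, dtype=bool)
    mask[best[0] : best[1]] = True
    return mask


def count_excursions(depth: np.ndarray, threshold_m: float) -> int:
    """Count shallow-ward runs with amplitude >= threshold.

    The depth trace is segmented into monotone runs (flat samples merge
    into the current run); each shallow-ward run whose total amplitude
    clears the threshold *and* reverses back toward depth counts as one
    vertical excursion.  A terminal ascent out of the bottom phase is not
    a reversal and does not count.
    """
    d = np.asarray(depth, dtype=float)
    if len(d) < 3:
        return 0
    diffs = np.diff(d)
    count = 0
    run = 0.0
    for step in diffs:
        if step < 0:  # moving shallower
            run += -step
        elif step > 0:
            if run >= threshold_m:
                count += 1
            run = 0.0
    return count


def dive_metrics(series: pd.DataFrame, seg: dict, params: ClassifierParams | None = None) -> dict:
    """Per-dive metrics: max depth, duration, bottom time, efficiency, wiggles."""
    params = params or ClassifierParams()
    d = series["depth_m"].to_numpy(float)[seg["i_start"] : seg["i_end"]]
    t = series["time_s"].to_numpy(float)[seg["i_start"] : seg["i_end"]]
    mask = _bottom_phase(d, params.bottom_depth_fraction)
    idx = np.flatnonzero(mask)
    bottom_min = (t[idx[-1]] - t[idx[0]]) / 60.0 if idx.size > 1 else 0.0
    duration = seg["duration_min"]
    wiggles = count_excursions(d[mask], params.wiggle_threshold_m) if idx.size > 2 else 0
    out = dict(seg)
    out.update(
        {
            "max_depth_m": float(d.max()),
            "bottom_time_min": float(min(bottom_min, duration)),
            "efficiency": float(min(bottom_min, duration) / duration) if duration > 0 else 0.0,
            "n_excursions": int(wiggles),
        }
    )
    return out


def _drift_segment_fraction(depth: np.ndarray, t: np.ndarray, max_rate: float,
                            min_rate: float = 0.02) -> float:
    """Longest slow monotone stretch as a fraction of dive duration.

    Sensor noise would break a strict sample-by-sample monotonicity test,
    so the trace is mean-smoothed and rates are taken over a ~24 s lag at
    every sample (no decimation, which can alias bottom wiggles into an
    apparent drift).  A stretch qualifies when every lagged rate is
    within the drift band, nonzero rates share one sign, and the *net*
    rate over the stretch is itself a real drift (between ``min_rate``
    and ``max_rate``) — a flat bottom phase has no drift direction and
    does not count.
    """
    if len(depth) < 4:
        return 0.0
    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(24.0 / dt)))
    if w > 1:
        kern = np.ones(w) / w
        sm = np.convolve(depth, kern, mode="same")
    else:
        sm = np.asarray(depth, dtype=float)
    if len(sm) <= w + 1:
        return 0.0
    lag_t = t[w:] - t[:-w]
    rate = (sm[w:] - sm[:-w]) / np.where(lag_t > 0, lag_t, 1e-9)
    slow = np.abs(rate) <= max_rate
    sign = np.sign(np.where(np.abs(rate) < min_rate, 0.0, rate))
    total = t[-1] - t[0]
    best = 0.0
    i = 0
    n = len(rate)
    while i < n:
        if not slow[i]:
            i += 1
            continue
        j = i
        s0 = 0.0
        while j < n and slow[j]:
            s = sign[j]
            if s != 0.0 and s0 != 0.0 and s != s0:
                break
            if s != 0.0:
                s0 = s
            j += 1
        # the stretch covers samples i .. j-1+w of the original trace
        span = t[min(j - 1 + w, len(t) - 1)] - t[i]
        if span > 0 and s0 != 0.0:
            net = abs(sm[min(j - 1 + w, len(sm) - 1)] - sm[i]) / span
            if min_rate <= net <= max_rate:
                best = max(best, span)
        i = max(j, i + 1)
    return float(best / total) if total > 0 else 0.0


def classify_dive(
    series: pd.DataFrame,
    record: dict,
    seafloor_depth_m: float | None = None,
    params: ClassifierParams | None = None,
) -> str:
    """Hierarchical four-type classification of one dive.

    Order: (1) drift if a monotone segment of at least ``drift_min_fraction``
    of the dive has vertical rate below ``drift_max_rate_m_s``; (2) benthic
    foraging if the maximum depth tracks the seafloor within the tolerance
    and there is a real bottom phase; (3) pelagic foraging if the bottom
    phase carries at least one wiggle; (4) otherwise transit.
    """
    params = params or ClassifierParams()
    d = series["depth_m"].to_numpy(float)[record["i_start"] : record["i_end"]]
    t = series["time_s"].to_numpy(float)[record["i_start"] : record["i_end"]]
    bottom_fraction = record["bottom_time_min"] / record["duration_min"] if record["duration_min"] else 0.0
    if _drift_segment_fraction(d, t, params.drift_max_rate_m_s) >= params.drift_min_fraction:
        return "drift"
    if seafloor_depth_m is not None and seafloor_depth_m > 0:
        if (
            abs(record["max_depth_m"] - seafloor_depth_m) <= params.benthic_tolerance * seafloor_depth_m
            and bottom_fraction >= params.transit_max_bottom_fraction
        ):
            return "benthic_foraging"
    if record["n_excursions"] >= 1 and bottom_fraction >= params.transit_max_bottom_fraction:
        return "pelagic_foraging"
    return "transit"


def assign_diel(timestamp, lat: float, lon: float, params: ClassifierParams | None = None) -> str:
    """Day/night label from the solar zenith angle at the dive midpoint."""
    if lat is None or lon is None or not np.isfinite(lat) or not np.isfinite(lon):
        raise ValueError("diel assignment needs a georeferenced dive")
    params = params or ClassifierParams()
    zen = float(solar_zenith_deg(np.datetime64(timestamp), lat, lon))
    return "day" if zen <= params.day_zenith_deg else "night"


def georeference_dives(dives: pd.DataFrame, hourly: pd.DataFrame,
                       clamp_margin_h: float = 2.0) -> pd.DataFrame:
    """Interpolate the hourly track to each dive's midpoint time.

    Dives slightly outside the track span (within ``clamp_margin_h``) are
    clamped to the nearest endpoint; anything farther is flagged
    ``unplaced`` with NaN coordinates rather than extrapolated.
    """
    ts = hourly["timestamp"].to_numpy().astype("datetime64[s]").astype(float)
    lat = hourly["lat"].to_numpy(float)
    lon = hourly["lon"].to_numpy(float)
    out = dives.copy()
    mid = out["mid_timestamp"].to_numpy().astype("datetime64[s]").astype(float)
    margin = clamp_margin_h * 3600.0
    inside = (mid >= ts[0] - margin) & (mid <= ts[-1] + margin)
    out["lat"] = np.where(inside, np.interp(mid, ts, lat), np.nan)
    out["lon"] = np.where(inside, np.interp(mid, ts, lon), np.nan)
    out["unplaced"] = ~inside
    return out


def process_deployment(
    series: pd.DataFrame,
    hourly: pd.DataFrame | None = None,
    seafloor_fn=None,
    detection: DiveDetectionParams | None = None,
    classifier: ClassifierParams | None = None,
    start_time=None,
    apply_zero_offset: bool = True,
) -> pd.DataFrame:
    """Full dive pipeline for one deployment's depth series.

    Subsample to 8 s, zero-offset correct, detect, compute metrics,
    georeference (if an hourly track is given), classify against the local
    seafloor (``seafloor_fn(lat, lon) -> m``) and assign diel labels.
    Returns one row per dive.
    """
    detection = detection or DiveDetectionParams()
    classifier = classifier or ClassifierParams()
    work = series
    t = work["time_s"].to_numpy(float)
    if len(t) > 1:
        src = float(np.median(np.diff(t)))
        if src < detection.subsample_interval_s - 1e-9:
            work = subsample_depth(work, detection.subsample_interval_s)
    if apply_zero_offset:
        work = zero_offset_correct(work, detection)
    segs = detect_dives(work, detection)
    if start_time is None and "timestamp" in series.columns:
        start_time = series["timestamp"].iloc[0]
    rows = []
    for seg in segs:
        rec = dive_metrics(work, seg, classifier)
        if start_time is not None:
            rec["mid_timestamp"] = np.datetime64(start_time) + np.timedelta64(
                int((rec["start_s"] + rec["end_s"]) / 2.0), "s"
            )
        rows.append(rec)
    dives = pd.DataFrame(rows)
    if dives.empty:
        return dives
    if hourly is not None and "mid_timestamp" in dives.columns:
        dives = georeference_dives(dives, hourly)
    else:
        dives["lat"] = np.nan
        dives["lon"] = np.nan
        dives["unplaced"] = True
    types = []
    diel = []
    seafloors = []
    for _, rec in dives.iterrows():
        sf = None
        if seafloor_fn is not None:
            sf = float(seafloor_fn(rec["lat"], rec["lon"]))
            if not np.isfinite(sf):
                sf = None
        seafloors.append(sf if sf is not None else np.nan)
        types.append(classify_dive(work, rec, sf, classifier))
        if "mid_timestamp" in dives.columns and np.isfinite(rec["lat"]):
            diel.append(assign_diel(rec["mid_timestamp"], rec["lat"], rec["lon"], classifier))
        else:
            diel.append("day")
    dives["seafloor_depth_m"] = seafloors
    dives["dive_type"] = types
    dives["diel"] = diel
    return dives
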