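"""ARGOS track filtering and state-space smoothing to hourly positions.

The raw satellite fixes are truncated to the at-sea trip, cleaned with a
speed/distance/angle filter (default thresholds 12 km/h and 160 deg), and
smoothed with a continuous-time correlated random walk (integrated
Ornstein-Uhlenbeck velocity) Kalman filter/smoother fitted by maximum
likelihood per deployment.  Smoothing happens in a planar azimuthal-
equidistant projection centred on the colony; measurement noise is set
per ARGOS location class, with a globally fitted scale so that clean
tracks are interpolated essentially exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geometry import AzimuthalEquidistant, haversine_km, turning_angle_deg
from .synthetic_data import DEFAULT_ARGOS_ERROR_SD_KM


@dataclass
class FilterParams:
    """Speed/distance/angle filter thresholds."""

    max_speed_kmh: float = 12.0
    min_turning_angle_deg: float = 160.0
    use_alternate: bool = True

    def __post_init__(self):
        if self.max_speed_kmh <= 0:
            raise ValueError("max speed must be positive")
        if not 0.0 < self.min_turning_angle_deg <= 180.0:
            raise ValueError("turning angle must be in (0, 180]")


def truncate_trip(fixes: pd.DataFrame, departure, arrival) -> pd.DataFrame:
    """Keep fixes within [departure, arrival]; error on an empty window."""
    departure = np.datetime64(departure)
    arrival = np.datetime64(arrival)
    if departure >= arrival:
        raise ValueError("departure must precede arrival")
    ts = fixes["timestamp"].to_numpy().astype("datetime64[s]")
    keep = (ts >= departure) & (ts <= arrival)
    out = fixes.loc[keep].sort_values("timestamp").reset_index(drop=True)
    if out.empty:
        raise ValueError("no fixes within the trip window: malformed deployment")
    return out


def _hours(ts: np.ndarray) -> np.ndarray:
    return (ts.astype("datetime64[s]") - ts[0].astype("datetime64[s]")).astype(
        "timedelta64[s]"
    ).astype(float) / 3600.0


def _speeds_kmh(lat, lon, th):
    dt = np.diff(th)
    dt = np.where(dt <= 0, 1e-6, dt)
    return haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:]) / dt


def sda_filter(fixes: pd.DataFrame, params: FilterParams | None = None) -> pd.DataFrame:
    """Speed/distance/angle filter over a single deployment's fixes.

    A fix is removed when either adjacent great-circle speed exceeds the
    maximum, or it forms a sharp spike: inner turning angle below the
    threshold with both adjacent displacements larger than an hour's
    travel at the maximum speed.  When a flagged fix carries an alternate
    (mirror) ARGOS solution that satisfies both criteria, the alternate
    replaces it instead.  Removal is iterative (worst offender first in
    each pass) until the track is clean; the filter is idempotent.
    """
    params = params or FilterParams()
    if len(fixes) < 3:
        raise ValueError("need at least 3 fixes to filter")
    df = fixes.sort_values("timestamp").reset_index(drop=True).copy()
    has_alt = params.use_alternate and {"alt_lat", "alt_lon"}.issubset(df.columns)

    def _offender(lat, lon, th):
        """Index of the next fix to treat, or None when the track is clean."""
        n = len(lat)
        sp = _speeds_kmh(lat, lon, th)
        if n >= 3:
            ang = turning_angle_deg(lat[:-2], lon[:-2], lat[1:-1], lon[1:-1], lat[2:], lon[2:])
            d_in = haversine_km(lat[:-2], lon[:-2], lat[1:-1], lon[1:-1])
            d_out = haversine_km(lat[1:-1], lon[1:-1], lat[2:], lon[2:])
            lim_in = params.max_speed_kmh * np.maximum(np.diff(th)[:-1], 0.1)
            lim_out = params.max_speed_kmh * np.maximum(np.diff(th)[1:], 0.1)
            spike = (ang < params.min_turning_angle_deg) & (d_in > lim_in) & (d_out > lim_out)
            if spike.any():
                return int(np.flatnonzero(spike)[0]) + 1
        fast = np.flatnonzero(sp > params.max_speed_kmh)
        if fast.size == 0:
            return None
        i = int(fast[0])
        # fast segment i -> i+1: blame the endpoint whose mean speed to its
        # neighbours is larger (an erroneous fix is fast on both sides)
        def mean_speed(j):
            s = []
            if j > 0:
                s.append(sp[j - 1])
            if j < n - 1:
                s.append(sp[j])
            return float(np.mean(s))

        return i if mean_speed(i) >= mean_speed(i + 1) else i + 1

    def _fix_ok(lat, lon, th, j):
        """Would fix j be clean (speeds and angle) in this configuration?"""
        n = len(lat)
        if j > 0:
            dt = max(th[j] - th[j - 1], 1e-6)
            if haversine_km(lat[j - 1], lon[j - 1], lat[j], lon[j]) / dt > params.max_speed_kmh:
                return False
        if j < n - 1:
            dt = max(th[j + 1] - th[j], 1e-6)
            if haversine_km(lat[j], lon[j], lat[j + 1], lon[j + 1]) / dt > params.max_speed_kmh:
                return False
        if 0 < j < n - 1:
            ang = float(
                turning_angle_deg(
                    lat[j - 1], lon[j - 1], lat[j], lon[j], lat[j + 1], lon[j + 1]
                )
            )
            d_in = haversine_km(lat[j - 1], lon[j - 1], lat[j], lon[j])
            d_out = haversine_km(lat[j], lon[j], lat[j + 1], lon[j + 1])
            lim_in = params.max_speed_kmh * max(th[j] - th[j - 1], 0.1)
            lim_out = params.max_speed_kmh * max(th[j + 1] - th[j], 0.1)
            if ang < params.min_turning_angle_deg and d_in > lim_in and d_out > lim_out:
                return False
        return True

    for _ in range(3 * len(df)):
        lat = df["lat"].to_numpy(float)
        lon = df["lon"].to_numpy(float)
        th = _hours(df["timestamp"].to_numpy())
        i = _offender(lat, lon, th)
        if i is None:
            break
        if has_alt and np.isfinite(df.at[i, "alt_lat"]):
            lat2, lon2 = lat.copy(), lon.copy()
            lat2[i], lon2[i] = float(df.at[i, "alt_lat"]), float(df.at[i, "alt_lon"])
            if _fix_ok(lat2, lon2, th, i):
                df.at[i, "lat"], df.at[i, "lon"] = lat2[i], lon2[i]
                df.at[i, "alt_lat"] = np.nan
                df.at[i, "alt_lon"] = np.nan
                continue
        df = df.drop(index=i).reset_index(drop=True)
        if len(df) < 3:
            break
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# continuous-time correlated random walk smoother
# ---------------------------------------------------------------------------


def _ctcrw_matrices(dt: float, beta: float, sigma2: float):
    """Transition and process-noise matrices of the IOU model over dt hours."""
    e = np.exp(-beta * dt)
    T = np.array([[1.0, (1.0 - e) / beta], [0.0, e]])
    q11 = (sigma2 / beta**2) * (dt - 2.0 * (1.0 - e) / beta + (1.0 - e * e) / (2.0 * beta))
    q12 = (sigma2 / beta**2) * (1.0 - e) ** 2 / 2.0
    q22 = sigma2 * (1.0 - e * e) / (2.0 * beta)
    Q = np.array([[q11, q12], [q12, q22]])
    return T, Q


def _kalman(times, zx, zy, r_sd, beta, sigma2, obs_mask, smooth=False):
    """Joint x/y Kalman filter (shared gain) over merged time points.

    Returns the negative log-likelihood and, if ``smooth``, RTS-smoothed
    states and covariances at every time point.
    """
    n = len(times)
    m = np.zeros((n, 2, 2))  # per-axis state [pos, vel]: m[t, axis, comp]
    P = np.zeros((n, 2, 2))
    mp = np.zeros((n, 2, 2))
    Pp = np.zeros((n, 2, 2))
    Ts = np.zeros((n, 2, 2))
    first = int(np.flatnonzero(obs_mask)[0])
    x = np.array([[zx[first], 0.0], [zy[first], 0.0]])  # rows: axis
    C = np.diag([max(r_sd[first] ** 2, 1.0), 25.0])
    nll = 0.0
    for t in range(n):
        if t == 0:
            dt = 1e-6
        else:
            dt = max(times[t] - times[t - 1], 1e-6)
        T, Q = _ctcrw_matrices(dt, beta, sigma2)
        Ts[t] = T
        x = x @ T.T
        C = T @ C @ T.T + Q
        mp[t] = x
        Pp[t] = C
        if obs_mask[t]:
            R = r_sd[t] ** 2
            S = C[0, 0] + R
            K = C[:, 0] / S
            vx = zx[t] - x[0, 0]
            vy = zy[t] - x[1, 0]
            nll += 0.5 * (2.0 * np.log(2.0 * np.pi * S) + (vx * vx + vy * vy) / S)
            x = x + np.outer(np.array([vx, vy]), K).reshape(2, 2) * 1.0
            C = C - np.outer(K, C[0, :])
            C = 0.5 * (C + C.T)
        m[t] = x
        P[t] = C
    if not smooth:
        return nll, None, None
    ms = m.copy()
    Ps = P.copy()
    for t in range(n - 2, -1, -1):
        G = P[t] @ Ts[t + 1].T @ np.linalg.inv(Pp[t + 1])
        ms[t] = m[t] + (ms[t + 1] - mp[t + 1]) @ G.T
        Ps[t] = P[t] + G @ (Ps[t + 1] - Pp[t + 1]) @ G.T
    return nll, ms, Ps


def smooth_track(
    fixes: pd.DataFrame,
    colony: tuple | None = None,
    step_h: float = 1.0,
    error_sd_km: dict | None = None,
    max_fit_points: int = 600,
) -> pd.DataFrame:
    """Smooth filtered fixes to regular hourly positions with uncertainty.

    Fits the velocity autocorrelation ``beta``, process variance and a
    measurement-error scale by maximum likelihood through the Kalman
    filter, then RTS-smooths over the union of fix times and on-the-hour
    prediction times.  Falls back to piecewise-linear interpolation (with
    a warning) if the fit fails to produce finite likelihoods.

    Returns columns: timestamp, lat, lon, sd_km, speed_kmh.
    """
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes to smooth")
    df = fixes.sort_values("timestamp").reset_index(drop=True)
    ts = df["timestamp"].to_numpy().astype("datetime64[s]")
    # hours relative to the wall-clock hour floor so predictions land on the hour
    t0 = ts[0].astype("datetime64[h]").astype("datetime64[s]")
    th = (ts - t0).astype("timedelta64[s]").astype(float) / 3600.0
    if th[-1] - th[0] < 2.0:
        raise ValueError("fixes must span at least 2 hours")
    error_sd_km = error_sd_km or DEFAULT_ARGOS_ERROR_SD_KM
    if colony is None:
        colony = (float(df["lat"].mean()), float(df["lon"].mean()))
    proj = AzimuthalEquidistant(*colony)
    zx, zy = proj.to_xy(df["lat"].to_numpy(float), df["lon"].to_numpy(float))
    lc = df["lc"].astype(str).to_numpy() if "lc" in df.columns else np.full(len(df), "3")
    r_base = np.array([error_sd_km.get(c, 4.0) for c in lc])

    # collapse duplicate timestamps for conditioning
    keep = np.concatenate([[True], np.diff(th) > 1e-9])
    thf, zxf, zyf, rf = th[keep], zx[keep], zy[keep], r_base[keep]
    if len(thf) > max_fit_points:
        sel = np.linspace(0, len(thf) - 1, max_fit_points).round().astype(int)
        thf, zxf, zyf, rf = thf[sel], zxf[sel], zyf[sel], rf[sel]
    mask = np.ones(len(thf), dtype=bool)

    def nll(theta):
        beta, sig2, rscale = np.exp(theta)
        beta = min(max(beta, 1e-4), 50.0)
        sig2 = min(max(sig2, 1e-6), 1e4)
        rscale = min(max(rscale, 1e-4), 1e2)
        try:
            v, _, _ = _kalman(thf, zxf, zyf, rf * rscale, beta, sig2, mask)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12
        return v if np.isfinite(v) else 1e12

    best = None
    for x0 in ([np.log(0.5), np.log(10.0), 0.0], [np.log(2.0), np.log(2.0), np.log(0.3)]):
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"maxiter": 200, "xatol": 1e-3, "fatol": 1e-3})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        warnings.warn("CTCRW fit failed; falling back to linear interpolation")
        return _linear_hourly(t0, proj, th, zx, zy, step_h)

    beta, sig2, rscale = np.exp(best.x)
    hours_out = np.arange(np.ceil(th[0]), np.floor(th[-1]) + 1e-9, step_h)
    all_t = np.unique(np.concatenate([th[keep], hours_out]))
    obs_mask = np.isin(all_t, th[keep])
    zx_a = np.zeros(len(all_t))
    zy_a = np.zeros(len(all_t))
    r_a = np.full(len(all_t), 1.0)
    pos = np.searchsorted(all_t, th[keep])
    zx_a[pos], zy_a[pos], r_a[pos] = zx[keep], zy[keep], r_base[keep] * rscale
    _, ms, Ps = _kalman(all_t, zx_a, zy_a, r_a, beta, sig2, obs_mask, smooth=True)
    out_idx = np.searchsorted(all_t, hours_out)
    lat, lon = proj.to_latlon(ms[out_idx, 0, 0], ms[out_idx, 1, 0])
    sd = np.sqrt(np.maximum(Ps[out_idx, 0, 0], 0.0))
    out = pd.DataFrame(
        {
            "timestamp": t0 + (hours_out * 3600.0).round().astype("timedelta64[s]"),
            "lat": lat,
            "lon": lon,
            "sd_km": sd,
        }
    )
    out["speed_kmh"] = transit_speeds(out)
    return out


def _linear_hourly(t0, proj, th, zx, zy, step_h):
    hours_out = np.arange(np.ceil(th[0]), np.floor(th[-1]) + 1e-9, step_h)
    xi = np.interp(hours_out, th, zx)
    yi = np.interp(hours_out, th, zy)
    lat, lon = proj.to_latlon(xi, yi)
    out = pd.DataFrame(
        {
            "timestamp": t0 + (hours_out * 3600.0).round().astype("timedelta64[s]"),
            "lat": lat,
            "lon": lon,
            "sd_km": np.nan,
        }
    )
    out["speed_kmh"] = transit_speeds(out)
    return out


def transit_speeds(hourly: pd.DataFrame) -> np.ndarray:
    """Great-circle speed (km/h) to the next position; last repeats previous."""
    if len(hourly) < 2:
        raise ValueError("need at least 2 positions")
    lat = hourly["lat"].to_numpy(float)
    lon = hourly["lon"].to_numpy(float)
    th = _hours(hourly["timestamp"].to_numpy())
    sp = _speeds_kmh(lat, lon, th)
    return np.concatenate([sp, [sp[-1]]])


def dedupe_repeat_deployments(deployments: pd.DataFrame, mode: str = "first",
                              seed: int | None = None) -> pd.DataFrame:
    """One trip per animal: keep the first (default) or a seeded random one."""
    if "animal_id" not in deployments.columns:
        return deployments
    if mode == "first":
        return deployments.sort_values("start").groupby("animal_id", as_index=False).first()
    rng = np.random.default_rng(seed)
    return (
        deployments.groupby("animal_id", as_index=False)
        .apply(lambda g: g.iloc[rng.integers(0, len(g))])
        .reset_index(drop=True)
    )
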