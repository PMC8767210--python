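"""Tag-fate attribution, last-location metrics and mortality modelling.

A transmitter that stops at sea is either a mechanical failure or a
death.  The attribution follows a fixed decision order: (1) transmitted
until colony return -> survived; (2) stopped but the animal was resighted
in a later season -> tag failure; (3) stopped, never resighted, but the
location-quality record degrades over the final transmitting month
(one-sided Mann-Kendall on daily best-class rank) -> tag failure;
(4) stopped, never resighted, quality trend-free -> presumed dead.

Deaths are modelled with binomial logit GLMs over all covariate subsets
containing sex (sex, trip, tagging year), ranked by AIC with a
delta-AIC <= 7 shortlist, likelihood-ratio tested against the null and
checked with a Hosmer-Lemeshow goodness-of-fit test; sex-specific
mortality probabilities are estimated-marginal-mean style (averaged over
trip levels on the link scale) with Wald confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .geometry import haversine_km
from .foraging_analysis import distance_to_shelf

#: location classes from best to worst, and their ordinal rank (higher = better)
CLASS_RANK = {"3": 5, "2": 4, "1": 3, "0": 2, "A": 1, "B": 0}

OUTCOMES = ("survived_returned", "survived_resighted_later", "tag_failure", "died")


@dataclass
class TagFate:
    deployment_id: str
    outcome: str
    stopped_at_sea: bool
    resighted_later: bool
    quality_trend_p: float  # one-sided Mann-Kendall p toward degradation
    quality_degrading: bool
    trend_window_days: int


def mann_kendall_onesided(values: np.ndarray) -> float:
    """One-sided p for a *decreasing* monotone trend (Mann-Kendall).

    Kendall's tau between time index and value; the one-sided p toward
    decline is half the two-sided p when tau < 0, else its complement.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4 or np.ptp(v) == 0:
        return 1.0
    tau, p_two = stats.kendalltau(np.arange(len(v)), v)
    if not np.isfinite(tau):
        return 1.0
    return p_two / 2.0 if tau < 0 else 1.0 - p_two / 2.0


def attribute_tag_fate(
    transmission: pd.DataFrame,
    resights: list,
    trip_days: float,
    trend_window_days: int = 30,
    alpha: float = 0.05,
    return_margin_days: float = 1.5,
) -> TagFate:
    """Classify one deployment's tag fate.

    ``transmission`` has columns ``day`` and ``best_class`` (daily best
    ARGOS class); ``resights`` is any iterable of later sighting dates
    (contents unused beyond emptiness).  A tag is "stopped at sea" when
    its last transmission precedes the scheduled return by more than
    ``return_margin_days``.
    """
    if transmission.empty:
        raise ValueError("transmission record is empty")
    last_day = float(transmission["day"].max())
    did = str(transmission.get("deployment_id", pd.Series([""])).iloc[0]) if "deployment_id" in transmission else ""
    stopped = last_day < trip_days - return_margin_days
    ranks = transmission.sort_values("day")["best_class"].map(CLASS_RANK).to_numpy(float)
    window = ranks[-trend_window_days:]
    p = mann_kendall_onesided(window)
    degrading = p < alpha
    resighted = len(resights) > 0
    if not stopped:
        outcome = "survived_returned"
    elif resighted:
        outcome = "survived_resighted_later"
    elif degrading:
        outcome = "tag_failure"
    else:
        outcome = "died"
    return TagFate(
        deployment_id=did,
        outcome=outcome,
        stopped_at_sea=bool(stopped),
        resighted_later=resighted,
        quality_trend_p=float(p),
        quality_degrading=bool(degrading),
        trend_window_days=int(min(trend_window_days, len(ranks))),
    )


def attribute_cohort(
    cohort: pd.DataFrame, transmissions: dict, resights: dict, **kwargs
) -> pd.DataFrame:
    """Attribute every deployment; returns the cohort with outcome columns.

    ``died`` is the binary modelling response; tag failures (with or
    without a later resight) are coded as survived.
    """
    rows = []
    for _, r in cohort.iterrows():
        did = r["deployment_id"]
        fate = attribute_tag_fate(
            transmissions[did], resights.get(did, []), float(r["trip_days"]), **kwargs
        )
        mechanical = fate.outcome in ("survived_resighted_later", "tag_failure")
        rows.append(
            {
                **r.to_dict(),
                "outcome": fate.outcome,
                "stopped_at_sea": fate.stopped_at_sea,
                "mechanical_failure": fate.stopped_at_sea and mechanical,
                "died": int(fate.outcome == "died"),
            }
        )
    return pd.DataFrame(rows)


def cohort_accounting(attributed: pd.DataFrame) -> dict:
    """Per-sex and overall percentages of stopped / failed / dead tags."""
    out = {}
    n_all = len(attributed)
    for sex in ("male", "female"):
        sub = attributed[attributed["sex"] == sex]
        n = len(sub)
        out[f"{sex}_deployments"] = n
        out[f"{sex}_stopped"] = int(sub["stopped_at_sea"].sum())
        out[f"{sex}_failures"] = int(sub["mechanical_failure"].sum())
        out[f"{sex}_deaths"] = int(sub["died"].sum())
        if n:
            out[f"{sex}_pct_stopped"] = 100.0 * out[f"{sex}_stopped"] / n
            out[f"{sex}_pct_failures"] = 100.0 * out[f"{sex}_failures"] / n
            out[f"{sex}_pct_deaths"] = 100.0 * out[f"{sex}_deaths"] / n
    out["total_deployments"] = n_all
    out["pct_dead_overall"] = 100.0 * attributed["died"].sum() / n_all if n_all else np.nan
    out["pct_failures_overall"] = (
        100.0 * attributed["mechanical_failure"].sum() / n_all if n_all else np.nan
    )
    return out


# ---------------------------------------------------------------------------
# last-location metrics
# ---------------------------------------------------------------------------


@dataclass
class LastLocation:
    lat: float
    lon: float
    transit_rate_m_s: float
    shelf_distance_km: float
    ecoregion: str
    trip_portion: str  # outward | farthest point | return


def last_location_metrics(
    hourly: pd.DataFrame,
    colony: tuple,
    shelf_lats,
    shelf_lons,
    ecoregions=None,
    apex_fraction: float = 0.90,
) -> LastLocation:
    """Metrics at the final transmitted position.

    The trip portion splits at the "farthest point" plateau: hours with
    colony distance >= ``apex_fraction`` of the trip maximum.  A track
    that ends while colony distance is still climbing steadily (the
    realized maximum is simply where transmission stopped) is "outward";
    one ending inside an established plateau is "farthest point";
    anything after the plateau is "return".
    """
    if len(hourly) < 2:
        raise ValueError("need at least 2 positions")
    lat = hourly["lat"].to_numpy(float)
    lon = hourly["lon"].to_numpy(float)
    dist = haversine_km(lat, lon, colony[0], colony[1])
    apex = dist >= apex_fraction * dist.max()
    last_apex = int(np.flatnonzero(apex)[-1])
    i = len(hourly) - 1
    if apex[i]:
        tail = dist[max(0, i - 4) : i + 1]
        still_climbing = len(tail) > 1 and np.all(np.diff(tail) > 0)
        portion = "outward" if still_climbing else "farthest point"
    elif i > last_apex:
        portion = "return"
    else:
        portion = "outward"
    if "speed_kmh" in hourly.columns:
        rate = float(hourly["speed_kmh"].iloc[-1]) / 3.6
    else:
        dt_h = 1.0
        rate = float(haversine_km(lat[-2], lon[-2], lat[-1], lon[-1]) / dt_h) / 3.6
    region = "unassigned"
    if ecoregions is not None:
        from shapely.geometry import Point, shape

        if isinstance(ecoregions, dict) and ecoregions.get("type") == "FeatureCollection":
            polys = {
                f["properties"].get("name", str(i)): shape(f["geometry"])
                for i, f in enumerate(ecoregions["features"])
                if f["geometry"]["type"] in ("Polygon", "MultiPolygon")
            }
        else:
            polys = dict(ecoregions)
        pt = Point(lon[-1], lat[-1])
        for name, poly in polys.items():
            if poly.covers(pt):
                region = name
                break
    return LastLocation(
        lat=float(lat[-1]),
        lon=float(lon[-1]),
        transit_rate_m_s=max(rate, 0.0),
        shelf_distance_km=distance_to_shelf(lat[-1], lon[-1], shelf_lats, shelf_lons),
        ecoregion=region,
        trip_portion=portion,
    )


# ---------------------------------------------------------------------------
# logistic mortality models
# ---------------------------------------------------------------------------


@dataclass
class MortalityModel:
    terms: tuple
    formula: str
    result: object  # fitted statsmodels GLM
    aic: float
    delta_aic: float = np.nan
    lrt_p_vs_null: float = np.nan
    hosmer_lemeshow_p: float = np.nan
    wald_terms: pd.DataFrame | None = None


def hosmer_lemeshow(y: np.ndarray, p: np.ndarray, g: int = 10):
    """Hosmer-Lemeshow goodness-of-fit: chi2 over g fitted-risk groups."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, g)
    chi2 = 0.0
    used = 0
    for idx in groups:
        if len(idx) == 0:
            continue
        o1 = y[idx].sum()
        e1 = p[idx].sum()
        n = len(idx)
        e0 = n - e1
        if e1 < 1e-12 or e0 < 1e-12:
            continue
        chi2 += (o1 - e1) ** 2 / e1 + ((n - o1) - e0) ** 2 / e0
        used += 1
    df = max(used - 2, 1)
    return float(chi2), float(stats.chi2.sf(chi2, df)), df


def fit_mortality_models(
    cohort: pd.DataFrame, delta_aic_cut: float = 7.0, hl_groups: int = 10
) -> list[MortalityModel]:
    """Fit and rank all logistic models containing sex.

    Candidate terms: sex (always), trip, year (categorical).  Models are
    IRLS maximum-likelihood binomial logit fits ranked by AIC; the best
    model carries a likelihood-ratio test against the intercept-only
    null, a Hosmer-Lemeshow fit test and a per-term Wald ANOVA.
    Complete separation falls back to an L2-penalized fit, flagged in the
    formula string.
    """
    if cohort["died"].nunique() < 2:
        raise ValueError("need both outcome levels to model mortality")
    optional = [t for t in ("trip", "year") if t in cohort.columns and cohort[t].nunique() > 1]
    term_sets = []
    for r in range(len(optional) + 1):
        for extra in combinations(optional, r):
            term_sets.append(("sex",) + extra)
    models = []
    data = cohort.copy()
    data["year"] = data.get("year", pd.Series(dtype=object)).astype(str)
    import warnings as _warnings

    for terms in term_sets:
        rhs = " + ".join(f"C({t})" for t in terms)
        formula = f"died ~ {rhs}"
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                fit = smf.glm(formula, data=data, family=sm.families.Binomial()).fit()
            if not np.all(np.isfinite(fit.params)) or np.any(np.abs(fit.params) > 15):
                raise ValueError("separation")
            aic = float(fit.aic)
        except Exception:
            # complete separation: keep a penalized fit for inspection but
            # rank it last (no proper likelihood)
            fit = smf.glm(formula, data=data, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-4, L1_wt=0.0
            )
            formula += "  [penalized: separation]"
            aic = np.inf
        models.append(MortalityModel(terms=terms, formula=formula, result=fit, aic=aic))
    models.sort(key=lambda m: (not np.isfinite(m.aic), m.aic))
    if not np.isfinite(models[0].aic):
        raise ValueError("all candidate models are separated; cannot rank by AIC")
    best_aic = models[0].aic
    null = smf.glm("died ~ 1", data=data, family=sm.families.Binomial()).fit()
    for m in models:
        m.delta_aic = m.aic - best_aic
    best = models[0]
    lrt = 2.0 * (best.result.llf - null.llf)
    df = best.result.df_model
    best.lrt_p_vs_null = float(stats.chi2.sf(lrt, max(df, 1)))
    p_hat = np.asarray(best.result.fittedvalues, dtype=float)
    _, best.hosmer_lemeshow_p, _ = hosmer_lemeshow(data["died"].to_numpy(), p_hat, hl_groups)
    try:
        wt = best.result.wald_test_terms(scalar=False)
        best.wald_terms = wt.table
    except Exception:
        best.wald_terms = None
    return models


def mortality_probability(model: MortalityModel, cohort: pd.DataFrame, sex: str) -> dict:
    """Sex-specific mortality probability with a 95% Wald CI.

    Estimated-marginal-means style: the linear predictor is averaged over
    the levels of the other factors (equal weight) at the given sex, the
    Wald interval is formed on the link scale and back-transformed.
    """
    data = cohort.copy()
    data["year"] = data.get("year", pd.Series(dtype=object)).astype(str)
    others = [t for t in model.terms if t != "sex"]
    grids = [[sex]] + [sorted(data[t].astype(str).unique()) for t in others]
    from itertools import product

    rows = [dict(zip(["sex"] + others, combo)) for combo in product(*grids)]
    frame = pd.DataFrame(rows)
    for t in ("trip", "year"):
        if t not in frame.columns and t in data.columns:
            frame[t] = data[t].astype(str).iloc[0]
    import patsy

    design = patsy.dmatrix(
        model.result.model.data.design_info, frame, return_type="dataframe"
    )
    X = design.to_numpy(float)
    w = np.full(len(X), 1.0 / len(X))
    eta = float(w @ (X @ model.result.params))
    cov = np.asarray(model.result.cov_params())
    var = float(w @ X @ cov @ X.T @ w)
    se = np.sqrt(max(var, 0.0))
    lo, hi = eta - 1.959963984540054 * se, eta + 1.959963984540054 * se
    expit = lambda z: 1.0 / (1.0 + np.exp(-z))
    return {"probability": expit(eta), "ci_low": expit(lo), "ci_high": expit(hi)}


def logistic_nll(beta, X, y):
    """Negative binomial-logit log-likelihood (grid-search oracle hook)."""
    eta = X @ np.asarray(beta, dtype=float)
    return float(np.sum(np.log1p(np.exp(eta))) - y @ eta)


def compare_death_locations(
    male: pd.DataFrame, female: pd.DataFrame, metrics=("shelf_distance_km", "transit_rate_m_s")
) -> pd.DataFrame:
    """Mann-Whitney comparisons of last-location metrics between sexes,
    Bonferroni-corrected over the metric family."""
    if len(male) < 3 or len(female) < 3:
        raise ValueError("need at least 3 deaths per sex")
    rows = []
    m = len(metrics)
    for metric in metrics:
        a = male[metric].to_numpy(float)
        b = female[metric].to_numpy(float)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "metric": metric,
                "u_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "p_adjusted": min(1.0, m * float(res.pvalue)),
                "male_median": float(np.median(a)),
                "female_median": float(np.median(b)),
            }
        )
    return pd.DataFrame(rows)
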