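"""Behavioural-strategy discovery: PCA, Ward clustering and discrimination.

The 31-variable trip profiles are centred and scaled, sparse rows
(majority missing) dropped and remaining gaps filled by regularized
iterative PCA imputation.  Correlation-matrix PCA retains components with
eigenvalue >= 1 that explain >= 10% of variance; Ward (D2) hierarchical
clustering of the retained scores with silhouette-based selection of k
yields the strategies; per-variable Gaussian identity-link models with
AICc ranking, likelihood-ratio and Wald tests, and Tukey-adjusted
pairwise contrasts describe what separates them.  Day/night comparisons
use Welch t-tests when both sides pass Shapiro-Wilk normality, otherwise
Mann-Whitney, Bonferroni-corrected across the family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class PCAResult:
    loadings: np.ndarray  # (p, p), columns are components
    scores: np.ndarray  # (n, p)
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    retained: np.ndarray  # indices of retained components
    columns: list = field(default_factory=list)


@dataclass
class ClusterSolution:
    linkage_tree: np.ndarray
    k: int
    assignments: np.ndarray  # 1..k
    silhouette_by_k: dict
    wss_by_k: dict


@dataclass
class DiscriminationResult:
    variable: str
    aicc: float
    null_aicc: float
    lrt_stat: float
    lrt_p: float
    wald_f: float
    wald_p: float
    cluster_means: dict
    contrasts: pd.DataFrame  # pair, estimate, p_adj
    unstable: bool = False


def _standardize(X: np.ndarray):
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column")
    return (X - mu) / sd, mu, sd


def _retained_set(eigenvalues: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    return np.flatnonzero((eigenvalues >= 1.0) & (fractions >= 0.10))


def assemble_matrix(
    summaries: pd.DataFrame,
    variables: list | None = None,
    max_missing_fraction: float = 0.50,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Numeric matrix for PCA: drop sparse rows, impute the rest.

    Rows missing more than half of the variables are excluded.  Remaining
    missing cells are imputed by regularized iterative PCA: standardize,
    fill gaps with the column mean, then alternate a shrunken low-rank
    reconstruction (rank = the eigenvalue/variance retention rule, at
    least 1) with re-imputing the missing cells until the imputed values
    change by less than ``tol``.
    """
    if variables is None:
        from .foraging_analysis import TRIP_SUMMARY_VARIABLES

        variables = [c for c in TRIP_SUMMARY_VARIABLES if c in summaries.columns]
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries")
    X = summaries[variables].to_numpy(float)
    frac_missing = np.isnan(X).mean(axis=1)
    keep = frac_missing <= max_missing_fraction
    if not keep.any():
        raise ValueError("all rows dropped as majority-missing")
    X = X[keep]
    idx = summaries.index[keep]
    miss = np.isnan(X)
    if not miss.any():
        return pd.DataFrame(X, index=idx, columns=variables)
    Z, mu, sd = _standardize(X)
    Z[miss] = 0.0
    n = Z.shape[0]
    prev = Z[miss].copy()
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        lam = s**2 / max(n - 1, 1)
        frac = lam / lam.sum()
        rank = max(1, len(_retained_set(lam, frac)))
        noise = s[rank:].mean() if len(s) > rank else 0.0
        s_shrunk = np.maximum(s[:rank] - noise, 0.0)
        Zhat = (U[:, :rank] * s_shrunk) @ Vt[:rank]
        Z[miss] = Zhat[miss]
        if np.max(np.abs(Z[miss] - prev)) < tol:
            break
        prev = Z[miss].copy()
    out = Z * sd + mu
    return pd.DataFrame(out, index=idx, columns=variables)


def run_pca(matrix: pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA with the eigenvalue/variance retention rule.

    Components are sign-fixed so the loading of largest magnitude on each
    component is positive.
    """
    X = matrix.to_numpy(float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    Z, _, _ = _standardize(X)
    n = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    lam = s**2 / (n - 1)
    frac = lam / lam.sum()
    loadings = Vt.T
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = Z @ loadings
    cols = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else []
    return PCAResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=lam,
        variance_fractions=frac,
        retained=_retained_set(lam, frac),
        columns=cols,
    )


def cluster(scores: np.ndarray, k_range=range(2, 9)) -> ClusterSolution:
    """Ward (D2) hierarchical clustering with silhouette-selected k.

    Euclidean dissimilarity on the retained PC scores; k maximizes the
    average silhouette over ``k_range`` (ties to the smaller k); the
    within-cluster sum of squares per k is reported for elbow reading.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    n = S.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations to cluster")
    tree = linkage(S, method="ward")
    sil = {}
    wss = {}
    for k in k_range:
        if k >= n:
            continue
        lab = fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(silhouette_score(S, lab))
        wss[k] = float(
            sum(((S[lab == c] - S[lab == c].mean(axis=0)) ** 2).sum() for c in np.unique(lab))
        )
    best_k = min(sil, key=lambda k: (-round(sil[k], 12), k))
    return ClusterSolution(
        linkage_tree=tree,
        k=best_k,
        assignments=fcluster(tree, t=best_k, criterion="maxclust"),
        silhouette_by_k=sil,
        wss_by_k=wss,
    )


def _aicc(llf: float, k_params: int, n: int) -> float:
    aic = -2.0 * llf + 2.0 * k_params
    denom = n - k_params - 1
    return aic + (2.0 * k_params * (k_params + 1) / denom if denom > 0 else np.inf)


def discriminate(values: np.ndarray, assignments: np.ndarray, variable: str = "") -> DiscriminationResult:
    """How well does one trip variable separate the clusters?

    Gaussian identity-link GLM with cluster as the (categorical)
    predictor, compared to the intercept-only null by AICc and a
    likelihood-ratio test; Wald ANOVA for the cluster term; Tukey-HSD
    pairwise contrasts between cluster means.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(assignments)
    ok = np.isfinite(y)
    y, g = y[ok], g[ok]
    levels = np.unique(g)
    if len(levels) < 2 or any((g == c).sum() < 2 for c in levels):
        unstable = True
    else:
        unstable = False
    n = len(y)
    X = pd.get_dummies(pd.Categorical(g), drop_first=True).to_numpy(float)
    X = sm.add_constant(X)
    model = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
    null = sm.GLM(y, np.ones((n, 1)), family=sm.families.Gaussian()).fit()
    # +1 for the dispersion parameter in the information criteria
    k_full = X.shape[1] + 1
    lrt = 2.0 * (model.llf - null.llf)
    df = X.shape[1] - 1
    lrt_p = float(stats.chi2.sf(lrt, df)) if df > 0 else 1.0
    # Wald ANOVA for the cluster term == one-way ANOVA F on the group means
    contrast = np.zeros((df, X.shape[1]))
    contrast[:, 1:] = np.eye(df)
    wald = model.wald_test(contrast, scalar=False, use_f=True)
    wald_f = float(np.squeeze(wald.statistic))
    wald_p = float(np.squeeze(wald.pvalue))
    means = {int(c) if np.issubdtype(levels.dtype, np.integer) else c: float(y[g == c].mean())
             for c in levels}
    if not unstable:
        from itertools import combinations

        tuk = pairwise_tukeyhsd(y, g)
        contrasts = pd.DataFrame(
            {
                "pair": [f"{a}-{b}" for a, b in combinations(tuk.groupsunique, 2)],
                "estimate": tuk.meandiffs,
                "p_adj": tuk.pvalues,
            }
        )
    else:
        contrasts = pd.DataFrame(columns=["pair", "estimate", "p_adj"])
    return DiscriminationResult(
        variable=variable,
        aicc=_aicc(model.llf, k_full, n),
        null_aicc=_aicc(null.llf, 2, n),
        lrt_stat=float(lrt),
        lrt_p=lrt_p,
        wald_f=wald_f,
        wald_p=wald_p,
        cluster_means=means,
        contrasts=contrasts,
        unstable=unstable,
    )


def discrimination_table(matrix: pd.DataFrame, assignments: np.ndarray) -> pd.DataFrame:
    """Run ``discriminate`` for every column; one row per variable."""
    rows = []
    for col in matrix.columns:
        r = discriminate(matrix[col].to_numpy(), assignments, col)
        rows.append(
            {
                "variable": r.variable,
                "aicc": r.aicc,
                "null_aicc": r.null_aicc,
                "delta_aicc_vs_null": r.aicc - r.null_aicc,
                "lrt_p": r.lrt_p,
                "wald_f": r.wald_f,
                "wald_p": r.wald_p,
                **{f"mean_cluster_{c}": m for c, m in r.cluster_means.items()},
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DielTest:
    test: str  # welch_t | mann_whitney
    statistic: float
    p_value: float
    p_adjusted: float
    n_day: int
    n_night: int


def diel_compare(day: np.ndarray, night: np.ndarray, family_size: int = 1,
                 alpha_normal: float = 0.05) -> DielTest:
    """Day/night comparison with normality-gated test choice.

    Shapiro-Wilk on each side; both normal -> Welch two-sample t-test,
    otherwise Mann-Whitney.  Constant vectors force the nonparametric
    branch.  ``family_size`` applies a Bonferroni correction for the set
    of comparisons run together.
    """
    d = np.asarray(day, dtype=float)
    nn = np.asarray(night, dtype=float)
    d = d[np.isfinite(d)]
    nn = nn[np.isfinite(nn)]
    if len(d) < 3 or len(nn) < 3:
        raise ValueError("need at least 3 values per side")
    const = np.ptp(d) == 0 or np.ptp(nn) == 0
    if const:
        normal = False
    else:
        normal = (stats.shapiro(d).pvalue > alpha_normal) and (
            stats.shapiro(nn).pvalue > alpha_normal
        )
    if normal:
        res = stats.ttest_ind(d, nn, equal_var=False)
        name = "welch_t"
    else:
        if np.ptp(np.concatenate([d, nn])) == 0:
            res = type("R", (), {"statistic": float(len(d) * len(nn) / 2), "pvalue": 1.0})
        else:
            res = stats.mannwhitneyu(d, nn, alternative="two-sided")
        name = "mann_whitney"
    p = float(res.pvalue)
    return DielTest(
        test=name,
        statistic=float(res.statistic),
        p_value=p,
        p_adjusted=min(1.0, family_size * p),
        n_day=len(d),
        n_night=len(nn),
    )
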