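"""Statistical screening of the 22 features.

The screening follows the repeated-measures design of the actor study:
per-feature cell means over action x actor combinations are modeled by a
one-way repeated-measures GLM across the five conditions, preceded by
outlier removal (|x - mean| > 2.5 SD) and accompanied by Mauchly's
sphericity test (with Greenhouse-Geisser correction on violation) and
Lilliefors-type Kolmogorov-Smirnov normality checks.  Significant omnibus
effects are followed by Bonferroni-adjusted paired comparisons encoded as
per-condition superscript letters (a = gentle, b = neutral, c = rude,
d = slow, e = fast).  A principal-axis factor analysis with varimax
rotation summarizes the significant features into components.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from vitalkin.errors import DataError, DegenerateInputError
from vitalkin.features import FEATURE_NAMES
from vitalkin.synthetic import CONDITIONS

log = logging.getLogger(__name__)

CONDITION_LETTERS = {"gentle": "a", "neutral": "b", "rude": "c", "slow": "d", "fast": "e"}

#: omnibus p-values of the published screening of the two-actor recordings;
#: thresholding them at .05 yields the canonical 17-feature classifier input
REFERENCE_SCREENING_PVALUES = {
    "Vmx": 1e-4, "Amx": 1e-4, "Jmx": 1e-4, "S": 0.01,
    "%POSmx": 0.30, "POSmx": 0.30, "%POWmx": 0.30, "POWmx": 0.30,
    "AL": 1e-4, "CWmx": 0.01,
    "SMmx": 1e-4, "SMa": 1e-4, "SMsd": 1e-4,
    "VWmx": 1e-4, "VWa": 1e-4, "VWsd": 1e-4,
    "AACmx": 1e-4, "AACa": 0.01, "AACsd": 1e-4,
    "AEmx": 0.01, "AEa": 0.30, "AEsd": 0.01,
}

#: the 17 features with established condition effects, in table order
SIGNIFICANT_FEATURES = tuple(
    f for f in FEATURE_NAMES if REFERENCE_SCREENING_PVALUES[f] < 0.05
)


def remove_outliers(values, k: float = 2.5):
    """Single-pass outlier removal: drop values with |x - mean| > k SD.

    Mean and SD are those of the full input; an all-identical input (SD = 0)
    removes nothing.  Returns ``(retained_values, removed_indices)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DataError(f"need >= 3 values for outlier screening, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy(), np.array([], dtype=int)
    keep = np.abs(x - x.mean()) <= k * sd
    removed = np.nonzero(~keep)[0]
    if removed.size:
        log.info("outlier removal: dropped %d of %d values", removed.size, x.size)
    return x[keep], removed


def build_cell_means(
    table: pd.DataFrame, feature: str, outlier_k: float = 2.5
) -> pd.DataFrame:
    """Action x actor cell means of one feature, columns = conditions.

    Outliers are removed per condition across the cell means (cells whose
    mean deviates > ``outlier_k`` SD from the condition mean become NaN).
    """
    cells = (
        table.pivot_table(
            index=["action", "actor"], columns="condition", values=feature, aggfunc="mean"
        )
        .reindex(columns=list(CONDITIONS))
    )
    for cond in cells.columns:
        col = cells[cond].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        if ok.sum() < 3:
            continue
        sd = col[ok].std(ddof=1)
        if sd == 0:
            continue
        bad = ok & (np.abs(col - col[ok].mean()) > outlier_k * sd)
        if bad.any():
            cells.loc[bad, cond] = np.nan
    return cells


@dataclass
class GlmResult:
    """One feature's repeated-measures screening outcome."""

    feature: str
    F: float
    p: float
    df1: float
    df2: float
    gg_applied: bool
    gg_epsilon: float
    mauchly_w: float
    mauchly_p: float
    ks_p: dict  # condition -> normality p-value
    n_subjects: int
    condition_means: dict
    posthoc_letters: dict = field(default_factory=dict)


def rm_anova_F(X: np.ndarray):
    """One-way repeated-measures ANOVA from a subjects x conditions matrix.

    Returns ``(F, df1, df2)`` with the textbook sum-of-squares partition
    (subjects, conditions, residual).
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    grand = X.mean()
    ss_cond = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((X - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        return 0.0, df1, df2
    return float(ms_cond / ms_err), df1, df2


def _gg_epsilon(X: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    k = X.shape[1]
    S = np.cov(X, rowvar=False)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (S.mean(axis=1) ** 2).sum() + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _mauchly(X: np.ndarray):
    """Mauchly's sphericity test; returns (W, p)."""
    n, k = X.shape
    # orthonormal contrasts of the k conditions
    C = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    Y = X @ C
    S = np.cov(Y, rowvar=False)
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 1e-30, None)
    d = k - 1
    W = float(np.prod(eig) / (eig.mean() ** d))
    chi_df = d * (d + 1) / 2 - 1
    f = 1 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    p = float(sps.chi2.sf(max(chi2, 0.0), chi_df))
    return W, p


def rm_glm(cells: pd.DataFrame, feature: str = "", alpha: float = 0.05) -> GlmResult:
    """Repeated-measures GLM of one feature's cell-means table.

    Rows with a missing condition are dropped (listwise); sphericity is
    assessed with Mauchly's test and the Greenhouse-Geisser-corrected
    p-value is reported when it is violated (p < .05).  Per-condition
    Lilliefors normality p-values are attached.
    """
    complete = cells.dropna()
    n_drop = len(cells) - len(complete)
    if n_drop:
        log.warning("%s: %d incomplete rows dropped from the GLM", feature, n_drop)
    if len(complete) < 3:
        raise DataError(f"{feature}: only {len(complete)} complete rows, need >= 3")
    X = complete.to_numpy(dtype=float)
    n, k = X.shape
    F, df1, df2 = rm_anova_F(X)
    if np.allclose(X.std(axis=0), 0) or F == 0.0:
        p = 1.0
        mauchly_w, mauchly_p, eps, gg = 1.0, 1.0, 1.0, False
    else:
        mauchly_w, mauchly_p = _mauchly(X)
        gg = mauchly_p < alpha
        eps = _gg_epsilon(X)
        if gg:
            p = float(sps.f.sf(F, eps * df1, eps * df2))
        else:
            p = float(sps.f.sf(F, df1, df2))
    from statsmodels.stats.diagnostic import lilliefors

    ks_p = {}
    for cond in cells.columns:
        col = complete[cond].to_numpy(dtype=float)
        if col.size < 4 or col.std(ddof=1) == 0:
            ks_p[cond] = np.nan  # normality test needs >= 4 observations
        else:
            ks_p[cond] = float(lilliefors(col, dist="norm")[1])
    return GlmResult(
        feature=feature,
        F=F,
        p=p,
        df1=df1,
        df2=df2,
        gg_applied=bool(gg),
        gg_epsilon=float(eps),
        mauchly_w=float(mauchly_w),
        mauchly_p=float(mauchly_p),
        ks_p=ks_p,
        n_subjects=n,
        condition_means={c: float(complete[c].mean()) for c in cells.columns},
    )


def posthoc_pairwise(cells: pd.DataFrame, omnibus_significant: bool = True, alpha: float = 0.05):
    """Bonferroni-adjusted paired t-tests over all condition pairs.

    Returns a letter-code mapping: for each condition, the letters of the
    conditions it differs from significantly.  Run on a non-significant
    omnibus the result is empty (with a warning).
    """
    letters = {c: "" for c in cells.columns}
    if not omnibus_significant:
        log.warning("post-hoc comparisons requested on a non-significant omnibus test")
        return letters
    complete = cells.dropna()
    pairs = list(itertools.combinations(cells.columns, 2))
    m = len(pairs)
    for c1, c2 in pairs:
        x, y = complete[c1].to_numpy(float), complete[c2].to_numpy(float)
        if np.allclose(x - y, (x - y)[0]):
            continue  # zero-variance difference: no test
        p = sps.ttest_rel(x, y).pvalue * m
        if p < alpha:
            letters[c1] += CONDITION_LETTERS[c2]
            letters[c2] += CONDITION_LETTERS[c1]
    return {c: "".join(sorted(v)) for c, v in letters.items()}


def screen_features(
    table: pd.DataFrame, features=FEATURE_NAMES, outlier_k: float = 2.5, alpha: float = 0.05
):
    """Run the full 22-GLM screening; returns (results list, summary frame).

    The summary frame mirrors the published layout: one row per feature
    with per-condition means and letter codes, F and p.
    """
    results = []
    rows = []
    for feat in features:
        cells = build_cell_means(table, feat, outlier_k)
        res = rm_glm(cells, feat, alpha)
        res.posthoc_letters = posthoc_pairwise(cells, res.p < alpha, alpha)
        results.append(res)
        row = {"feature": feat}
        for cond in CONDITIONS:
            row[cond] = res.condition_means.get(cond, np.nan)
            row[f"{cond}_letters"] = res.posthoc_letters.get(cond, "")
        row.update(
            F=res.F, p=res.p, gg_applied=res.gg_applied, mauchly_p=res.mauchly_p,
            significant=res.p < alpha,
        )
        rows.append(row)
    return results, pd.DataFrame(rows)


def compare_actors(table: pd.DataFrame, features=FEATURE_NAMES, alpha: float = 0.05):
    """Paired t-test per feature between the two actors over matched
    action x condition cell means; returns a frame with t, p, significance."""
    actors = sorted(table["actor"].unique())
    if len(actors) != 2:
        raise DataError(f"actor comparison needs exactly 2 actors, found {actors}")
    a1, a2 = actors
    rows = []
    for feat in features:
        piv = table.pivot_table(
            index=["action", "condition"], columns="actor", values=feat, aggfunc="mean"
        )
        miss = piv.index[piv.isna().any(axis=1)]
        if len(miss):
            raise DataError(
                f"{feat}: unmatched action x condition cells between actors: "
                f"{[tuple(i) for i in miss[:5]]}"
            )
        t = sps.ttest_rel(piv[a1], piv[a2])
        rows.append({"feature": feat, "t": float(t.statistic), "p": float(t.pvalue),
                     "significant": bool(t.pvalue < alpha)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# principal-axis factor analysis with varimax rotation
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    loadings: pd.DataFrame  # features x components
    eigenvalues: np.ndarray  # of the correlation matrix
    n_components: int
    communalities: pd.Series
    representatives: list  # one feature per component, by largest |loading|


def _varimax(L: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation of a loading matrix."""
    p, k = L.shape
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p))
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return L @ R


def principal_factor_analysis(
    table: pd.DataFrame,
    features=SIGNIFICANT_FEATURES,
    max_iter: int = 200,
    tol: float = 1e-6,
    ridge: float = 1e-8,
) -> FactorModel:
    """Principal-axis factoring of the feature correlation matrix.

    Components are retained by the eigenvalue-one criterion on the
    correlation matrix, loadings are varimax-rotated, and each component's
    representative is the feature with the largest absolute loading
    (features already chosen for an earlier component are skipped).
    """
    X = table[list(features)].to_numpy(dtype=float)
    if X.shape[0] < 50:
        raise DataError(f"factor analysis needs >= 50 rows, got {X.shape[0]}")
    R = np.corrcoef(X, rowvar=False)
    if not np.isfinite(R).all():
        raise DegenerateInputError("correlation matrix has undefined entries")
    eigvals = np.linalg.eigvalsh(R)[::-1]
    n_comp = max(int((eigvals > 1.0).sum()), 1)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        Rinv = np.linalg.inv(R + ridge * np.eye(len(R)))
        log.warning("singular correlation matrix; ridge %.0e applied", ridge)
    h = 1.0 - 1.0 / np.diag(Rinv)  # squared multiple correlations
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h)
        w, V = np.linalg.eigh(Rr)
        idx = np.argsort(w)[::-1][:n_comp]
        L = V[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
        h_new = np.clip((L**2).sum(axis=1), 0, 0.999)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            break
        h = h_new
    L = _varimax(L)
    # orient each component so its dominant loading is positive
    signs = np.sign(L[np.abs(L).argmax(axis=0), np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    L = L * signs
    # order components by explained variance
    order = np.argsort(-(L**2).sum(axis=0))
    L = L[:, order]
    loadings = pd.DataFrame(
        L, index=list(features), columns=[f"C{i + 1}" for i in range(n_comp)]
    )
    reps = []
    taken = set()
    for c in loadings.columns:
        for feat in loadings[c].abs().sort_values(ascending=False).index:
            if feat not in taken:
                reps.append(feat)
                taken.add(feat)
                break
    return FactorModel(
        loadings=loadings,
        eigenvalues=eigvals,
        n_components=n_comp,
        communalities=pd.Series(h, index=list(features)),
        representatives=reps,
    )
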