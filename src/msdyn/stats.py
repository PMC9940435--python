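"""Covariate-adjusted group comparison and trait correlation.

The inferential recipe: regress each feature on nuisance covariates (age,
sex, and mean framewise displacement for fMRI-derived features) by ordinary
least squares, compare the residuals between groups with a two-sample t test,
confirm with a label-permutation test, control the false discovery rate over
each analysis family with Benjamini–Hochberg, and report Cohen's d.  Trait
associations use partial Pearson correlations with Fisher-z confidence
intervals (degrees of freedom reduced by the number of covariates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "residualize",
    "two_sample_t",
    "welch_t_from_summary",
    "chi_square_2x2",
    "permutation_test",
    "permutation_pvalues",
    "fdr_bh",
    "partial_pearson",
    "midas_category",
    "subgroup_split",
    "compare_features",
    "correlate_features",
]


@dataclass
class ComparisonResult:
    feature: str
    t: float
    p_param: float
    p_perm: float
    d: float
    q: float
    n_per_group: tuple[int, int]


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    ci95: tuple[float, float]
    p: float
    n: int
    covariates: list[str]


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept plus covariate columns, dropping collinear columns with a warning."""
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        keep = [0]
        for j in range(1, X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        warnings.warn(
            f"design is rank-deficient; dropped {X.shape[1] - len(keep)} "
            "collinear column(s)", stacklevel=3)
        X = X[:, keep]
    return X


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of y on [intercept, covariates].

    With no covariates this is centering.  Residuals are orthogonal to every
    design column, and residualizing them again on the same design is the
    identity (projection idempotence).
    """
    y = np.asarray(y, dtype=float)
    X = _design(covariates, y.shape[0])
    if y.shape[0] <= X.shape[1]:
        raise ValueError("need more subjects than design columns")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return np.nan
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def two_sample_t(x: np.ndarray, y: np.ndarray, kind: str = "pooled"
                 ) -> tuple[float, float, float]:
    """Two-sample t test plus Cohen's d (pooled-SD effect size).

    ``kind='pooled'`` assumes equal variances (the default for feature
    comparisons); ``kind='welch'`` does not.  Returns (t, two-sided p, d).
    Identical constant groups have zero pooled variance; t and d are NaN and
    a warning is emitted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if kind not in ("pooled", "welch"):
        raise ValueError("kind must be 'pooled' or 'welch'")
    d = _cohens_d(x, y)
    if np.isnan(d) and x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        warnings.warn("zero pooled variance; t undefined", stacklevel=2)
        return np.nan, np.nan, np.nan
    res = sps.ttest_ind(x, y, equal_var=(kind == "pooled"))
    return float(res.statistic), float(res.pvalue), d


def welch_t_from_summary(m1: float, sem1: float, m2: float, sem2: float) -> float:
    """Welch-type t from group means and standard errors of the mean.

    t = (m1 - m2) / sqrt(sem1^2 + sem2^2) — the only t computable when a
    table reports mean ± SEM without raw data.
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    return float((m1 - m2) / np.hypot(sem1, sem2))


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 count table.

    Rows are groups, columns categories: [[a, b], [c, d]].  Returns
    (chi2, p).  A zero row or column margin leaves the statistic undefined.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if table.sum() == 0:
        raise ValueError("empty table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("zero margin; chi-square undefined", stacklevel=2)
        return np.nan, np.nan
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def permutation_test(values: np.ndarray, group_labels: np.ndarray,
                     n_iter: int = 10000, seed: int | None = None) -> float:
    """Label-permutation p-value for a two-group mean difference.

    The observed statistic is the pooled two-sample t; group labels are
    shuffled ``n_iter`` times and the two-sided p-value is
    (1 + #{|t_perm| >= |t_obs|}) / (n_iter + 1).  Residualize the values
    first to adjust for covariates (the covariate fit is not re-estimated
    per permutation).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two groups required")
    mask = labels == groups[0]
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    t_obs = _t_from_mask(values, mask)
    rng = np.random.default_rng(seed)
    count = 0
    # vectorized in blocks: permute indicator matrix
    block = 2000
    done = 0
    while done < n_iter:
        b = min(block, n_iter - done)
        perm = np.argsort(rng.random((b, values.size)), axis=1)[:, :n1]
        masks = np.zeros((b, values.size), dtype=bool)
        np.put_along_axis(masks, perm, True, axis=1)
        t_perm = _t_from_masks(values, masks)
        count += int(np.sum(np.abs(t_perm) >= np.abs(t_obs) - 1e-12))
        done += b
    return (1 + count) / (n_iter + 1)


def _t_from_mask(v: np.ndarray, mask: np.ndarray) -> float:
    return _t_from_masks(v, mask[None, :])[0]


def _t_from_masks(v: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled t for each boolean row mask (group 1) against its complement."""
    n = v.size
    n1 = masks.sum(axis=1)
    n2 = n - n1
    s = v.sum()
    ss = np.sum(v ** 2)
    s1 = masks @ v
    ss1 = masks @ (v ** 2)
    m1 = s1 / n1
    m2 = (s - s1) / n2
    var1 = (ss1 - n1 * m1 ** 2) / (n1 - 1)
    var2 = (ss - ss1 - n2 * m2 ** 2) / (n2 - 1)
    sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def permutation_pvalues(values: np.ndarray, group_labels: np.ndarray,
                        n_iter: int = 10000, seed: int | None = None
                        ) -> np.ndarray:
    """Permutation p-values for many features at once, sharing the shuffles.

    ``values`` is subjects x features; the same label permutations are
    applied to every column (preserving the features' joint structure),
    which makes a replicate-level calibration study tractable.  Returns one
    two-sided p-value per feature, with the same (1 + count)/(n_iter + 1)
    estimator as :func:`permutation_test`.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == len(group_labels):
        V = values
    else:
        V = values.T
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two groups required")
    mask = labels == groups[0]
    n, m = V.shape
    n1 = int(mask.sum())
    t_obs = _t_matrix(V, mask[None, :])[0]
    rng = np.random.default_rng(seed)
    count = np.zeros(m)
    done = 0
    block = 2000
    while done < n_iter:
        b = min(block, n_iter - done)
        perm = np.argsort(rng.random((b, n)), axis=1)[:, :n1]
        masks = np.zeros((b, n), dtype=bool)
        np.put_along_axis(masks, perm, True, axis=1)
        t_perm = _t_matrix(V, masks)
        count += np.sum(np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12, axis=0)
        done += b
    return (1 + count) / (n_iter + 1)


def _t_matrix(V: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled t for each (mask row, feature column) pair: B x m."""
    n, m = V.shape
    n1 = masks.sum(axis=1)[:, None]
    n2 = n - n1
    s = V.sum(axis=0)[None, :]
    ss = np.sum(V ** 2, axis=0)[None, :]
    s1 = masks.astype(float) @ V
    ss1 = masks.astype(float) @ (V ** 2)
    m1 = s1 / n1
    m2 = (s - s1) / n2
    var1 = (ss1 - n1 * m1 ** 2) / (n1 - 1)
    var2 = (ss - ss1 - n2 * m2 ** 2) / (n2 - 1)
    sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns (rejected flags, adjusted p-values); adjusted p-values are
    monotone in the raw ranks and a hypothesis is never rejected unless its
    raw p is at or below ``alpha``.  NaN p-values are passed through
    unrejected.
    """
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(pvals)
    if np.any((pvals[ok] < 0) | (pvals[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected = np.zeros(pvals.shape, dtype=bool)
    adjusted = np.full(pvals.shape, np.nan)
    if ok.any():
        rej, adj, _, _ = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")
        rejected[ok] = rej
        adjusted[ok] = adj
    return rejected, adjusted


def partial_pearson(x: np.ndarray, y: np.ndarray,
                    covariates: np.ndarray | None = None,
                    names: tuple[str, str] = ("x", "y"),
                    covariate_names: list[str] | None = None) -> CorrelationResult:
    """Partial Pearson correlation with Fisher-z 95% confidence interval.

    Both variables are residualized on the covariates; r is the Pearson
    correlation of the residuals.  The CI uses Fisher's z with standard
    error 1/sqrt(n - k - 3) and the two-sided p comes from the t
    distribution with n - k - 2 degrees of freedom (k covariates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    k = 0 if covariates is None else np.atleast_2d(np.asarray(covariates)).reshape(n, -1).shape[1]
    if n <= k + 3:
        raise ValueError("too few observations for the covariate count")
    rx = residualize(x, covariates)
    ry = residualize(y, covariates)
    if rx.std() == 0 or ry.std() == 0:
        warnings.warn("degenerate residuals; correlation undefined", stacklevel=2)
        return CorrelationResult(names, np.nan, (np.nan, np.nan), np.nan, n,
                                 covariate_names or [])
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r ** 2))
        p = float(2 * sps.t.sf(abs(t), df))
    se = 1.0 / np.sqrt(n - k - 3)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zc = sps.norm.ppf(0.975)
    lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    if abs(r) == 1.0:
        lo, hi = (r if r > 0 else -1.0), (1.0 if r > 0 else r)
    return CorrelationResult(names, r, (float(lo), float(hi)), p, n,
                             covariate_names or [])


#: MIDAS disability grades, by total score.
_MIDAS_BINS = [
    (0, 5, "little_or_none"),
    (6, 10, "mild"),
    (11, 20, "moderate"),
]


def midas_category(score: float) -> str:
    """Migraine Disability Assessment grade for a total score.

    0–5 little or no disability, 6–10 mild, 11–20 moderate, >=21 severe.
    """
    if score < 0:
        raise ValueError("MIDAS score must be nonnegative")
    if float(score) != int(score):
        raise ValueError("MIDAS score must be integer-valued")
    score = int(score)
    for lo, hi, tag in _MIDAS_BINS:
        if lo <= score <= hi:
            return tag
    return "severe"


def subgroup_split(table: pd.DataFrame, rule: str
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a patient table into two clinical subgroups.

    Rules: ``duration`` (disease duration > 5 vs <= 5 years), ``attacks``
    (> 2 vs <= 2 attacks per month), ``pain_side`` (left vs the rest),
    ``medication`` (the two most frequent tags).  A subgroup smaller than 3
    triggers a warning that downstream comparisons should be skipped.
    """
    if rule == "duration":
        mask = table["duration_years"] > 5
    elif rule == "attacks":
        mask = table["attacks_per_month"] > 2
    elif rule == "pain_side":
        mask = table["pain_side"] == "left"
    elif rule == "medication":
        tags = table["medication"].value_counts().index.tolist()
        if len(tags) < 2:
            warnings.warn("only one medication tag present", stacklevel=2)
            return table.copy(), table.iloc[0:0].copy()
        mask = table["medication"] == tags[0]
        table = table[table["medication"].isin(tags[:2])]
        mask = mask.loc[table.index]
    else:
        raise ValueError(f"unknown subgroup rule {rule!r}")
    g1, g2 = table[mask].copy(), table[~mask].copy()
    if len(g1) < 3 or len(g2) < 3:
        warnings.warn(
            f"subgroup under rule {rule!r} has fewer than 3 subjects; "
            "comparison should be skipped", stacklevel=2)
    return g1, g2


def compare_features(table: pd.DataFrame, features: list[str],
                     covariates: list[str] | None = None,
                     group_column: str = "group",
                     groups: tuple[str, str] = ("patient", "control"),
                     n_iter: int = 10000, alpha: float = 0.05,
                     seed: int | None = None) -> pd.DataFrame:
    """Covariate-adjusted group comparison of a family of features.

    Each feature is residualized on the covariates across all subjects, the
    residuals are compared between groups (pooled t, Cohen's d), the result
    is confirmed by a label-permutation test, and BH-FDR is applied over the
    family (on the parametric p-values).  Returns one row per feature with
    columns (feature, t, p_param, p_perm, d, q, significant, n1, n2).
    Set ``n_iter=0`` to skip the permutation stage (p_perm = NaN).
    """
    cov = _covariate_matrix(table, covariates)
    lab = table[group_column].to_numpy()
    mask1 = lab == groups[0]
    mask2 = lab == groups[1]
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    rng = np.random.default_rng(seed)
    rows = []
    for feat in features:
        y = table[feat].to_numpy(dtype=float)
        resid = residualize(y, cov)
        t, p, d = two_sample_t(resid[mask1], resid[mask2], kind="pooled")
        if n_iter > 0:
            p_perm = permutation_test(resid[mask1 | mask2], lab[mask1 | mask2],
                                      n_iter=n_iter,
                                      seed=int(rng.integers(2 ** 31)))
        else:
            p_perm = np.nan
        rows.append((feat, t, p, p_perm, d, n1, n2))
    out = pd.DataFrame(rows, columns=["feature", "t", "p_param", "p_perm",
                                      "d", "n1", "n2"])
    rejected, q = fdr_bh(out["p_param"].to_numpy(), alpha=alpha)
    out["q"] = q
    out["significant"] = rejected
    return out


def correlate_features(table: pd.DataFrame, features: list[str], trait: str,
                       covariates: list[str] | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Partial Pearson correlation of each feature with a trait.

    Returns one row per feature with r, the Fisher 95% CI, raw p, BH-adjusted
    q and the significance flag (both raw and corrected p-values are kept —
    report whichever convention the analysis calls for).
    """
    cov = _covariate_matrix(table, covariates)
    y = table[trait].to_numpy(dtype=float)
    rows = []
    for feat in features:
        res = partial_pearson(table[feat].to_numpy(dtype=float), y, cov,
                              names=(feat, trait),
                              covariate_names=covariates or [])
        rows.append((feat, trait, res.r, res.ci95[0], res.ci95[1], res.p, res.n))
    out = pd.DataFrame(rows, columns=["feature", "trait", "r", "ci_lo",
                                      "ci_hi", "p", "n"])
    rejected, q = fdr_bh(out["p"].to_numpy(), alpha=alpha)
    out["q"] = q
    out["significant"] = rejected
    return out


def _covariate_matrix(table: pd.DataFrame, covariates: list[str] | None
                      ) -> np.ndarray | None:
    if not covariates:
        return None
    cols = []
    for c in covariates:
        col = table[c]
        if col.dtype == object or str(col.dtype) == "category":
            codes = pd.Categorical(col).codes.astype(float)
            cols.append(codes)
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)
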