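"""Nonparametric group statistics for connectivity summaries.

The battery mirrors common practice in clinical MEG connectivity work:
Mann-Whitney U tests for whole-brain and within-network PLI group
comparisons, a permutation test (independent-samples t statistic, group
labels permuted) for per-ROI comparisons, Spearman rank correlations with
clinical covariates, and an effect-modification (interaction) regression
in which a volume measure may change the PLI-covariate association
between groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sst
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors


@dataclass
class GroupComparison:
    statistic_u: float
    p_value: float
    n1: int
    n2: int
    direction: str  # "higher_in_x" | "lower_in_x" | "equal"


def mann_whitney(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U test (ties mid-ranked).

    ``statistic_u`` is the U of the first sample; exact p for small
    tie-free samples, normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        return GroupComparison(statistic_u=len(x) * len(y) / 2.0,
                               p_value=1.0, n1=len(x), n2=len(y),
                               direction="equal")
    res = sst.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    half = len(x) * len(y) / 2.0
    if res.statistic > half:
        direction = "higher_in_x"
    elif res.statistic < half:
        direction = "lower_in_x"
    else:
        direction = "equal"
    return GroupComparison(statistic_u=float(res.statistic),
                           p_value=float(res.pvalue),
                           n1=len(x), n2=len(y), direction=direction)


@dataclass
class PermutationResult:
    per_roi_t: np.ndarray
    per_roi_p: np.ndarray
    n_permutations: int
    corrected: str  # "none" | "maxstat"
    degenerate: np.ndarray  # flags ROIs with zero variance in both groups


def _t_stats(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column for each permutation row.

    ``values``: (n_subjects, n_roi); ``mask``: (n_perm, n_subjects) boolean,
    True marking group 1.  Returns (n_perm, n_roi).
    """
    n = values.shape[0]
    n1 = mask.sum(axis=1, keepdims=True).astype(float)
    n2 = n - n1
    m = mask.astype(float)
    s1 = m @ values
    s2 = values.sum(axis=0)[None, :] - s1
    q1 = m @ (values**2)
    q2 = (values**2).sum(axis=0)[None, :] - q1
    mean1, mean2 = s1 / n1, s2 / n2
    ss = (q1 - n1 * mean1**2) + (q2 - n2 * mean2**2)
    pooled = ss / (n1 + n2 - 2.0)
    denom = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean1 - mean2) / denom
    t[~np.isfinite(t)] = 0.0
    return t


def permutation_roi_test(
    values: np.ndarray,
    labels,
    n_perm: int = 5000,
    seed: int = 0,
    correction: str = "none",
) -> PermutationResult:
    """Permutation test of group differences, one test per ROI.

    A null distribution of two-sample t statistics is built by permuting
    group assignment; the two-sided p per ROI is the proportion of
    permuted ``|t|`` at or above the observed ``|t|``.  When all
    ``C(n, n1)`` group assignments number at most ``n_perm`` the null is
    enumerated exhaustively; otherwise ``n_perm`` random permutations are
    drawn and the identity permutation is included, so p >= 1/(n_perm+1).
    Optional max-statistic correction controls the family-wise error over
    ROIs.  Deterministic given ``seed``.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.ndim != 2:
        raise ValueError("values must be (n_subjects, n_roi)")
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("labels length mismatch")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    if correction not in ("none", "maxstat"):
        raise ValueError("correction must be 'none' or 'maxstat'")
    is1 = labels == uniq[0]
    n, n_roi = values.shape
    n1 = int(is1.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both groups must be non-empty")

    from math import comb
    n_exhaustive = comb(n, n1)
    if n_exhaustive <= n_perm:
        masks = np.zeros((n_exhaustive, n), dtype=bool)
        for row, idx in enumerate(combinations(range(n), n1)):
            masks[row, list(idx)] = True
        t_perm = _t_stats(values, masks)
        t_obs = _t_stats(values, is1[None, :])[0]
        p = (np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12).mean(axis=0)
        n_used = n_exhaustive
        t_null = t_perm
    else:
        if n_perm < 1000:
            raise ValueError("n_perm must be >= 1000")
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_perm, n), dtype=bool)
        for row in range(n_perm):
            masks[row, rng.choice(n, size=n1, replace=False)] = True
        t_obs = _t_stats(values, is1[None, :])[0]
        t_perm = _t_stats(values, masks)
        exceed = (np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12)
        p = (1.0 + exceed.sum(axis=0)) / (n_perm + 1.0)
        n_used = n_perm
        t_null = t_perm

    degenerate = np.array([np.ptp(values[:, j]) == 0.0
                           for j in range(n_roi)])
    p = np.where(degenerate, 1.0, p)

    if correction == "maxstat":
        max_null = np.abs(t_null).max(axis=1)
        if n_exhaustive <= n_perm:
            p = (max_null[:, None]
                 >= np.abs(t_obs)[None, :] - 1e-12).mean(axis=0)
        else:
            exceed = (max_null[:, None] >= np.abs(t_obs)[None, :] - 1e-12)
            p = (1.0 + exceed.sum(axis=0)) / (n_used + 1.0)
        p = np.where(degenerate, 1.0, p)

    return PermutationResult(per_roi_t=t_obs, per_roi_p=p,
                             n_permutations=n_used, corrected=correction,
                             degenerate=degenerate)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with the two-sided
    t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero rank variance")
    rho, p = sst.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class EffectModification:
    """Within-group slopes of outcome on a putative effect modifier."""

    slope_group1: float
    slope_group2: float
    beta_group1: float   # standardized
    beta_group2: float
    p_group1: float
    p_group2: float
    interaction_coef: float
    interaction_beta: float
    interaction_p: float
    groups: tuple[str, str]


def effect_modification_regression(y, volume, group) -> EffectModification:
    """Test whether a volume's association with the outcome differs by group.

    Fits ``y ~ group + volume + group x volume`` for the interaction term
    and group-specific OLS fits for per-group unstandardized B,
    standardized beta (B * SD(volume) / SD(y) within group) and p-values.
    """
    y = np.asarray(y, dtype=float)
    volume = np.asarray(volume, dtype=float)
    group = np.asarray(group)
    if not (len(y) == len(volume) == len(group)):
        raise ValueError("length mismatch")
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    uniq = np.unique(group)
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    for g in uniq:
        if np.ptp(volume[group == g]) == 0:
            raise ValueError(f"volume is constant within group {g!r} "
                             "(collinear design)")

    ind = (group == uniq[1]).astype(float)
    X = sm.add_constant(np.column_stack([ind, volume, ind * volume]))
    fit = sm.OLS(y, X).fit()
    inter = float(fit.params[3])
    inter_beta = inter * float(np.std(ind * volume, ddof=1)
                               / np.std(y, ddof=1))

    slopes, betas, pvals = [], [], []
    for g in uniq:
        sel = group == g
        Xg = sm.add_constant(volume[sel])
        fg = sm.OLS(y[sel], Xg).fit()
        b = float(fg.params[1])
        slopes.append(b)
        sd_y = np.std(y[sel], ddof=1)
        betas.append(b * float(np.std(volume[sel], ddof=1))
                     / sd_y if sd_y > 0 else 0.0)
        pvals.append(float(fg.pvalues[1]))

    return EffectModification(
        slope_group1=slopes[0], slope_group2=slopes[1],
        beta_group1=betas[0], beta_group2=betas[1],
        p_group1=pvals[0], p_group2=pvals[1],
        interaction_coef=inter, interaction_beta=inter_beta,
        interaction_p=float(fit.pvalues[3]),
        groups=(str(uniq[0]), str(uniq[1])))


def ks_normality(x) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of normality with estimated mean and SD
    (Lilliefors correction for the estimated parameters)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p)


def discard_outliers(x, y, threshold: float = 3.0):
    """Drop points with |studentized residual| > threshold in an OLS fit of
    y on x.  Returns (x_kept, y_kept, n_dropped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    resid = fit.get_influence().resid_studentized_external
    keep = np.abs(resid) <= threshold
    return x[keep], y[keep], int((~keep).sum())
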