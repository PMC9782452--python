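"""Two-group cohort statistics, age adjustment, FDR, and voxelwise maps.

The statistical layer of the study: low-risk vs high-risk comparisons with
Student's t / Wilcoxon rank-sum / chi-square, Pearson (or Spearman)
correlations overall and per group, age adjustment of uptake values to the
sample-mean age, Benjamini-Hochberg control of the false discovery rate,
and a simplified voxelwise two-sample t map with BH-FDR thresholding and
26-connected cluster labelling in place of full random-field parametric
mapping (which needs real registered brain volumes and is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparison:
    """Result of a two-group test on one variable."""

    variable: str
    test: str                 # "t" | "welch" | "wilcoxon" | "chi2"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float | None = None
    mean_b: float | None = None
    median_a: float | None = None
    median_b: float | None = None


def compare_groups(values, groups, test: str = "t",
                   variable: str = "value") -> GroupComparison:
    """Two-sided two-group comparison.

    ``test="t"`` is the pooled-variance Student form, ``"welch"`` the
    unequal-variance form, ``"wilcoxon"`` the rank-sum test (exact when
    both groups have <= 8 observations and no ties, normal approximation
    with tie correction otherwise), ``"chi2"`` a contingency test on
    category counts.  Missing values (NaN) are dropped pairwise.
    """
    values = np.asarray(values, dtype=float if test != "chi2" else object)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {labels}")
    a_all = values[groups == labels[0]]
    b_all = values[groups == labels[1]]

    if test == "chi2":
        cats = sorted(set(values.tolist()))
        table = np.array([[np.sum(a_all == c) for c in cats],
                          [np.sum(b_all == c) for c in cats]])
        res = sps.chi2_contingency(table, correction=False)
        return GroupComparison(variable, "chi2", float(res.statistic),
                               float(res.pvalue), len(a_all), len(b_all))

    a = a_all[~np.isnan(a_all.astype(float))]
    b = b_all[~np.isnan(b_all.astype(float))]
    if a.size == 0 or b.size == 0:
        raise ValueError("one group is empty after missing-data exclusion")

    if test in ("t", "welch"):
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test needs >= 2 subjects per group")
        if np.var(a) == 0 and np.var(b) == 0:
            # degenerate constant groups: no evidence against equality
            # when means agree, overwhelming evidence when they differ
            equal = np.mean(a) == np.mean(b)
            stat, p = (0.0, 1.0) if equal else (np.inf, 0.0)
        else:
            res = sps.ttest_ind(a, b, equal_var=(test == "t"))
            stat, p = float(res.statistic), float(res.pvalue)
    elif test == "wilcoxon":
        no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
        small = max(a.size, b.size) <= 8
        method = "exact" if (small and no_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(variable, test, stat, p, a.size, b.size,
                           mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
                           median_a=float(np.median(a)),
                           median_b=float(np.median(b)))


def age_adjust(values, ages) -> np.ndarray:
    """Adjust values to the sample-mean age by removing the linear age trend.

    Fits value = alpha + beta*age by least squares and returns
    ``value_i - beta*(age_i - mean(age))``; the adjusted mean equals the
    raw mean and the operation is idempotent.  With fewer than 3 subjects
    or zero age variance, values are returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape:
        raise ValueError("values and ages must have equal length")
    if values.size < 3 or np.var(ages) == 0:
        return values.copy()
    beta = np.polyfit(ages, values, 1)[0]
    return values - beta * (ages - ages.mean())


@dataclass
class CorrelationResult:
    stratum: str
    r: float
    p_value: float
    n: int


def correlate(x, y, by_group=None, method: str = "pearson") -> list[CorrelationResult]:
    """Correlation overall and, optionally, within each group.

    Pearson r with the t-based two-sided p value by default; Spearman as
    an option.  Pairs with a NaN in either variable are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")

    def one(label, xs, ys):
        ok = ~(np.isnan(xs) | np.isnan(ys))
        xs, ys = xs[ok], ys[ok]
        if xs.size < 3:
            raise ValueError(f"stratum {label!r}: need >= 3 complete pairs")
        if np.var(xs) == 0 or np.var(ys) == 0:
            raise ValueError(f"stratum {label!r}: zero variance")
        res = fn(xs, ys)
        return CorrelationResult(label, float(res.statistic), float(res.pvalue),
                                 int(xs.size))

    out = [one("overall", x, y)]
    if by_group is not None:
        by_group = np.asarray(by_group)
        for g in sorted(set(by_group.tolist())):
            sel = by_group == g
            out.append(one(str(g), x[sel], y[sel]))
    return out


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns ``(adjusted, significant_at_q)`` in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


@dataclass
class VoxelMapResult:
    """Voxelwise two-sample comparison of 3-D uptake maps."""

    t_map: np.ndarray
    p_map: np.ndarray
    fdr_q: float
    mask: np.ndarray          # True where BH-FDR significant
    cluster_labels: np.ndarray
    cluster_sizes: dict[int, int]


def voxelwise_group_map(maps_a, maps_b, q: float = 0.05,
                        test: str = "t") -> VoxelMapResult:
    """Per-voxel two-sample t map with BH-FDR mask and 26-connected clusters.

    ``maps_a``/``maps_b`` are stacks of same-shape 3-D arrays (one per
    subject).  Voxels with zero variance in both groups are excluded from
    the test and from the FDR family (their p is NaN, never significant).
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.ndim != 4 or b.ndim != 4 or a.shape[1:] != b.shape[1:]:
        raise ValueError("need two stacks of same-shape 3-D maps")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    res = sps.ttest_ind(a, b, axis=0, equal_var=(test == "t"))
    t_map = np.asarray(res.statistic, dtype=float)
    p_map = np.asarray(res.pvalue, dtype=float)
    testable = np.isfinite(p_map)  # zero-variance voxels give NaN
    mask = np.zeros(p_map.shape, dtype=bool)
    if testable.any():
        _, rej = bh_fdr(p_map[testable], q=q)
        mask[testable] = rej
    labels, n_clusters = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    sizes = {int(k): int(v) for k, v in
             zip(*np.unique(labels[labels > 0], return_counts=True))}
    return VoxelMapResult(t_map=t_map, p_map=p_map, fdr_q=q, mask=mask,
                          cluster_labels=labels, cluster_sizes=sizes)
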