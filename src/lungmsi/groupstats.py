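"""Group comparisons: exact Wilcoxon rank-sum tests and summary-statistic ANOVA.

The experimental unit is the animal (one section per animal), so group
comparisons run on 5-vs-5-sized samples where the exact (permutation-
enumeration) null of the Wilcoxon rank-sum statistic is both feasible and
appropriate.  The exact two-sided p-value is the doubled smaller tail of the
enumerated rank-sum distribution over all C(n_a + n_b, n_a) assignments of
the observed (possibly tied, mid-ranked) values, capped at 1.  For combined
sample sizes above 20 the test falls back to a tie-corrected normal
approximation.

Animal characteristics tables report only means ± SD per group, so the
one-way ANOVA is computed directly from summary statistics (group means,
SDs, ns), which is algebraically identical to the raw-data ANOVA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "SummaryStats",
    "wilcoxon_rank_sum_exact",
    "anova_oneway_from_summary",
    "tukey_hsd_from_summary",
    "compare_clump_stats",
    "compare_distance_bins",
]

#: largest combined sample size for which the exact null is enumerated
EXACT_ENUMERATION_LIMIT = 20


@dataclass
class GroupComparison:
    """Result of one two-group rank-sum comparison."""

    statistic_name: str
    group_a_values: list[float]
    group_b_values: list[float]
    rank_sum: float
    p_two_sided: float
    method: str  # "exact" or "normal-approx"


@dataclass
class SummaryStats:
    """Per-group summary statistics (sample SDs) for a one-way layout."""

    group_means: list[float]
    group_sds: list[float]
    group_ns: list[int]

    def validate(self) -> None:
        k = len(self.group_means)
        if k < 2 or len(self.group_sds) != k or len(self.group_ns) != k:
            raise ValueError("need >= 2 groups with matching means/sds/ns lengths")
        if any(sd < 0 for sd in self.group_sds):
            raise ValueError("standard deviations must be non-negative")
        if any(n < 2 for n in self.group_ns):
            raise ValueError("each group needs n >= 2")


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def wilcoxon_rank_sum_exact(
    a: list[float] | np.ndarray,
    b: list[float] | np.ndarray,
    statistic_name: str = "",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test, exact by full enumeration.

    Ties get mid-ranks.  Exact mode enumerates every assignment of the
    pooled ranks to group A, so the null distribution conditions on the
    observed tie pattern; p = min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    ranks = _midranks(np.concatenate([a, b]))
    w_obs = float(ranks[:na].sum())

    if n <= EXACT_ENUMERATION_LIMIT:
        total = math.comb(n, na)
        n_le = 0
        n_ge = 0
        eps = 1e-9
        for comb in itertools.combinations(range(n), na):
            w = float(ranks[list(comb)].sum())
            if w <= w_obs + eps:
                n_le += 1
            if w >= w_obs - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        method = "exact"
    else:
        # normal approximation with tie correction
        mean_w = na * (n + 1) / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var_w = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_w <= 0:
            p = 1.0
        else:
            # continuity-corrected two-sided tail
            z = (abs(w_obs - mean_w) - 0.5) / math.sqrt(var_w)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * stats.norm.sf(z))
        method = "normal-approx"

    return GroupComparison(
        statistic_name=statistic_name,
        group_a_values=[float(x) for x in a],
        group_b_values=[float(x) for x in b],
        rank_sum=w_obs,
        p_two_sided=float(p),
        method=method,
    )


def anova_oneway_from_summary(summary: SummaryStats) -> tuple[float, float]:
    """One-way ANOVA F and p from group means, sample SDs and ns.

    SSB = sum n_i (mean_i - grand_mean)^2, SSW = sum (n_i - 1) sd_i^2;
    F = (SSB / (k-1)) / (SSW / (N-k)) with the upper-tail F(k-1, N-k) p.
    """
    summary.validate()
    means = np.asarray(summary.group_means, dtype=float)
    sds = np.asarray(summary.group_sds, dtype=float)
    ns = np.asarray(summary.group_ns, dtype=float)
    k = means.size
    N = ns.sum()
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    if ssw <= 0:
        raise ValueError("zero pooled within-group variance; F undefined")
    F = (ssb / (k - 1)) / (ssw / (N - k))
    p = float(stats.f.sf(F, k - 1, N - k))
    return float(F), p


def tukey_hsd_from_summary(summary: SummaryStats) -> list[tuple[int, int, float, float]]:
    """Tukey HSD pairwise comparisons from summary statistics.

    Returns ``(i, j, mean_diff, p_adj)`` per group pair, using the
    studentized-range distribution with the pooled within-group variance.
    The original analysis names no post hoc method; this is a conventional
    choice, flagged as such.
    """
    summary.validate()
    means = np.asarray(summary.group_means, dtype=float)
    sds = np.asarray(summary.group_sds, dtype=float)
    ns = np.asarray(summary.group_ns, dtype=float)
    k = means.size
    N = float(ns.sum())
    df = N - k
    msw = float(((ns - 1) * sds**2).sum() / df)
    if msw <= 0:
        raise ValueError("zero pooled within-group variance")
    out = []
    for i, j in itertools.combinations(range(k), 2):
        diff = float(means[i] - means[j])
        se = math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df))
        out.append((i, j, diff, min(1.0, p)))
    return out


def compare_clump_stats(
    group_a_sections: list[tuple[int, float | None]],
    group_b_sections: list[tuple[int, float | None]],
) -> tuple[GroupComparison, GroupComparison]:
    """Wilcoxon comparisons of per-section clump count and median clump size.

    Inputs are ``(count, median_size)`` pairs, one per section/animal.
    Sections with no clumps have undefined median size and are excluded
    from the size comparison (their count 0 still enters the count test).
    """
    if len(group_a_sections) < 2 or len(group_b_sections) < 2:
        raise ValueError("need >= 2 sections per group")
    counts_a = [float(c) for c, _ in group_a_sections]
    counts_b = [float(c) for c, _ in group_b_sections]
    sizes_a = [float(m) for _, m in group_a_sections if m is not None]
    sizes_b = [float(m) for _, m in group_b_sections if m is not None]
    cmp_count = wilcoxon_rank_sum_exact(counts_a, counts_b, "clump_count")
    cmp_size = wilcoxon_rank_sum_exact(sizes_a, sizes_b, "clump_median_size_px")
    return cmp_count, cmp_size


def compare_distance_bins(
    group_a_profiles: list,
    group_b_profiles: list,
    use: str = "fractions",
) -> list[GroupComparison]:
    """Per-bin Wilcoxon comparisons of distance-from-border profiles.

    One exact test per 3-mm band, on per-animal bin fractions (or counts if
    ``use='counts'``); no multiplicity adjustment, matching the per-bin
    reporting convention.
    """
    if use not in ("fractions", "counts"):
        raise ValueError("use must be 'fractions' or 'counts'")
    if not group_a_profiles or not group_b_profiles:
        raise ValueError("both profile groups must be non-empty")
    edges = group_a_profiles[0].bin_edges_mm
    for prof in itertools.chain(group_a_profiles, group_b_profiles):
        if tuple(prof.bin_edges_mm) != tuple(edges):
            raise ValueError("profiles have mismatched bin edges")
    nbins = len(edges) - 1
    attr = "bin_fractions" if use == "fractions" else "bin_counts"
    results = []
    for i in range(nbins):
        va = [float(getattr(p, attr)[i]) for p in group_a_profiles]
        vb = [float(getattr(p, attr)[i]) for p in group_b_profiles]
        name = f"distance_{edges[i]:g}-{edges[i + 1]:g}mm_{use}"
        results.append(wilcoxon_rank_sum_exact(va, vb, name))
    return results
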