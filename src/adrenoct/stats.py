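"""Cohort statistics: normality-gated breed comparisons, REGWQ letter
grouping, paired side tests, weight-group tests and weight correlations.

The analysis battery is the one conventionally run on a multi-breed
morphometry cohort: Shapiro-Wilk decides between the parametric branch
(one-way ANOVA followed by the Ryan-Einot-Gabriel-Welsch studentized-range
multiple range test, REGWQ) and the nonparametric branch (Kruskal-Wallis
followed by pairwise two-sample Wilcoxon tests); side differences use the
paired t or Wilcoxon signed-rank test on left-right pairs; weight classes
are compared with the two-sample Wilcoxon test; and sizes are related to
body weight by Pearson correlation with a verbal strength band.

REGWQ is a step-down procedure on the ordered group means: the range of
``p`` adjacent ordered means is tested against a studentized-range critical
value at level ``alpha_p = 1 - (1-alpha)**(p/k)`` for ``p <= k-2`` and
``alpha_p = alpha`` for ``p in {k-1, k}``; a range that is not rejected is
declared homogeneous and none of its sub-ranges is tested further.  Letters
encode the maximal homogeneous ranges, so two groups sharing a letter were
never declared different.  Unequal group sizes enter through the harmonic
mean of the sizes in the tested range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from .indices import _metric_value, classify_correlation, classify_weight
from .records import DogRecord

__all__ = [
    "StatsReport",
    "GroupingResult",
    "normality_gate",
    "regwq",
    "compare_groups",
    "compare_breeds",
    "side_difference",
    "weight_group_difference",
    "correlate_with_weight",
    "apply_inclusion_criteria",
]

DEFAULT_ALPHA = 0.05


@dataclass
class StatsReport:
    """Outcome of one test: which test ran, its statistic and p-value."""

    metric: str
    test: str
    statistic: float
    p_value: float
    n: int
    normal: bool | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass
class GroupingResult:
    """Letter display of a multiple-range comparison.

    ``letters`` maps each group to the set of letters of the maximal
    homogeneous subsets containing it; ``subsets`` lists those subsets.
    Two groups share a letter iff some accepted (non-rejected) range
    contains both.
    """

    groups: list[str]
    means: dict[str, float]
    ns: dict[str, int]
    letters: dict[str, set[str]]
    subsets: list[tuple[str, ...]]

    @property
    def any_difference(self) -> bool:
        """True if some pair of groups shares no letter."""
        gs = self.groups
        return any(
            not (self.letters[a] & self.letters[b])
            for i, a in enumerate(gs) for b in gs[i + 1:]
        )

    def separated(self, set_a: "set[str]", set_b: "set[str]") -> bool:
        """True if no group in *set_a* shares a letter with any in *set_b*."""
        return all(
            not (self.letters[a] & self.letters[b]) for a in set_a for b in set_b
        )


def normality_gate(values, alpha: float = DEFAULT_ALPHA) -> bool:
    """Shapiro-Wilk gate: True (treat as normal) iff p >= alpha."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("normality gate needs at least 3 observations")
    if np.ptp(v) == 0:
        raise ValueError("degenerate sample: all values identical")
    return bool(sps.shapiro(v).pvalue >= alpha)


@lru_cache(maxsize=None)
def _q_crit(conf: float, p: int, df: int) -> float:
    return float(sps.studentized_range.ppf(conf, p, df))


def _letters_from_subsets(groups: list[str], subsets: list[tuple[str, ...]]):
    letters: dict[str, set[str]] = {g: set() for g in groups}
    for idx, sub in enumerate(subsets):
        sym = chr(ord("A") + idx) if idx < 26 else f"L{idx}"
        for g in sub:
            letters[g].add(sym)
    return letters


def regwq(groups: dict, alpha: float = DEFAULT_ALPHA) -> GroupingResult:
    """Ryan-Einot-Gabriel-Welsch (studentized range) multiple range test.

    Parameters
    ----------
    groups
        Mapping of group name to 1-D sample (each with >= 2 observations).
    alpha
        Familywise significance level.
    """
    names = list(groups)
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: np.asarray(groups[g], dtype=float) for g in names}
    ns = {g: s.size for g, s in samples.items()}
    if any(n < 2 for n in ns.values()):
        bad = [g for g, n in ns.items() if n < 2]
        raise ValueError(f"groups below minimum size 2: {bad}")
    means = {g: float(s.mean()) for g, s in samples.items()}
    N = sum(ns.values())
    df = N - k
    mse = sum((ns[g] - 1) * samples[g].var(ddof=1) for g in names) / df

    order = sorted(names, key=lambda g: means[g])
    m = np.array([means[g] for g in order])
    n_arr = np.array([ns[g] for g in order], dtype=float)

    accepted: list[tuple[int, int]] = []
    stack = [(0, k - 1)]
    while stack:
        i, j = stack.pop()
        p = j - i + 1
        if p < 2:
            continue
        if any(ai <= i and j <= aj for ai, aj in accepted):
            continue  # sub-range of an accepted (homogeneous) range
        alpha_p = alpha if p >= k - 1 else 1.0 - (1.0 - alpha) ** (p / k)
        n_h = p / np.sum(1.0 / n_arr[i:j + 1])
        se = np.sqrt(mse / n_h)
        diff = m[j] - m[i]
        if se == 0.0:
            reject = diff > 0
        else:
            reject = (diff / se) > _q_crit(1.0 - alpha_p, p, df)
        if reject:
            stack.append((i, j - 1))
            stack.append((i + 1, j))
        else:
            accepted.append((i, j))

    # maximal accepted ranges, plus singletons not covered by any range
    maximal = [
        (i, j) for (i, j) in accepted
        if not any((ai <= i and j <= aj) and (ai, aj) != (i, j) for ai, aj in accepted)
    ]
    covered = set()
    for i, j in maximal:
        covered.update(range(i, j + 1))
    for s in range(k):
        if s not in covered:
            maximal.append((s, s))
    maximal.sort()
    subsets = [tuple(order[i:j + 1]) for i, j in maximal]
    return GroupingResult(
        groups=names, means=means, ns=ns,
        letters=_letters_from_subsets(names, subsets), subsets=subsets,
    )


def _nonparametric_letters(samples: dict, alpha: float):
    """Letters from the pairwise Wilcoxon non-rejection graph.

    Groups are ordered by mean rank; maximal runs of groups in which every
    pair was not rejected form the homogeneous subsets (greedy interval
    cover of the non-rejection graph).  Raw, uncorrected pairwise p-values
    are used and returned.
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    ranks = sps.rankdata(pooled)
    mean_rank, pos = {}, 0
    for g in names:
        n = samples[g].size
        mean_rank[g] = float(ranks[pos:pos + n].mean())
        pos += n
    order = sorted(names, key=lambda g: mean_rank[g])
    k = len(order)
    pairwise: dict[tuple[str, str], float] = {}
    nonrej = np.ones((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            p = float(sps.mannwhitneyu(
                samples[order[i]], samples[order[j]], alternative="two-sided"
            ).pvalue)
            pairwise[(order[i], order[j])] = p
            nonrej[i, j] = nonrej[j, i] = p >= alpha
    subsets = []
    for i in range(k):  # maximal all-pairs-non-rejected run starting at i
        j = i
        while j + 1 < k and all(nonrej[a, j + 1] for a in range(i, j + 1)):
            j += 1
        subsets.append((i, j))
    maximal = [
        (a, b) for (a, b) in subsets
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in subsets)
    ]
    named = [tuple(order[a:b + 1]) for a, b in maximal]
    return _letters_from_subsets(names, named), named, pairwise


def compare_groups(
    groups: dict, metric: str = "", alpha: float = DEFAULT_ALPHA,
    gate_alpha: float = DEFAULT_ALPHA,
) -> tuple[StatsReport, GroupingResult]:
    """Normality-gated comparison of k groups with a letter display.

    If every group passes the Shapiro-Wilk gate: one-way ANOVA with REGWQ
    letters.  Otherwise: Kruskal-Wallis; pairwise two-sample Wilcoxon tests
    (uncorrected, run only when Kruskal-Wallis rejects) supply the letters.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: np.asarray(groups[g], dtype=float) for g in names}
    small = [g for g, s in samples.items() if s.size < 3]
    if small:
        raise ValueError(f"groups below minimum size 3: {small}")
    normal = all(normality_gate(s, gate_alpha) for s in samples.values())
    N = sum(s.size for s in samples.values())
    if normal:
        f, p = sps.f_oneway(*samples.values())
        grouping = regwq(samples, alpha=alpha)
        report = StatsReport(metric=metric, test="anova", statistic=float(f),
                             p_value=float(p), n=N, normal=True)
        return report, grouping
    h, p = sps.kruskal(*samples.values())
    means = {g: float(s.mean()) for g, s in samples.items()}
    ns = {g: s.size for g, s in samples.items()}
    if p < alpha:
        letters, subsets, pairwise = _nonparametric_letters(samples, alpha)
        extra = {"pairwise_wilcoxon_p": {f"{a}|{b}": v for (a, b), v in pairwise.items()}}
    else:
        subsets = [tuple(names)]
        letters = _letters_from_subsets(names, subsets)
        extra = {}
    report = StatsReport(metric=metric, test="kruskal-wallis", statistic=float(h),
                         p_value=float(p), n=N, normal=False, extra=extra)
    return report, GroupingResult(groups=names, means=means, ns=ns,
                                  letters=letters, subsets=subsets)


def _values(records: list[DogRecord], metric: str, side: str) -> np.ndarray:
    vals = []
    for rec in records:
        g = rec.gland(side)
        if g is None:
            continue
        v = _metric_value(rec, g, metric)
        if v is not None:
            vals.append(v)
    return np.asarray(vals, dtype=float)


def _grouped_values(records, metric, side):
    by_breed: dict[str, list[float]] = {}
    for rec in records:
        g = rec.gland(side)
        if g is None:
            continue
        v = _metric_value(rec, g, metric)
        if v is not None:
            by_breed.setdefault(rec.breed, []).append(v)
    return {b: np.asarray(v) for b, v in by_breed.items()}


def compare_breeds(
    records: list[DogRecord], metric: str, side: str = "left",
    alpha: float = DEFAULT_ALPHA,
) -> tuple[StatsReport, GroupingResult]:
    """Breed comparison of one gland metric (see :func:`compare_groups`)."""
    groups = _grouped_values(records, metric, side)
    report, grouping = compare_groups(groups, metric=f"{metric}:{side}", alpha=alpha)
    return report, grouping


def side_difference(
    records: list[DogRecord], metric: str, alpha: float = DEFAULT_ALPHA
) -> StatsReport:
    """Paired left-right comparison: paired t if the differences pass the
    normality gate, else Wilcoxon signed-rank."""
    pairs = []
    for rec in records:
        if rec.left is None or rec.right is None:
            continue
        lv = _metric_value(rec, rec.left, metric)
        rv = _metric_value(rec, rec.right, metric)
        if lv is not None and rv is not None:
            pairs.append((lv, rv))
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 complete left/right pairs, have {len(pairs)}")
    left = np.array([p[0] for p in pairs])
    right = np.array([p[1] for p in pairs])
    diffs = left - right
    if np.ptp(diffs) == 0:
        # identical differences everywhere: either no difference at all, or a
        # deterministic offset
        p = 1.0 if diffs[0] == 0 else 0.0
        return StatsReport(metric=metric, test="paired-t", statistic=np.inf if p == 0 else 0.0,
                           p_value=p, n=len(pairs), normal=None)
    if normality_gate(diffs):
        t, p = sps.ttest_rel(left, right)
        return StatsReport(metric=metric, test="paired-t", statistic=float(t),
                           p_value=float(p), n=len(pairs), normal=True)
    w, p = sps.wilcoxon(left, right)
    return StatsReport(metric=metric, test="wilcoxon-signed-rank", statistic=float(w),
                       p_value=float(p), n=len(pairs), normal=False)


def weight_group_difference(
    records: list[DogRecord], metric: str, side: str = "left",
    boundary_kg: float = 20.0,
) -> StatsReport:
    """Two-sample Wilcoxon test of a metric between light and heavy dogs."""
    light, heavy = [], []
    for rec in records:
        g = rec.gland(side)
        if g is None:
            continue
        v = _metric_value(rec, g, metric)
        if v is None:
            continue
        (light if classify_weight(rec.body_weight_kg, boundary_kg) == "light" else heavy).append(v)
    if not light or not heavy:
        raise ValueError("both weight classes must be nonempty")
    u, p = sps.mannwhitneyu(light, heavy, alternative="two-sided")
    return StatsReport(metric=f"{metric}:{side}", test="wilcoxon-two-sample",
                       statistic=float(u), p_value=float(p), n=len(light) + len(heavy))


def correlate_with_weight(
    records: list[DogRecord], metric: str, side: str = "left"
) -> tuple[float, float, str]:
    """Pearson correlation of a gland metric with body weight, with band."""
    xs, ys = [], []
    for rec in records:
        g = rec.gland(side)
        if g is None:
            continue
        v = _metric_value(rec, g, metric)
        if v is not None:
            xs.append(rec.body_weight_kg)
            ys.append(v)
    x, y = np.asarray(xs), np.asarray(ys)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant weight or metric: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), classify_correlation(float(r))


def apply_inclusion_criteria(
    records: list[DogRecord], min_age_years: float = 2.0
) -> tuple[list[DogRecord], list[tuple[DogRecord, str]]]:
    """Study inclusion screen: adults with both glands assessable and
    homogeneous contrast distribution in both glands."""
    kept, excluded = [], []
    for rec in records:
        if rec.age_years < min_age_years:
            excluded.append((rec, f"age<{min_age_years:g}"))
        elif rec.left is None:
            excluded.append((rec, "missing left gland"))
        elif rec.right is None:
            excluded.append((rec, "missing right gland"))
        elif not rec.left.homogeneous:
            excluded.append((rec, "non-homogeneous left gland"))
        elif not rec.right.homogeneous:
            excluded.append((rec, "non-homogeneous right gland"))
        else:
            kept.append(rec)
    return kept, excluded
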