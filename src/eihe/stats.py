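"""Statistical comparisons of guild and genus abundances between samples.

Two-sample (unreplicated) designs compare read proportions with Fisher's
exact test; the confidence interval for the difference of proportions is
the Newcombe hybrid score interval, built from the two per-sample Wilson
score intervals. Replicated designs use Welch's t-test (two groups) or the
Kruskal-Wallis rank test with Dunn's post-hoc comparisons (three or more).

Conventions, stated because alternatives exist:

* the two-sided Fisher p-value sums all 2×2 tables with the observed
  margins whose probability does not exceed that of the observed table
  (not the doubling convention);
* degenerate margins (no successes, or no failures, in either sample
  combined) give p = 1.0, never an error;
* the normal quantile in the Wilson interval is computed from the inverse
  standard-normal CDF, so any confidence level works.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .guilds import GuildDefinition
from .index import DEFAULT_POLICY, NameMatchPolicy, match_genus_names
from .io import TaxonCountTable

__all__ = [
    "ProportionComparison",
    "GroupComparisonResult",
    "wilson_interval",
    "newcombe_diff_interval",
    "fisher_exact_two_proportions",
    "permutation_two_proportions",
    "per_genus_screen",
    "guild_level_test",
    "welch_t",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class ProportionComparison:
    """A two-sample contrast of read proportions.

    ``diff`` is p1 − p2 with its Newcombe-Wilson interval at level
    ``conf``; ``p_value`` is the two-sided Fisher exact p. ``p_adjusted``
    and ``significant`` are filled by screening routines that apply a
    multiple-testing policy.
    """

    label: str
    k1: int
    n1: int
    k2: int
    n2: int
    p1: float
    p2: float
    diff: float
    ci_low: float
    ci_high: float
    p_value: float
    conf: float = 0.95
    p_adjusted: float | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of a replicated-design comparison (Welch or Kruskal-Wallis)."""

    label: str
    group_values: tuple[tuple[float, ...], ...]
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    pairwise: tuple[tuple[int, int, float], ...] | None = None


def _validate_counts(k: int, n: int) -> None:
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n.

    Center (p + z²/2n)/(1 + z²/n), half-width
    z·sqrt(p(1−p)/n + z²/4n²)/(1 + z²/n); bounds clipped to [0, 1].
    """
    _validate_counts(k, n)
    z = sps.norm.ppf((1.0 + conf) / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2.0 * n)) / denom
    half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    # at k=0 / k=n the bound is exactly 0 / 1; pin it against roundoff
    low = 0.0 if k == 0 else max(0.0, center - half)
    high = 1.0 if k == n else min(1.0, center + half)
    return low, high


def newcombe_diff_interval(
    k1: int, n1: int, k2: int, n2: int, conf: float = 0.95
) -> tuple[float, float]:
    """Newcombe hybrid score interval for the difference p1 − p2.

    With (l1, u1) and (l2, u2) the per-sample Wilson intervals and
    d = p1 − p2:

        low  = d − sqrt((p1 − l1)² + (u2 − p2)²)
        high = d + sqrt((u1 − p1)² + (p2 − l2)²)

    clipped to [−1, 1]. Unlike the Wald interval this never degenerates at
    k = 0 or k = n.
    """
    _validate_counts(k1, n1)
    _validate_counts(k2, n2)
    p1, p2 = k1 / n1, k2 / n2
    l1, u1 = wilson_interval(k1, n1, conf)
    l2, u2 = wilson_interval(k2, n2, conf)
    d = p1 - p2
    low = d - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    high = d + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    return max(-1.0, low), min(1.0, high)


def fisher_exact_two_proportions(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    conf: float = 0.95,
    label: str = "",
) -> ProportionComparison:
    """Fisher's exact test for k1/n1 vs k2/n2 with a Newcombe-Wilson CI.

    This is the conditional-exact (permutation) view of the 2×2 comparison:
    conditioning on the margins, the two-sided p sums hypergeometric
    probabilities of tables at least as extreme as the observed one.
    """
    _validate_counts(k1, n1)
    _validate_counts(k2, n2)
    if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
        p_value = 1.0
    else:
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        p_value = float(sps.fisher_exact(table, alternative="two-sided")[1])
    low, high = newcombe_diff_interval(k1, n1, k2, n2, conf)
    p1, p2 = k1 / n1, k2 / n2
    return ProportionComparison(
        label=label,
        k1=k1,
        n1=n1,
        k2=k2,
        n2=n2,
        p1=p1,
        p2=p2,
        diff=p1 - p2,
        ci_low=low,
        ci_high=high,
        p_value=min(1.0, p_value),
        conf=conf,
    )


def permutation_two_proportions(
    k1: int, n1: int, k2: int, n2: int, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo permutation p for the same 2×2 contrast.

    Cross-check for :func:`fisher_exact_two_proportions`: reads are pooled
    and reassigned to the two samples, and the permutation p is the
    fraction of reassignments whose |p1 − p2| is at least the observed one.
    """
    _validate_counts(k1, n1)
    _validate_counts(k2, n2)
    rng = np.random.default_rng(seed)
    observed = abs(k1 / n1 - k2 / n2)
    k = k1 + k2
    draws = rng.hypergeometric(k, n1 + n2 - k, n1, size=n_perm)
    diffs = np.abs(draws / n1 - (k - draws) / n2)
    return float((np.sum(diffs >= observed - 1e-12) + 1) / (n_perm + 1))


def _genus_counts_for_samples(
    table: TaxonCountTable,
    guild: GuildDefinition,
    sample_a: str,
    sample_b: str,
    policy: NameMatchPolicy,
) -> tuple[dict[str, tuple[int, int]], int, int]:
    for s in (sample_a, sample_b):
        if s not in table.sample_names:
            raise ValueError(f"unknown sample name {s!r}")
    counts = table.genus_counts()
    mapping = match_genus_names(list(counts.index), guild, policy)
    roots = table.root_counts()
    per_genus = {}
    for genus, label in mapping.items():
        if label is None:
            per_genus[genus] = (0, 0)
        else:
            per_genus[genus] = (
                int(counts.at[label, sample_a]),
                int(counts.at[label, sample_b]),
            )
    return per_genus, roots[sample_a], roots[sample_b]


def per_genus_screen(
    table: TaxonCountTable,
    guild: GuildDefinition,
    sample_a: str,
    sample_b: str,
    alpha: float = 0.05,
    correction: str = "none",
    conf: float = 0.95,
    policy: NameMatchPolicy = DEFAULT_POLICY,
) -> list[ProportionComparison]:
    """Fisher exact test per guild genus between two samples.

    Each genus contributes a 2×2 table of (genus reads, other reads) in the
    two samples. ``correction`` is ``'none'`` (each raw p compared to
    ``alpha``) or ``'bh'`` (Benjamini-Hochberg across the guild). Results
    are sorted by the difference in proportions, largest excess in
    ``sample_a`` first.
    """
    if correction not in {"none", "bh"}:
        raise ValueError(f"unknown correction {correction!r}")
    per_genus, n1, n2 = _genus_counts_for_samples(
        table, guild, sample_a, sample_b, policy
    )
    comparisons = [
        fisher_exact_two_proportions(ka, n1, kb, n2, conf=conf, label=genus)
        for genus, (ka, kb) in per_genus.items()
    ]
    raw_p = [c.p_value for c in comparisons]
    if correction == "bh":
        reject, adjusted, _, _ = multipletests(raw_p, alpha=alpha, method="fdr_bh")
        comparisons = [
            replace(c, p_adjusted=float(q), significant=bool(r))
            for c, q, r in zip(comparisons, adjusted, reject)
        ]
    else:
        comparisons = [
            replace(c, p_adjusted=c.p_value, significant=c.p_value < alpha)
            for c in comparisons
        ]
    return sorted(comparisons, key=lambda c: -c.diff)


def guild_level_test(
    table: TaxonCountTable,
    guild: GuildDefinition,
    sample_a: str,
    sample_b: str,
    conf: float = 0.95,
    policy: NameMatchPolicy = DEFAULT_POLICY,
) -> ProportionComparison:
    """Fisher exact test of total guild membership between two samples.

    Reads are dichotomized into "guild" vs "others": k is the summed reads
    of all guild genera and n the root count, per sample. By construction
    100·p1 and 100·p2 equal the samples' EIHE values.
    """
    per_genus, n1, n2 = _genus_counts_for_samples(
        table, guild, sample_a, sample_b, policy
    )
    k1 = sum(ka for ka, _ in per_genus.values())
    k2 = sum(kb for _, kb in per_genus.values())
    return fisher_exact_two_proportions(k1, n1, k2, n2, conf=conf, label="guild")


def welch_t(
    group_a: Sequence[float], group_b: Sequence[float], label: str = ""
) -> GroupComparisonResult:
    """Welch's unequal-variance t-test between two groups of replicates.

    t = (x̄₁ − x̄₂)/sqrt(s₁²/n₁ + s₂²/n₂) with Welch-Satterthwaite degrees
    of freedom. When both sample variances are zero the test statistic is
    undefined: equal means give p = 1, unequal means are reported as an
    infinite statistic with p = 0 (documented policy, not an error).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch's t-test needs at least 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            stat, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
        else:
            stat = math.copysign(math.inf, a.mean() - b.mean())
            p, df = 0.0, float(len(a) + len(b) - 2)
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return GroupComparisonResult(
        label=label,
        group_values=(tuple(map(float, a)), tuple(map(float, b))),
        statistic=stat,
        p_value=p,
        method="welch_t",
        df=df,
    )


def _dunn_pairwise(
    groups: Sequence[Sequence[float]],
) -> tuple[tuple[int, int, float], ...]:
    """Dunn's z pairwise comparisons on pooled ranks, Bonferroni-adjusted."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))
    ]
    n = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0.0:
                p = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_pairs)
            out.append((i, j, float(p)))
    return tuple(out)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    posthoc: bool = False,
    label: str = "",
) -> GroupComparisonResult:
    """Kruskal-Wallis rank test across ≥2 groups, tie-corrected.

    p comes from the chi-square approximation with (groups − 1) degrees of
    freedom, which needs a total of at least 5 observations. With
    ``posthoc=True``, Dunn's z pairwise comparisons with Bonferroni
    adjustment are attached. All values identical gives H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if sum(len(g) for g in groups) < 5:
        raise ValueError(
            "chi-square approximation needs a total of at least 5 values"
        )
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
    else:
        res = sps.kruskal(*arrays)
        stat, p = float(res.statistic), float(res.pvalue)
    pairwise = _dunn_pairwise(arrays) if posthoc else None
    return GroupComparisonResult(
        label=label,
        group_values=tuple(tuple(map(float, a)) for a in arrays),
        statistic=stat,
        p_value=p,
        method="kruskal_wallis",
        df=float(len(groups) - 1),
        pairwise=pairwise,
    )
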