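import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.proportion import (
    confint_proportions_2indep,
    proportion_confint,
)

from eihe.stats import (
    fisher_exact_two_proportions,
    guild_level_test,
    kruskal_wallis,
    newcombe_diff_interval,
    per_genus_screen,
    permutation_two_proportions,
    welch_t,
    wilson_interval,
)
from eihe.index import compute_eihe
from eihe.guilds import GuildDefinition, GuildGenus
from eihe.io import read_genus_matrix
import io


# ---------------------------------------------------------------- oracles

def wilson_oracle(k, n, conf):
    """Independent transcription of the Wilson score interval."""
    z = sps.norm.ppf(0.5 + conf / 2.0)
    p = k / n
    low = (2 * n * p + z**2 - z * math.sqrt(z**2 + 4 * n * p * (1 - p))) / (
        2 * (n + z**2)
    )
    high = (2 * n * p + z**2 + z * math.sqrt(z**2 + 4 * n * p * (1 - p))) / (
        2 * (n + z**2)
    )
    return max(0.0, low), min(1.0, high)


def newcombe_oracle(k1, n1, k2, n2, conf):
    """Two Wilson intervals, then the hybrid square-root combination."""
    l1, u1 = wilson_oracle(k1, n1, conf)
    l2, u2 = wilson_oracle(k2, n2, conf)
    p1, p2 = k1 / n1, k2 / n2
    d = p1 - p2
    return (
        max(-1.0, d - math.hypot(p1 - l1, u2 - p2)),
        min(1.0, d + math.hypot(u1 - p1, p2 - l2)),
    )


def fisher_oracle(k1, n1, k2, n2):
    """Exhaustive two-sided Fisher p by exact hypergeometric enumeration."""
    k = k1 + k2
    n = n1 + n2
    denom = math.comb(n, n1)
    def prob(x):
        if x < 0 or x > n1 or k - x < 0 or k - x > n2:
            return 0.0
        return math.comb(k, x) * math.comb(n - k, n1 - x) / denom
    p_obs = prob(k1)
    total = sum(
        prob(x) for x in range(0, min(k, n1) + 1) if prob(x) <= p_obs * (1 + 1e-7)
    )
    return min(1.0, total)


# ---------------------------------------------------------------- Wilson

class TestWilsonInterval:
    def test_zero_successes_pins_lower_bound(self):
        low, high = wilson_interval(0, 10)
        assert low == 0.0 and 0 < high < 1

    def test_all_successes_pins_upper_bound(self):
        low, high = wilson_interval(10, 10)
        assert high == 1.0 and 0 < low < 1

    def test_closed_form_transcription(self):
        assert wilson_interval(5, 10) == pytest.approx(
            wilson_oracle(5, 10, 0.95), abs=1e-10
        )

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        n=st.integers(1, 500),
        frac=st.floats(0, 1),
        conf=st.sampled_from([0.8, 0.9, 0.95, 0.99]),
    )
    def test_matches_independent_transcription(self, n, frac, conf):
        k = round(frac * n)
        assert wilson_interval(k, n, conf) == pytest.approx(
            wilson_oracle(k, n, conf), abs=1e-10
        )

    def test_matches_statsmodels(self):
        for k, n in [(3, 17), (0, 5), (40, 41), (250, 500)]:
            expected = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert wilson_interval(k, n) == pytest.approx(expected, abs=1e-10)


class TestNewcombeDiffInterval:
    def test_equal_samples_symmetric_about_zero(self):
        low, high = newcombe_diff_interval(7, 20, 7, 20)
        assert low == pytest.approx(-high, abs=1e-12)
        assert low < 0 < high

    def test_extreme_difference_clips_to_one(self):
        low, high = newcombe_diff_interval(10, 10, 0, 10)
        assert high == 1.0
        assert low > 0

    def test_worked_example_against_two_step_recipe(self):
        assert newcombe_diff_interval(56, 70, 48, 80) == pytest.approx(
            newcombe_oracle(56, 70, 48, 80, 0.95), abs=1e-10
        )

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        n1=st.integers(1, 300),
        n2=st.integers(1, 300),
        f1=st.floats(0, 1),
        f2=st.floats(0, 1),
    )
    def test_matches_independent_transcription(self, n1, n2, f1, f2):
        k1, k2 = round(f1 * n1), round(f2 * n2)
        assert newcombe_diff_interval(k1, n1, k2, n2) == pytest.approx(
            newcombe_oracle(k1, n1, k2, n2, 0.95), abs=1e-10
        )

    def test_matches_statsmodels_newcomb(self):
        ours = newcombe_diff_interval(56, 70, 48, 80)
        theirs = confint_proportions_2indep(
            56, 70, 48, 80, method="newcomb", compare="diff", correction=False
        )
        assert ours == pytest.approx(theirs, abs=1e-8)


class TestCoverage:
    def test_wilson_95_coverage_near_nominal(self):
        # 10,000 binomial draws, n=100, p=0.3; intervals memoized over k
        rng = np.random.default_rng(20260101)
        n, p = 100, 0.3
        intervals = [wilson_interval(k, n) for k in range(n + 1)]
        ks = rng.binomial(n, p, size=10_000)
        covered = np.array([intervals[k][0] <= p <= intervals[k][1] for k in ks])
        assert 0.93 <= covered.mean() <= 0.97

    def test_newcombe_95_coverage_near_nominal(self):
        rng = np.random.default_rng(20260102)
        n, p = 200, 0.05
        k1 = rng.binomial(n, p, size=10_000)
        k2 = rng.binomial(n, p, size=10_000)
        cache = {}
        hits = 0
        for a, b in zip(k1, k2):
            key = (int(a), int(b))
            if key not in cache:
                cache[key] = newcombe_diff_interval(a, n, b, n)
            low, high = cache[key]
            hits += low <= 0.0 <= high
        assert 0.93 <= hits / 10_000 <= 0.98


# ---------------------------------------------------------------- Fisher

class TestFisherExact:
    def test_identical_tables_give_p_one(self):
        assert fisher_exact_two_proportions(5, 10, 5, 10).p_value == 1.0

    def test_degenerate_margins_give_p_one(self):
        res = fisher_exact_two_proportions(0, 10, 0, 15)
        assert res.p_value == 1.0 and res.diff == 0.0
        assert fisher_exact_two_proportions(10, 10, 15, 15).p_value == 1.0

    def test_against_enumeration_on_small_grid(self):
        for n1, n2 in [(3, 5), (8, 8), (12, 7)]:
            for k1, k2 in product(range(n1 + 1), range(n2 + 1)):
                ours = fisher_exact_two_proportions(k1, n1, k2, n2).p_value
                assert ours == pytest.approx(
                    fisher_oracle(k1, n1, k2, n2), abs=1e-10
                ), (k1, n1, k2, n2)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        n1=st.integers(1, 40),
        n2=st.integers(1, 40),
        f1=st.floats(0, 1),
        f2=st.floats(0, 1),
    )
    def test_symmetries(self, n1, n2, f1, f2):
        k1, k2 = round(f1 * n1), round(f2 * n2)
        p = fisher_exact_two_proportions(k1, n1, k2, n2).p_value
        swapped = fisher_exact_two_proportions(k2, n2, k1, n1).p_value
        relabeled = fisher_exact_two_proportions(n1 - k1, n1, n2 - k2, n2).p_value
        assert p == pytest.approx(swapped, rel=1e-12)
        assert p == pytest.approx(relabeled, rel=1e-12)

    def test_ci_brackets_diff(self):
        res = fisher_exact_two_proportions(56, 70, 48, 80)
        assert res.ci_low <= res.diff <= res.ci_high

    def test_permutation_mode_agrees_with_exact(self):
        exact = fisher_exact_two_proportions(30, 100, 15, 100).p_value
        mc = permutation_two_proportions(30, 100, 15, 100, n_perm=40_000, seed=7)
        assert mc == pytest.approx(exact, abs=0.01)


# ------------------------------------------------------- screening / guild

def two_sample_fixture(genus_counts):
    """genus -> (count_a, count_b); totals padded to 25,000 with filler."""
    total = 25_000
    fill_a = total - sum(a for a, _ in genus_counts.values())
    fill_b = total - sum(b for _, b in genus_counts.values())
    lines = ["genus\tA\tB"] + [
        f"{g}\t{a}\t{b}" for g, (a, b) in genus_counts.items()
    ] + [f"Filler\t{fill_a}\t{fill_b}"]
    return read_genus_matrix(io.StringIO("\n".join(lines) + "\n"))


def guild_of(*names):
    return GuildDefinition(
        name="g", version="1", entries=tuple(GuildGenus(n) for n in names)
    )


class TestPerGenusScreen:
    def test_single_extreme_genus_flagged(self):
        table = two_sample_fixture({"G1": (1000, 0), "G2": (50, 50), "G3": (10, 12)})
        guild = guild_of("G1", "G2", "G3")
        rows = per_genus_screen(table, guild, "A", "B")
        flagged = [r.label for r in rows if r.significant]
        assert flagged == ["G1"]
        assert rows[0].label == "G1"  # sorted by diff descending

    def test_identical_samples_flag_nothing(self):
        table = two_sample_fixture({"G1": (100, 100), "G2": (30, 30)})
        rows = per_genus_screen(table, guild_of("G1", "G2"), "A", "B")
        assert not any(r.significant for r in rows)

    def test_bh_flags_subset_of_uncorrected(self):
        table = two_sample_fixture(
            {"G1": (300, 200), "G2": (120, 80), "G3": (60, 40), "G4": (33, 30)}
        )
        guild = guild_of("G1", "G2", "G3", "G4")
        none_set = {
            r.label for r in per_genus_screen(table, guild, "A", "B") if r.significant
        }
        bh_set = {
            r.label
            for r in per_genus_screen(table, guild, "A", "B", correction="bh")
            if r.significant
        }
        assert bh_set <= none_set

    def test_unknown_sample_rejected(self):
        table = two_sample_fixture({"G1": (10, 10)})
        with pytest.raises(ValueError, match="unknown sample"):
            per_genus_screen(table, guild_of("G1"), "A", "nope")


class TestGuildLevelTest:
    def test_hand_arithmetic_on_pollution_contrast(self):
        table = two_sample_fixture({"G1": (1300, 250)})
        res = guild_level_test(table, guild_of("G1"), "A", "B")
        assert res.p1 == pytest.approx(0.052)
        assert res.p2 == pytest.approx(0.010)
        assert res.diff == pytest.approx(0.042)
        assert res.p_value < 1e-15

    def test_absent_guild_gives_null_result(self):
        table = two_sample_fixture({"G1": (10, 10)})
        res = guild_level_test(table, guild_of("NotThere"), "A", "B")
        assert res.diff == 0.0 and res.p_value == 1.0

    def test_proportions_equal_index_values(self, two_sample_table, guild63):
        res = guild_level_test(two_sample_table, guild63, "polluted", "pristine")
        by_name = {r.sample_name: r for r in compute_eihe(two_sample_table, guild63)}
        assert 100.0 * res.p1 == pytest.approx(by_name["polluted"].eihe, abs=1e-9)
        assert 100.0 * res.p2 == pytest.approx(by_name["pristine"].eihe, abs=1e-9)


# ----------------------------------------------------- replicated designs

class TestWelchT:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_variance_distinct_means_documented_policy(self):
        res = welch_t([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
        assert res.p_value == 0.0 and math.isinf(res.statistic)

    def test_zero_variance_equal_means(self):
        res = welch_t([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_t([1.0], [1.0, 2.0])

    def test_against_direct_formula(self):
        rng = np.random.default_rng(42)
        a, b = rng.normal(0, 1, 5), rng.normal(0.5, 2, 5)
        res = welch_t(a, b)
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        p = 2 * sps.t.sf(abs(t), df)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


class TestKruskalWallis:
    def test_identical_groups_give_zero_H(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_ranked_example(self):
        # ranks 1..9 split into thirds: H = 12/(9*10)*(36+225+576)/3 - 30 = 7.2
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2, abs=1e-10)
        assert res.p_value == pytest.approx(sps.chi2.sf(7.2, 2), abs=1e-10)

    def test_group_order_exchangeable(self):
        groups = [[1.0, 4.0, 2.0], [9.0, 3.0], [5.0, 5.0, 8.0]]
        a = kruskal_wallis(groups)
        b = kruskal_wallis(groups[::-1])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_posthoc_pairwise_present_and_valid(self):
        res = kruskal_wallis(
            [[1, 2, 3], [4, 5, 6], [70, 80, 90]], posthoc=True
        )
        assert len(res.pairwise) == 3
        assert all(0.0 <= p <= 1.0 for _, _, p in res.pairwise)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], [2.0]])
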