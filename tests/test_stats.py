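"""Nonparametric statistics: KW, Dunn, compact letters, Spearman t."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import stemflex as sf


def mid_ranks(values):
    """Independent pure-python mid-rank oracle."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_H(groups):
    """KW H with tie correction, computed from first principles."""
    names = list(groups)
    pooled = [v for g in names for v in groups[g]]
    ranks = mid_ranks(pooled)
    N = len(pooled)
    rbars, i = {}, 0
    for g in names:
        n = len(groups[g])
        rbars[g] = sum(ranks[i:i + n]) / n
        i += n
    H = 12.0 / (N * (N + 1)) * sum(
        len(groups[g]) * (rbars[g] - (N + 1) / 2) ** 2 for g in names)
    tie = sum(c ** 3 - c for c in
              [ranks.count(r) for r in set(ranks)])
    denom = 1 - tie / (N ** 3 - N)
    return H / denom if denom > 0 else 0.0


class TestDiameterClasses:
    @pytest.mark.parametrize("d, expect", [
        (3.0, "narrow"), (1.8, "narrow"), (3.89, "narrow"),
        (3.9, "medium"), (5.9, "medium"),
        (5.91, "large"), (6.2, "large"),
        (1.0, "below"),
    ])
    def test_assignment(self, d, expect):
        assert sf.assign_diameter_class(d) == expect

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sf.assign_diameter_class(0.0)


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        groups = {"a": [5.0] * 4, "b": [5.0] * 4, "c": [5.0] * 4}
        res = sf.kruskal_wallis(groups)
        assert res.H == 0.0 and res.p == 1.0

    def test_toy_groups_match_hand_oracle(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = sf.kruskal_wallis(groups)
        assert res.H == pytest.approx(7.2)  # 12/90 * (3*9 + 0 + 3*9)
        assert res.H == pytest.approx(brute_force_H(groups))
        assert res.df == 2

    def test_matches_scipy_with_ties(self, rng):
        groups = {g: np.round(rng.normal(i, 1, 12), 1)
                  for i, g in enumerate("abc")}
        res = sf.kruskal_wallis(groups)
        H_ref, p_ref = sps.kruskal(*groups.values())
        assert res.H == pytest.approx(H_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-12)

    def test_chi2_p_close_to_exact_permutation_null(self):
        # moderate-H regime where the chi2 tail is a good small-n
        # approximation; in the deep tail at n = 8 it degrades (methods note)
        groups = {"a": [1.0, 2.0, 4.0], "b": [5.0, 6.0, 8.0], "c": [3.0, 7.0]}
        res = sf.kruskal_wallis(groups, min_size=2)
        pooled = sorted(v for g in groups.values() for v in g)
        sizes = [len(groups[g]) for g in groups]
        count = total = 0
        for perm in itertools.permutations(pooled):
            reassigned = {"a": perm[:3], "b": perm[3:6], "c": perm[6:]}
            if brute_force_H(reassigned) >= res.H - 1e-12:
                count += 1
            total += 1
        p_exact = count / total
        assert abs(res.p - p_exact) < 0.02

    def test_small_group_excluded_with_reason(self):
        groups = {"a": [1, 2, 3, 4], "b": [5, 6, 7], "c": [9.0]}
        res = sf.kruskal_wallis(groups, min_size=3)
        assert "c" in res.excluded and "c" not in res.groups

    def test_rank_invariance_under_monotone_transform(self, rng):
        groups = {g: rng.normal(i, 1, 10) for i, g in enumerate("abcd")}
        res1 = sf.kruskal_wallis(groups)
        res2 = sf.kruskal_wallis({g: np.exp(v) for g, v in groups.items()})
        assert res1.H == pytest.approx(res2.H, rel=1e-12)


class TestDunn:
    def test_identical_pair_z_zero(self):
        z, p = sf.dunn_posthoc({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert z.loc["a", "b"] == pytest.approx(0.0)
        assert p.loc["a", "b"] == pytest.approx(1.0)

    def test_toy_groups_match_direct_formula(self):
        groups = {"a": [1.0, 2.0, 2.0], "b": [2.0, 5.0, 6.0], "c": [7.0, 8.0]}
        z, _ = sf.dunn_posthoc(groups)
        pooled = [v for g in groups.values() for v in g]
        ranks = mid_ranks(pooled)
        rbar = {"a": sum(ranks[:3]) / 3, "b": sum(ranks[3:6]) / 3,
                "c": sum(ranks[6:]) / 2}
        N = 8
        tie = sum(c ** 3 - c for c in [ranks.count(r) for r in set(ranks)])
        var = N * (N + 1) / 12 - tie / (12 * (N - 1))
        for i, j, ni, nj in [("a", "b", 3, 3), ("a", "c", 3, 2), ("b", "c", 3, 2)]:
            expect = (rbar[i] - rbar[j]) / math.sqrt(var * (1 / ni + 1 / nj))
            assert z.loc[i, j] == pytest.approx(expect, rel=1e-12)

    def test_bonferroni_is_m_times_raw(self, rng):
        groups = {g: rng.normal(i, 1, 8) for i, g in enumerate("abc")}
        _, p_raw = sf.dunn_posthoc(groups, adjustment="none")
        _, p_bon = sf.dunn_posthoc(groups, adjustment="bonferroni")
        for i, j in itertools.combinations("abc", 2):
            assert p_bon.loc[i, j] == pytest.approx(
                min(1.0, 3 * p_raw.loc[i, j]))

    def test_kw_two_groups_equals_dunn_z_squared(self, rng):
        groups = {"a": rng.normal(0, 1, 9), "b": rng.normal(1, 1, 7)}
        res = sf.kruskal_wallis(groups)
        z, _ = sf.dunn_posthoc(groups)
        assert res.H == pytest.approx(z.loc["a", "b"] ** 2, rel=1e-9)


def p_matrix(names, entries):
    df = pd.DataFrame(1.0, index=list(names), columns=list(names))
    for (i, j), v in entries.items():
        df.loc[i, j] = df.loc[j, i] = v
    return df


class TestCompactLetters:
    def test_all_nonsignificant_single_letter(self):
        letters = sf.compact_letter_display(p_matrix("abc", {}))
        assert set(letters.values()) == {"a"}

    def test_all_significant_distinct_letters(self):
        p = p_matrix("xyz", {("x", "y"): 0.001, ("x", "z"): 0.001,
                             ("y", "z"): 0.001})
        letters = sf.compact_letter_display(p)
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_chain_pattern(self):
        # A != C, A ~ B, B ~ C -> a, ab, b
        p = p_matrix("ABC", {("A", "C"): 0.01})
        letters = sf.compact_letter_display(p)
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    @pytest.mark.parametrize("seed", range(8))
    def test_soundness_on_random_patterns(self, seed):
        # letters reconstruct the thresholded significance relation exactly
        rng = np.random.default_rng(seed)
        names = list("abcde")
        entries = {(i, j): rng.uniform(0, 0.12)
                   for i, j in itertools.combinations(names, 2)}
        p = p_matrix(names, entries)
        letters = sf.compact_letter_display(p, alpha=0.05)
        for i, j in itertools.combinations(names, 2):
            share = bool(set(letters[i]) & set(letters[j]))
            assert share == (p.loc[i, j] >= 0.05), (letters, p)


class TestSpearman:
    @pytest.mark.parametrize("rs, n, expect", [
        (0.7503, 269, 18.54),
        (-0.5720, 269, -11.40),
    ])
    def test_t_from_printed_coefficients(self, rs, n, expect):
        assert sf.spearman_t_from_r(rs, n) == pytest.approx(expect, abs=0.01)

    def test_perfect_monotone_unbounded(self):
        res = sf.spearman_t([1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0])
        assert res.rs == 1.0 and res.unbounded_t and res.p == 0.0

    def test_matches_scipy_spearmanr(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = sf.spearman_t(x, y)
        rho, p = sps.spearmanr(x, y)
        assert res.rs == pytest.approx(rho, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_rank_invariance(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        r1 = sf.spearman_t(x, y)
        r2 = sf.spearman_t(np.exp(x), y ** 3)
        assert r1.rs == pytest.approx(r2.rs, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            sf.spearman_t([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(derandomize=True, max_examples=50)
    @given(rs=st.floats(min_value=-0.999, max_value=0.999),
           n=st.integers(min_value=5, max_value=500))
    def test_t_transform_inverts(self, rs, n):
        t = sf.spearman_t_from_r(rs, n)
        back = t / math.sqrt(n - 2 + t * t)
        assert back == pytest.approx(rs, abs=1e-12)
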