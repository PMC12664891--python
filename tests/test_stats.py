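"""Permutation-FDR tests and Fisher enrichment against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from redoxtmt import stats as st


def _config(**kw):
    kw.setdefault("rng_seed", 5)
    return st.PermutationConfig(**kw)


class TestTTestContracts:
    def test_three_levels_rejected(self):
        data = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 6)))
        with pytest.raises(st.ConfigError, match="anova|ANOVA|2"):
            st.permutation_fdr_ttest(data, ["a", "a", "b", "b", "c", "c"], _config())

    def test_small_group_rejected(self):
        data = pd.DataFrame(np.zeros((2, 3)))
        with pytest.raises(st.ConfigError, match=">= 2"):
            st.permutation_fdr_ttest(data, ["a", "a", "b"], _config())

    def test_zero_variance_row_excluded_with_reason(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(size=(5, 8)))
        data.iloc[2] = 3.0  # constant row
        res, excluded = st.permutation_fdr_ttest(
            data, ["a"] * 4 + ["b"] * 4, _config(s0=0.0)
        )
        assert 2 in excluded.index
        assert excluded.loc[2, "reason"] == "zero variance"
        assert 2 not in res.index

    def test_s0_rescues_zero_variance_row(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(size=(5, 8)))
        data.iloc[2] = 3.0
        res, excluded = st.permutation_fdr_ttest(
            data, ["a"] * 4 + ["b"] * 4, _config(s0=0.5)
        )
        assert excluded.empty and res.loc[2, "statistic"] == 0.0

    def test_insufficient_replicates_excluded(self):
        data = pd.DataFrame(np.random.default_rng(2).normal(size=(3, 8)))
        data.iloc[0, :3] = np.nan  # one group left with a single value
        res, excluded = st.permutation_fdr_ttest(
            data, ["a"] * 4 + ["b"] * 4, _config()
        )
        assert excluded.loc[0, "reason"] == "insufficient replicates"


class TestAnovaContracts:
    def test_two_levels_rejected(self):
        data = pd.DataFrame(np.zeros((2, 4)))
        with pytest.raises(st.ConfigError, match="t test|ttest"):
            st.permutation_fdr_anova(data, ["a", "a", "b", "b"], _config())

    def test_planted_group_shift_detected(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(60, 9)))
        data.iloc[0, 6:] += 10.0  # one group shifted by 10 sd
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res, _ = st.permutation_fdr_anova(data, groups, _config())
        assert bool(res.loc[0, "significant"])
        assert res.loc[0, "statistic"] == res["statistic"].max()


@pytest.fixture(scope="module")
def seeded_data():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(rng.normal(size=(80, 10)))
    data.iloc[:8, 5:] += 4.0
    return data, ["x"] * 5 + ["y"] * 5


class TestQValueProperties:

    def test_q_monotone_in_statistic_order(self, seeded_data):
        data, groups = seeded_data
        res, _ = st.permutation_fdr_ttest(data, groups, _config())
        q_sorted = res.sort_values("statistic", key=np.abs, ascending=False)["q_value"]
        assert (np.diff(q_sorted.to_numpy()) >= -1e-12).all()
        assert res["q_value"].between(0, 1).all()

    def test_significant_implies_q_below_threshold(self, seeded_data):
        data, groups = seeded_data
        res, _ = st.permutation_fdr_ttest(data, groups, _config(fdr_threshold=0.05))
        assert (res.loc[res["significant"], "q_value"] <= 0.05).all()

    def test_invariant_to_relabeling_and_row_order(self, seeded_data):
        data, groups = seeded_data
        res, _ = st.permutation_fdr_ttest(data, groups, _config())
        relabeled = ["ctrl" if g == "x" else "ox" for g in groups]
        res2, _ = st.permutation_fdr_ttest(data, relabeled, _config())
        np.testing.assert_allclose(res["q_value"], res2["q_value"])
        shuffled = data.sample(frac=1, random_state=0)
        res3, _ = st.permutation_fdr_ttest(shuffled, groups, _config())
        np.testing.assert_allclose(
            res3["q_value"].sort_index(), res["q_value"].sort_index()
        )

    def test_power_nondecreasing_in_effect_size(self):
        rng = np.random.default_rng(11)
        noise = rng.normal(size=(200, 10))
        groups = ["x"] * 5 + ["y"] * 5
        hits = []
        for effect in (0.0, 2.0, 6.0):
            data = pd.DataFrame(noise.copy())
            data.iloc[:20, 5:] += effect
            res, _ = st.permutation_fdr_ttest(data, groups, _config())
            hits.append(int(res["significant"].iloc[:20].sum()))
        assert hits[0] <= hits[1] <= hits[2]

    def test_exact_enumeration_count(self):
        assert st.n_distinct_permutations([5, 5]) == 252
        assert st.n_distinct_permutations([3, 3, 3]) == 1680

    def test_raw_p_mode(self, seeded_data):
        data, groups = seeded_data
        res, _ = st.permutation_fdr_ttest(
            data, groups, _config(use_raw_p=True, fdr_threshold=0.05)
        )
        assert (res.loc[res["significant"], "raw_p"] <= 0.05).all()


def hypergeom_two_sided(a, b, c, d):
    """Independent exact oracle: sum of hypergeometric pmfs <= pmf(observed)."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = math.comb(r1 + r2, c1)
    return sum(
        math.comb(r1, k) * math.comb(r2, c1 - k)
        for k in range(lo, hi + 1)
        if math.comb(r1, k) * math.comb(r2, c1 - k) <= w_obs
    ) / total


class TestFisherEnrichment:
    def test_selection_equals_background_degenerate(self):
        bg = {f"P{i}" for i in range(10)}
        cats = {p: ["cat1"] if i < 4 else ["cat2"] for i, p in enumerate(sorted(bg))}
        out = st.fisher_enrichment(bg, bg, cats)
        assert np.allclose(out["relative_enrichment"], 1.0)
        assert np.allclose(out["p_value"], 1.0)

    def test_hand_table_matches_hypergeometric_oracle(self):
        # a=5 selected in category, b=5 selected outside, c=5, d=85
        bg = [f"P{i}" for i in range(100)]
        sel = set(bg[:10])
        cats = {p: ["target"] for p in bg[:5] + bg[10:15]}
        out = st.fisher_enrichment(sel, set(bg), cats).set_index("category")
        row = out.loc["target"]
        assert (row["a"], row["b"], row["c"], row["d"]) == (5, 5, 5, 85)
        assert row["p_value"] == pytest.approx(hypergeom_two_sided(5, 5, 5, 85), abs=1e-12)

    def test_empty_category_absent(self):
        bg = {"P1", "P2"}
        out = st.fisher_enrichment({"P1"}, bg, {})
        assert out.empty

    def test_selection_not_subset_is_error(self):
        with pytest.raises(ValueError, match="subset"):
            st.fisher_enrichment({"X"}, {"P1"}, {})

    def test_relative_enrichment_value(self):
        bg = [f"P{i}" for i in range(20)]
        sel = set(bg[:5])
        cats = {p: ["m"] for p in bg[:4]}  # 4/20 background, 4/5 of selection
        out = st.fisher_enrichment(sel, set(bg), cats).set_index("category")
        assert out.loc["m", "relative_enrichment"] == pytest.approx((4 / 5) / (4 / 20))


def bh_step_up(p):
    """Reference Benjamini-Hochberg step-up, written independently."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_bh_qvalues_match_reference_step_up(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(50):
        p = rng.uniform(size=rng.integers(2, 120))
        _, q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, bh_step_up(p), atol=1e-12)
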