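"""Impurity correction, carrier separation and protein normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

import redoxtmt as rt
from redoxtmt import reporter as rep
from redoxtmt.design import DesignError


class TestImpurityCorrection:
    def test_identity_matrix_is_noop(self):
        y = np.array([100.0, 200.0, 0.0])
        out = rep.correct_isotope_impurities(y, np.eye(3))
        np.testing.assert_allclose(out, y, atol=1e-12)

    def test_two_channel_hand_oracle(self):
        # M row-stochastic; true x=[100,0] observed as y = M' x = [90,10]
        m = np.array([[0.9, 0.1], [0.1, 0.9]])
        out = rep.correct_isotope_impurities(np.array([90.0, 10.0]), m)
        np.testing.assert_allclose(out, [100.0, 0.0], atol=1e-9)

    def test_negative_unconstrained_solution_clipped_optimally(self):
        # y chosen so the unconstrained solution has a negative entry
        m = np.array([[0.9, 0.1], [0.1, 0.9]])
        y = np.array([0.0, 50.0])
        unconstrained = np.linalg.solve(m.T, y)
        assert unconstrained.min() < 0
        out = rep.correct_isotope_impurities(y, m)
        assert (out >= 0).all() and out[0] == 0.0
        # grid-search oracle: no non-negative candidate beats the NNLS residual
        resid_ours = np.linalg.norm(m.T @ out - y)
        for a in np.linspace(0, 20, 81):
            for b in np.linspace(0, 120, 121):
                cand = np.linalg.norm(m.T @ np.array([a, b]) - y)
                assert resid_ours <= cand + 1e-9

    def test_roundtrip_property_seeded(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 19))
            leak = float(rng.uniform(0.0, 0.12))
            m = rt.tmt_like_impurity_matrix(n, leak)
            x = rng.uniform(0, 1e6, size=n)
            y = m.T @ x
            out = rep.correct_isotope_impurities(y, m)
            np.testing.assert_allclose(out, x, atol=1e-8 * max(1, x.max()))

    def test_matrix_rows_must_sum_to_one(self):
        bad = np.array([[0.9, 0.2], [0.1, 0.9]])
        with pytest.raises(ValueError, match="sum to 1"):
            rep.correct_isotope_impurities(np.ones(2), bad)

    def test_ill_conditioned_matrix_raises(self):
        m = np.array([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(rep.IllConditionedMatrixError):
            rep.correct_isotope_impurities(np.ones(2), m)

    def test_missing_values_restored(self):
        m = rt.tmt_like_impurity_matrix(3, 0.05)
        y = np.array([np.nan, 100.0, 50.0])
        out = rep.correct_isotope_impurities(y, m)
        assert np.isnan(out[0]) and not np.isnan(out[1:]).any()

    def test_dataframe_in_dataframe_out(self):
        m = rt.tmt_like_impurity_matrix(2, 0.05)
        df = pd.DataFrame([[90.0, 10.0]], columns=["126", "127"], index=[5])
        out = rep.correct_isotope_impurities(df, m)
        assert isinstance(out, pd.DataFrame)
        assert list(out.columns) == ["126", "127"] and list(out.index) == [5]


class TestZerosToMissing:
    @pytest.mark.parametrize(
        "row,expected_nan",
        [([0.0, 0.0], [True, True]), ([1.0, 2.0], [False, False]),
         ([0.0, 3.0], [True, False])],
    )
    def test_rules(self, row, expected_nan):
        out = rep.zeros_to_missing(np.array([row]))
        assert list(np.isnan(out[0])) == expected_nan


class TestSplitCarrier:
    def test_carrier_column_removed(self):
        design = rt.simple_design(["a", "b", "c"], 3, carrier=True)
        mat = pd.DataFrame(
            np.arange(20, dtype=float).reshape(2, 10), columns=design.names
        )
        samples, carrier = rep.split_carrier(mat, design)
        assert samples.shape == (2, 9)
        assert list(carrier) == [9.0, 19.0]
        # column conservation
        assert samples.shape[1] + 1 == mat.shape[1]

    def test_no_carrier_identity(self):
        design = rt.simple_design(["a", "b"], 2, carrier=False)
        mat = pd.DataFrame(np.ones((3, 4)), columns=design.names)
        samples, carrier = rep.split_carrier(mat, design)
        pd.testing.assert_frame_equal(samples, mat)
        assert carrier.empty

    def test_two_carriers_rejected_at_design(self):
        with pytest.raises(DesignError, match="carrier"):
            rt.ChannelDesign(
                channels=(
                    rt.Channel("1", is_carrier=True),
                    rt.Channel("2", is_carrier=True),
                )
            )


class TestNormalizeToProtein:
    def _inputs(self, pep_rows, prot_rows):
        cols = ["126", "127"]
        pep = pd.DataFrame(pep_rows, columns=cols, index=pd.Index(range(len(pep_rows)), name="id"))
        prot = pd.DataFrame(prot_rows, columns=cols, index=["P1"])
        link = pd.Series(["P1"] * len(pep_rows), index=pep.index)
        return pep, prot, link

    def test_identical_vectors_give_zero_log_ratio(self):
        pep, prot, link = self._inputs([[100.0, 100.0]], [[100.0, 100.0]])
        out, orphans = rep.normalize_to_protein(pep, prot, link)
        np.testing.assert_allclose(out.to_numpy(), 0.0)
        assert orphans.empty

    def test_scale_invariance(self):
        pep, prot, link = self._inputs([[200.0, 50.0]], [[100.0, 100.0]])
        base, _ = rep.normalize_to_protein(pep, prot, link)
        scaled, _ = rep.normalize_to_protein(pep * 7, prot * 7, link)
        pd.testing.assert_frame_equal(base, scaled)

    def test_log2_values(self):
        pep, prot, link = self._inputs([[200.0, 100.0]], [[100.0, 100.0]])
        out, _ = rep.normalize_to_protein(pep, prot, link)
        np.testing.assert_allclose(out.to_numpy(), [[1.0, 0.0]])

    def test_orphan_routed_with_reason(self):
        pep, prot, _ = self._inputs([[1.0, 1.0], [2.0, 2.0]], [[1.0, 1.0]])
        link = pd.Series(["P1", "MISSING"], index=pep.index)
        out, orphans = rep.normalize_to_protein(pep, prot, link)
        assert len(out) == 1 and len(orphans) == 1
        assert orphans.iloc[0]["reason"] == "no surviving protein group"

    def test_missing_propagates(self):
        pep, prot, link = self._inputs([[np.nan, 100.0]], [[100.0, np.nan]])
        out, _ = rep.normalize_to_protein(pep, prot, link)
        assert np.isnan(out.to_numpy()).all()


@given(
    scale=hst.floats(min_value=0.01, max_value=100.0),
    pep=hst.lists(hst.floats(min_value=1.0, max_value=1e6), min_size=2, max_size=2),
)
def test_normalization_invariant_to_global_rescale(scale, pep):
    cols = ["126", "127"]
    pep_df = pd.DataFrame([pep], columns=cols, index=pd.Index([0], name="id"))
    prot = pd.DataFrame([[50.0, 70.0]], columns=cols, index=["P1"])
    link = pd.Series(["P1"], index=pep_df.index)
    a, _ = rep.normalize_to_protein(pep_df, prot, link)
    b, _ = rep.normalize_to_protein(pep_df * scale, prot * scale, link)
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9)
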