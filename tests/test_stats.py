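"""Fold change, Wilcoxon signed-rank, selection, Spearman banding and
paired power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from conftest import make_table
from uromet.datamodel import ValidationError
from uromet.stats import (
    correlation_band,
    paired_power,
    paired_power_mc,
    select_biomarkers,
    signed_fold_change,
    spearman_matrix,
    wilcoxon_signed_rank,
)


def enumerate_signed_rank_p(d: np.ndarray) -> float:
    """Independent oracle: exact two-sided p by full enumeration of all
    2^n sign assignments of the (mid-)ranks."""
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=len(d))]
    ws = np.asarray(ws)
    n = len(ws)
    lo = (ws <= w_obs + 1e-9).sum() / n
    hi = (ws >= w_obs - 1e-9).sum() / n
    return min(1.0, 2 * min(lo, hi))


class TestSignedFoldChange:
    @pytest.mark.parametrize("ref,cmp,expect", [
        (948.0, 3037.0, 3.2),     # strong rise
        (15.4, 9.87, -1.6),       # signed decrease
        (5.0, 5.0, 1.0),          # identity
        (1.55, 10.8, 7.0),        # late persistent rise
    ])
    def test_one_decimal_values(self, ref, cmp, expect):
        assert round(signed_fold_change(ref, cmp), 1) == expect

    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4))
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry_and_magnitude_floor(self, a, b):
        fc = signed_fold_change(a, b)
        assert abs(fc) >= 1.0
        if a != b:
            assert fc == pytest.approx(-signed_fold_change(b, a), rel=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValidationError):
            signed_fold_change(0.0, 1.0)


class TestWilcoxon:
    def test_identical_vectors_give_degenerate_p_one(self):
        res = wilcoxon_signed_rank([1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5])
        assert res.p_value == 1.0 and res.degenerate

    def test_five_positive_differences(self):
        res = wilcoxon_signed_rank(np.zeros(5), np.arange(1.0, 6.0))
        assert res.p_value == pytest.approx(2 / 32)

    def test_twelve_same_sign_differences_reach_floor(self):
        res = wilcoxon_signed_rank(np.zeros(12), np.arange(1.0, 13.0))
        assert res.p_value == pytest.approx(2 / 4096)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 13)
        d = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding induces ties
        d = np.where(d == 0, 0.1, d)
        res = wilcoxon_signed_rank(np.zeros(n), d, method="exact")
        assert res.p_value == pytest.approx(enumerate_signed_rank_p(d),
                                            abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_scipy_without_ties(self, seed):
        rng = np.random.default_rng(seed + 100)
        x = rng.normal(size=10)
        y = x + rng.normal(0.5, 1.0, 10)
        ours = wilcoxon_signed_rank(x, y, method="exact").p_value
        ref = sps.wilcoxon(y, x, mode="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(0.3, 1.0, 30)
        ours = wilcoxon_signed_rank(x, y, method="approx").p_value
        ref = sps.wilcoxon(y, x, mode="approx", correction=False).pvalue
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_too_few_usable_pairs_rejected(self):
        with pytest.raises(ValidationError, match="5"):
            wilcoxon_signed_rank([1.0, 2, 3, 4], [2.0, 3, 4, 5])


class TestSpearman:
    def _table(self, seed=0, n=15, metabolites=3):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(1, 0.5, size=(n, metabolites))
        return make_table(vals, times=list(range(5)) * (n // 5),
                          subjects=[f"S{i % (n // 5):02d}" for i in range(n)],
                          normalized=True)

    def test_self_correlation_is_high_positive_unit(self):
        cm = spearman_matrix(self._table(), ["m1", "m2"])
        assert cm.rho.loc["m1", "m1"] == 1.0
        assert cm.band.loc["m1", "m1"] == "high_positive"

    def test_monotone_decrease_with_time_is_high_negative(self):
        n = 15
        times = np.array(list(range(5)) * 3)
        vals = np.column_stack([20.0 - 4.0 * times,  # strictly falls with hour
                                np.ones(n) + np.arange(n) % 3])
        t = make_table(vals, times=list(times),
                       subjects=[f"S{i % 3}" for i in range(n)],
                       normalized=True)
        cm = spearman_matrix(t, ["m1"], include_time=True)
        assert cm.rho.loc["m1", "time"] == pytest.approx(-1.0)
        assert cm.band.loc["m1", "time"] == "high_negative"

    def test_matches_naive_rank_correlation_oracle(self):
        t = self._table(seed=4, n=20, metabolites=13)
        cm = spearman_matrix(t, t.metabolites)
        X = t.values.to_numpy()
        for i in range(13):
            for j in range(13):
                ri = sps.rankdata(X[:, i])
                rj = sps.rankdata(X[:, j])
                rho = np.corrcoef(ri, rj)[0, 1]
                assert cm.rho.iloc[i, j] == pytest.approx(rho, abs=1e-12)

    def test_invariant_under_strictly_monotone_transform(self):
        t = self._table(seed=6)
        a = spearman_matrix(t, t.metabolites).rho
        warped = t.values.copy()
        warped["m1"] = np.exp(warped["m1"])
        warped["m2"] = warped["m2"] ** 3
        b = spearman_matrix(t.replace_values(warped), t.metabolites).rho
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_variable_flagged_undefined(self):
        t = self._table(seed=7)
        vals = t.values.copy()
        vals["m1"] = 2.0
        cm = spearman_matrix(t.replace_values(vals), t.metabolites)
        assert cm.constant == ["m1"]
        assert np.isnan(cm.rho.loc["m1", "m2"])
        assert cm.band.loc["m1", "m2"] == "undefined"

    @pytest.mark.parametrize("r,band", [
        (0.6, "high_positive"), (0.59, "positive"), (0.2, "positive"),
        (0.19, "neutral"), (-0.19, "neutral"), (-0.2, "negative"),
        (-0.59, "negative"), (-0.6, "high_negative"),
    ])
    def test_band_thresholds(self, r, band):
        assert correlation_band(r) == band


class TestSelectBiomarkers:
    def _table(self, seed=0, n_subj=6, fc=4.0):
        rng = np.random.default_rng(seed)
        rows, times, subjects = [], [], []
        for s in range(n_subj):
            base = rng.lognormal(1, 0.1, 3)
            for t in range(5):
                shift = np.array([fc if t == 1 else 1.0, 1.0, 1.0])
                rows.append(base * shift * rng.lognormal(0, 0.05, 3))
                times.append(t)
                subjects.append(f"S{s:02d}")
        return make_table(np.array(rows), subjects=subjects, times=times,
                          normalized=True)

    def test_triple_gate_conjunction(self):
        t = self._table()
        vip = pd.Series([2.0, 0.9, 1.5], index=["m1", "m2", "m3"])
        out = select_biomarkers(t, vip).set_index("metabolite")
        assert bool(out.loc["m1", "selected"])       # passes all three
        assert not bool(out.loc["m2", "selected"])   # VIP gate fails
        assert not bool(out.loc["m3", "selected"])   # FC/p gates fail

    def test_vip_gate_blocks_despite_huge_fold_change(self):
        t = self._table(fc=10.0)
        vip = pd.Series([0.9, 2.0, 2.0], index=["m1", "m2", "m3"])
        out = select_biomarkers(t, vip).set_index("metabolite")
        assert abs(out.loc["m1", "fc_0_1"]) > 1.5
        assert out.loc["m1", "p_0_1"] <= 0.05
        assert not bool(out.loc["m1", "selected"])

    def test_output_sorted_by_vip_descending(self):
        t = self._table()
        vip = pd.Series([0.5, 3.0, 1.2], index=["m1", "m2", "m3"])
        out = select_biomarkers(t, vip)
        assert out["vip"].is_monotonic_decreasing

    def test_fold_change_magnitude_floor_holds(self):
        t = self._table(seed=3)
        vip = pd.Series(1.0, index=t.metabolites)
        out = select_biomarkers(t, vip)
        for col in ("fc_0_1", "fc_0_4"):
            assert (out[col].abs() >= 1.0).all()

    def test_vip_mismatch_rejected(self):
        t = self._table()
        with pytest.raises(ValidationError, match="VIP"):
            select_biomarkers(t, pd.Series([1.0], index=["m1"]))

    def test_scaled_table_rejected(self):
        t = self._table()
        t.transform_state = "scaled"
        with pytest.raises(ValidationError, match="concentration"):
            select_biomarkers(t, pd.Series(1.0, index=t.metabolites))


class TestPairedPower:
    def test_reference_design_attains_acceptable_power(self):
        assert paired_power(0.9, 12, 0.05) == pytest.approx(0.81, abs=0.01)

    def test_null_effect_gives_alpha(self):
        for alpha in (0.01, 0.05, 0.2):
            assert paired_power(0.0, 12, alpha) == pytest.approx(alpha,
                                                                 abs=1e-9)

    def test_monotone_in_effect_size_and_sample_size(self):
        ds = [0.2, 0.5, 0.9, 1.5]
        ps = [paired_power(d, 12) for d in ds]
        assert all(np.diff(ps) > 0)
        ns = [6, 12, 24, 48]
        ps = [paired_power(0.5, n) for n in ns]
        assert all(np.diff(ps) > 0)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValidationError):
            paired_power(0.9, 12, 1.5)

    def test_monte_carlo_t_agrees_with_analytic(self):
        mc = paired_power_mc(0.9, 12, 0.05, test="t", n_rep=20_000, seed=0)
        assert mc == pytest.approx(paired_power(0.9, 12, 0.05), abs=0.02)

    def test_wilcoxon_mc_power_close_to_but_below_t(self):
        mc = paired_power_mc(0.9, 12, 0.05, test="wilcoxon", n_rep=20_000,
                             seed=1)
        t_power = paired_power(0.9, 12, 0.05)
        assert 0.6 < mc < t_power + 0.02
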