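"""Burden matrices, age-at-death OLS, sensitivity and subgroup tests."""

import numpy as np
import pandas as pd
import pytest
import dataclasses

import sdyburden as s
from sdyburden.annotate import FrequencyBins, filter_nonsynonymous
from sdyburden.ageburden import (
    adjust_across_bins,
    burden_matrix,
    compare_subgroups,
    fit_age_model,
    sensitivity_extremes,
)
from sdyburden.datatypes import variants_to_frame
from oracles import ols_normal_equations


def _variant(sample, gene, af, consequence="nonsynonymous"):
    return s.VariantRecord(
        sample_id=sample,
        gene=gene,
        contig="1",
        position=100,
        ref="A",
        alt="G",
        consequence_class=consequence,
        af_global=af,
    )


PANEL = s.GenePanel("p", frozenset({"G1", "G2"}))


class TestBurdenMatrix:
    def test_single_sample_bin_placement(self):
        variants = [
            _variant("s1", "G1", 1e-4),
            _variant("s1", "G1", 0.005),
            _variant("s1", "G2", 0.3),
        ]
        matrix = burden_matrix(variants, PANEL, samples=["s1"])
        assert matrix.loc["s1"].tolist() == [1, 1, 0, 0, 1]

    def test_zero_variant_samples_get_zero_rows(self):
        matrix = burden_matrix([], PANEL, samples=["s1", "s2"])
        assert matrix.shape == (2, 5)
        assert (matrix.to_numpy() == 0).all()

    def test_unknown_sample_fails(self):
        with pytest.raises(ValueError, match="absent from the manifest"):
            burden_matrix([_variant("ghost", "G1", 1e-4)], PANEL, samples=["s1"])

    def test_row_and_variant_order_invariance(self, small_study):
        nonsyn = filter_nonsynonymous(small_study.variants)
        cases = small_study.manifest.cases
        nonsyn = nonsyn[nonsyn["sample_id"].isin(cases)]
        panel = small_study.panels[0]
        a = burden_matrix(nonsyn, panel, samples=cases)
        shuffled = nonsyn.sample(frac=1.0, random_state=1)
        b = burden_matrix(shuffled, panel, samples=list(reversed(cases)))
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_overflow_frequencies_excluded(self):
        variants = [_variant("s1", "G1", 0.6)]
        matrix = burden_matrix(variants, PANEL, samples=["s1"])
        assert matrix.loc["s1"].sum() == 0


class TestFitAgeModel:
    def test_matches_normal_equations_on_six_points(self):
        age = pd.Series([1.0, 2.0, 5.0, 3.5, 8.0, 4.0],
                        index=[f"s{i}" for i in range(6)])
        burden = pd.Series([3, 2, 1, 2, 0, 1], index=age.index, dtype=float)
        pcs = pd.DataFrame(
            {"pc1": [0.1, -0.2, 0.0, 0.3, -0.1, 0.2]}, index=age.index
        )
        fit = fit_age_model(age, burden, pcs)
        X = np.column_stack(
            [np.ones(6), burden.to_numpy(), pcs["pc1"].to_numpy()]
        )
        beta, se = ols_normal_equations(X, age.to_numpy())
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert fit.stderr == pytest.approx(se[1], abs=1e-10)

    def test_planted_negative_slope_recovered(self):
        rng = np.random.default_rng(4)
        n = 200
        idx = [f"s{i}" for i in range(n)]
        burden = pd.Series(rng.poisson(3.0, n).astype(float), index=idx)
        pcs = pd.DataFrame(rng.normal(size=(n, 2)), index=idx, columns=["pc1", "pc2"])
        age = pd.Series(
            10.0 - 0.5 * burden + rng.normal(0, 0.5, n), index=idx
        )
        fit = fit_age_model(age, burden, pcs)
        assert fit.slope == pytest.approx(-0.5, abs=2 * fit.stderr)
        assert fit.p_raw < 0.001

    def test_constant_age_refused(self):
        idx = [f"s{i}" for i in range(10)]
        age = pd.Series(5.0, index=idx)
        burden = pd.Series(np.arange(10, dtype=float), index=idx)
        pcs = pd.DataFrame({"pc1": np.random.default_rng(0).normal(size=10)}, index=idx)
        with pytest.raises(ValueError, match="zero variance"):
            fit_age_model(age, burden, pcs)

    def test_collinear_design_refused(self):
        idx = [f"s{i}" for i in range(12)]
        burden = pd.Series(np.arange(12, dtype=float), index=idx)
        pcs = pd.DataFrame({"pc1": 2.0 * burden}, index=idx)
        age = pd.Series(np.random.default_rng(0).normal(5, 1, 12), index=idx)
        with pytest.raises(ValueError, match="collinear"):
            fit_age_model(age, burden, pcs)

    def test_too_few_complete_cases_refused(self):
        idx = [f"s{i}" for i in range(8)]
        age = pd.Series([1.0, 2, 3, np.nan, np.nan, np.nan, np.nan, np.nan], index=idx)
        burden = pd.Series(np.arange(8, dtype=float), index=idx)
        pcs = pd.DataFrame(
            np.random.default_rng(0).normal(size=(8, 6)),
            index=idx,
            columns=[f"pc{i}" for i in range(1, 7)],
        )
        with pytest.raises(ValueError, match="complete cases"):
            fit_age_model(age, burden, pcs)


class TestAdjustAcrossBins:
    def _fits(self, pvals):
        from sdyburden.ageburden import AgeModelFit

        return [
            AgeModelFit(
                bin=f"b{i}", slope=0.0, stderr=1.0, p_raw=p, p_adjusted=None,
                n=10, n_pcs=0,
            )
            for i, p in enumerate(pvals)
        ]

    def test_ties_unchanged(self):
        fits = adjust_across_bins(self._fits([0.2] * 5))
        assert all(f.p_adjusted == pytest.approx(0.2) for f in fits)

    def test_single_small_p_among_ones(self):
        fits = adjust_across_bins(self._fits([0.004, 1.0, 1.0, 1.0, 1.0]))
        assert fits[0].p_adjusted == pytest.approx(min(5 * 0.004, 1.0))

    def test_hand_applied_stepup(self):
        raw = [0.01, 0.04, 0.03, 0.005, 0.2]
        fits = adjust_across_bins(self._fits(raw))
        # BH by hand: sorted (0.005,0.01,0.03,0.04,0.2) ->
        # q = (0.025, 0.025, 0.05, 0.05, 0.2)
        expected = {0.005: 0.025, 0.01: 0.025, 0.03: 0.05, 0.04: 0.05, 0.2: 0.2}
        for f in fits:
            assert f.p_adjusted == pytest.approx(expected[f.p_raw])
        assert all(f.p_adjusted >= f.p_raw for f in fits)


class TestSensitivityExtremes:
    def _pcs(self, idx, rng):
        return pd.DataFrame({"pc1": rng.normal(size=len(idx))}, index=idx)

    def test_null_data_stays_null(self):
        rng = np.random.default_rng(6)
        idx = [f"s{i}" for i in range(80)]
        burden = pd.Series(rng.poisson(2.0, 80).astype(float), index=idx)
        age = pd.Series(rng.normal(5, 2, 80), index=idx)
        full, trimmed = sensitivity_extremes(age, burden, self._pcs(idx, rng))
        assert full.p_raw > 0.05 and trimmed.p_raw > 0.05
        assert trimmed.extreme_excluded and trimmed.n_excluded > 0

    def test_single_outlier_driven_slope_loses_significance(self):
        rng = np.random.default_rng(8)
        n = 40
        idx = [f"s{i}" for i in range(n)]
        burden = pd.Series(
            np.r_[rng.integers(0, 3, n - 1), 40].astype(float), index=idx
        )
        age = pd.Series(np.r_[rng.normal(10, 1, n - 1), 0.1], index=idx)
        full, trimmed = sensitivity_extremes(age, burden, self._pcs(idx, rng))
        assert full.p_raw < 0.01          # the outlier fabricates the signal
        assert trimmed.p_raw > 0.05       # it vanishes without the extremes

    def test_planted_effect_survives_trimming(self):
        retained_sign = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            n = 150
            idx = [f"s{i}" for i in range(n)]
            burden = pd.Series(rng.poisson(3.0, n).astype(float), index=idx)
            age = pd.Series(8.0 - 0.5 * burden + rng.normal(0, 1.0, n), index=idx)
            _, trimmed = sensitivity_extremes(age, burden, self._pcs(idx, rng))
            retained_sign += trimmed.slope < 0
        assert retained_sign >= 8

    def test_overtrimming_refused(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(8)]
        burden = pd.Series([0.0] * 4 + [5.0] * 4, index=idx)
        age = pd.Series(rng.normal(5, 1, 8), index=idx)
        pcs = pd.DataFrame(rng.normal(size=(8, 6)), index=idx,
                           columns=[f"pc{i}" for i in range(1, 7)])
        with pytest.raises(ValueError):
            sensitivity_extremes(age, burden, pcs)


class TestCompareSubgroups:
    def test_identical_distributions_give_p_one(self):
        burden = pd.Series(
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            index=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        res = compare_subgroups(burden, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert res.method == "exact" and res.p_value == 1.0

    def test_fully_separated_three_vs_three(self):
        burden = pd.Series(
            {"a1": 1.0, "a2": 2.0, "a3": 3.0, "b1": 10.0, "b2": 11.0, "b3": 12.0}
        )
        res = compare_subgroups(burden, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments

    def test_exact_agrees_with_scipy_when_no_ties(self):
        from scipy import stats

        rng = np.random.default_rng(12)
        values = rng.normal(size=13)
        burden = pd.Series(values, index=[f"x{i}" for i in range(13)])
        a, b = [f"x{i}" for i in range(6)], [f"x{i}" for i in range(6, 13)]
        res = compare_subgroups(burden, a, b)
        ref = stats.mannwhitneyu(
            values[:6], values[6:], alternative="two-sided", method="exact"
        )
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(2)
        idx = [f"x{i}" for i in range(21)]
        burden = pd.Series(rng.poisson(3.0, 21).astype(float), index=idx)
        res = compare_subgroups(burden, idx[:6], idx[6:])
        assert res.method == "normal"
        assert 0.0 < res.p_value <= 1.0

    def test_overlap_rejected(self):
        burden = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValueError, match="overlap"):
            compare_subgroups(burden, ["a", "b"], ["b", "c"])

    def test_empty_group_rejected(self):
        burden = pd.Series({"a": 1.0})
        with pytest.raises(ValueError):
            compare_subgroups(burden, ["a"], [])
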