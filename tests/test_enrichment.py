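"""Resampling null, empirical p, Fisher test, FDR, Z-scores."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import sdyburden as s
from sdyburden.enrichment import (
    NullDistribution,
    damaged_gene_count,
    empirical_p,
    fdr_adjust,
    fisher_case_control,
    resample_null,
    run_enrichment,
    zscore,
)
from oracles import fisher_exact_enumeration, hypergeometric_mean


def _calls(entries) -> s.DamageCallSet:
    return s.DamageCallSet(
        pd.DataFrame(entries, columns=["sample_id", "gene", "score"])
    )


class TestDamagedGeneCount:
    def test_hand_enumeration_toy(self):
        # 4 samples x 6 genes; damaged iff any sample in the arm >= 0.69
        calls = _calls(
            [
                ("s1", "G1", 0.8),
                ("s1", "G2", 0.1),
                ("s2", "G2", 0.7),
                ("s2", "G3", 0.68),
                ("s3", "G4", 1.5),
                ("s4", "G5", 0.2),
                ("s4", "G6", 0.69),
            ]
        )
        gene_list = {"G1", "G2", "G3", "G4", "G5", "G6"}
        # arm {s1,s2}: G1 (0.8), G2 (0.7) -> 2
        assert damaged_gene_count(calls, gene_list, ["s1", "s2"]) == 2
        # arm {s3,s4}: G4, G6 -> 2;  G5 below threshold
        assert damaged_gene_count(calls, gene_list, ["s3", "s4"]) == 2
        # whole cohort: G1, G2, G4, G6
        assert damaged_gene_count(calls, gene_list, ["s1", "s2", "s3", "s4"]) == 4

    def test_none_reach_threshold(self):
        calls = _calls([("s1", "G1", 0.5), ("s2", "G2", 0.68)])
        assert damaged_gene_count(calls, {"G1", "G2"}, ["s1", "s2"]) == 0

    def test_all_damaged_equals_list_size(self):
        calls = _calls([("s1", g, 0.9) for g in ("G1", "G2", "G3")])
        assert damaged_gene_count(calls, {"G1", "G2", "G3"}, ["s1"]) == 3

    def test_empty_list_fails(self):
        calls = _calls([("s1", "G1", 0.9)])
        with pytest.raises(ValueError):
            damaged_gene_count(calls, set(), ["s1"])


class TestResampleNull:
    def test_damaged_equals_universe(self):
        symbols = [f"G{i}" for i in range(20)]
        null = resample_null(symbols, 5, set(symbols), n_draws=500, seed=1)
        assert (null.draws == 5).all() and null.sd == 0.0

    def test_damaged_empty(self):
        symbols = [f"G{i}" for i in range(20)]
        null = resample_null(symbols, 5, set(), n_draws=500, seed=1)
        assert (null.draws == 0).all()

    def test_mean_matches_hypergeometric_closed_form(self):
        symbols = [f"G{i}" for i in range(20)]
        damaged = set(symbols[:8])
        null = resample_null(symbols, 5, damaged, n_draws=20_000, seed=7)
        expected = hypergeometric_mean(5, 8, 20)
        assert expected == 2.0
        # 4 standard errors of the Monte-Carlo mean
        se = null.sd / np.sqrt(null.n_draws)
        assert abs(null.mean - expected) <= 4 * se

    def test_list_larger_than_universe_fails(self):
        with pytest.raises(ValueError):
            resample_null(["G1", "G2"], 3, set(), n_draws=10, seed=1)

    def test_seeded_reproducibility(self):
        symbols = [f"G{i}" for i in range(30)]
        a = resample_null(symbols, 10, set(symbols[:7]), n_draws=1000, seed=3)
        b = resample_null(symbols, 10, set(symbols[:7]), n_draws=1000, seed=3)
        assert (a.draws == b.draws).all()


class TestEmpiricalP:
    def _null(self, draws):
        draws = np.asarray(draws)
        return NullDistribution(
            draws=draws, n_draws=len(draws), list_size=100, universe_size=1000, seed=0
        )

    def test_observed_beyond_all_draws(self):
        null = self._null([1, 2, 3, 4])
        assert empirical_p(10, null) == 1 / 5

    def test_observed_below_all_draws(self):
        null = self._null([5, 6, 7, 8])
        assert empirical_p(1, null) == 1.0

    def test_observed_at_median_of_symmetric_null(self):
        draws = np.concatenate([np.full(500, 4), np.full(500, 6), [5]])
        null = self._null(draws)
        assert empirical_p(5, null) == pytest.approx(0.5, abs=0.01)

    def test_bounds(self):
        null = self._null(np.arange(100))
        for obs in (0, 50, 99, 200):
            p = empirical_p(obs, null)
            assert 1 / 101 <= p <= 1.0


class TestFisher:
    def test_identical_arms_give_p_one(self):
        assert fisher_case_control(7, 7, 20) == 1.0

    @pytest.mark.parametrize(
        "case_damaged,control_damaged,list_size",
        [(3, 1, 4), (10, 0, 10), (5, 2, 14), (7, 12, 15)],
    )
    def test_matches_enumeration_oracle(self, case_damaged, control_damaged, list_size):
        got = fisher_case_control(case_damaged, control_damaged, list_size)
        want = fisher_exact_enumeration(
            case_damaged,
            control_damaged,
            list_size - case_damaged,
            list_size - control_damaged,
        )
        assert got == pytest.approx(want, rel=1e-9)

    def test_strong_imbalance_significant(self):
        p = fisher_case_control(10, 0, 10)
        assert p == pytest.approx(fisher_exact_enumeration(10, 0, 0, 10), rel=1e-9)
        assert p < 0.01

    def test_negative_cells_fail(self):
        with pytest.raises(ValueError):
            fisher_case_control(5, 2, 4)  # 4-5 < 0


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepup_hand_example(self):
        # sorted p (0.01,0.02,0.03,0.04): q_i = min_j>=i (4/j) p_j = 0.04 each
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        assert (fdr_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_fails(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        assert (fdr_adjust(p) >= p).all()


class TestZscore:
    def _null(self):
        rng = np.random.default_rng(0)
        draws = rng.binomial(50, 0.3, size=5000)
        return NullDistribution(
            draws=draws, n_draws=5000, list_size=50, universe_size=500, seed=0
        )

    def test_zero_at_mean_and_two_at_two_sd(self):
        null = self._null()
        assert zscore(null.mean, null) == pytest.approx(0.0)
        assert zscore(null.mean + 2 * null.sd, null) == pytest.approx(2.0)

    def test_degenerate_null_reports_nan(self):
        null = NullDistribution(
            draws=np.full(100, 3), n_draws=100, list_size=5, universe_size=50, seed=0
        )
        assert np.isnan(zscore(4, null))


def _study(effect: float, seed: int) -> s.SimulatedStudy:
    return s.simulate_study(
        s.SimulationConfig(
            n_genes=400,
            n_cases=60,
            n_controls=60,
            panel_specs=(s.PanelSpec("p", 50),),
            damaged_fraction=0.004,
            enrichment_effect=effect,
            seed=seed,
        )
    )


class TestFullStage:
    def test_result_invariants_on_null_study(self, small_study):
        results = run_enrichment(
            small_study.panels,
            small_study.universe,
            small_study.damage,
            small_study.manifest,
            n_draws=2000,
            seed=5,
        )
        (r,) = results
        B = r.n_draws
        assert 1 / (B + 1) <= r.empirical_p_case <= 1.0
        assert 1 / (B + 1) <= r.empirical_p_control <= 1.0
        assert r.fdr_q >= r.empirical_p_case
        assert np.isfinite(r.z_case) and np.isfinite(r.z_control)
        assert 0 <= r.case_damaged <= r.list_size

    def test_zscore_monotone_in_planted_effect(self):
        mean_z = []
        for effect in (1.0, 2.5, 6.0):
            zs = []
            for seed in range(4):
                study = _study(effect, 100 + seed)
                (res,) = run_enrichment(
                    study.panels,
                    study.universe,
                    study.damage,
                    study.manifest,
                    n_draws=2000,
                    seed=seed,
                )
                zs.append(res.z_case)
            mean_z.append(np.mean(zs))
        assert mean_z[0] < mean_z[1] < mean_z[2]

    def test_case_z_exceeds_control_z_under_planted_effect(self):
        wins = 0
        for seed in range(5):
            study = _study(4.0, 200 + seed)
            (res,) = run_enrichment(
                study.panels,
                study.universe,
                study.damage,
                study.manifest,
                n_draws=2000,
                seed=seed,
            )
            wins += res.z_case > res.z_control
        assert wins >= 4

    def test_panel_outside_universe_rejected(self, small_study):
        rogue = s.GenePanel("rogue", frozenset({"NOT_IN_UNIVERSE"}))
        with pytest.raises(ValueError, match="outside the universe"):
            run_enrichment(
                [rogue],
                small_study.universe,
                small_study.damage,
                small_study.manifest,
                n_draws=100,
                seed=1,
            )

    def test_arm_label_permutation_leaves_null_statistics_exchangeable(
        self, small_study
    ):
        """Under the null, swapping arm labels yields a statistic of the
        same magnitude class (sanity check of exchangeability)."""
        manifest = small_study.manifest
        swapped = manifest.frame.copy()
        swapped["arm"] = swapped["arm"].map({"case": "control", "control": "case"})
        orig = run_enrichment(
            small_study.panels, small_study.universe, small_study.damage,
            manifest, n_draws=1000, seed=3,
        )[0]
        swap = run_enrichment(
            small_study.panels, small_study.universe, small_study.damage,
            s.CohortManifest(swapped), n_draws=1000, seed=3,
        )[0]
        assert orig.case_damaged == swap.control_damaged
        assert orig.control_damaged == swap.case_damaged
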