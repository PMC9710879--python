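"""Effect ratios, rescue regression, overlap concordance, enrichment."""

import numpy as np
import pandas as pd
import pytest

import generescue as gr
from generescue.rescue import (
    RtmControl,
    effect_ratios,
    enrichment,
    fit_rescue,
    genotype_means,
    overlap_analysis,
    report_gene_panel,
    rtm_control,
)


class TestGenotypeMeans:
    def test_replicate_average(self):
        norm = pd.DataFrame(
            {"WT_1": [10.0], "WT_2": [30.0], "NipblHet_1": [40.0],
             "WaplHet_1": [8.0], "Double_1": [12.0]},
            index=["g"],
        )
        samples = pd.DataFrame(
            {"genotype": ["WT", "WT", "NipblHet", "WaplHet", "Double"]},
            index=norm.columns,
        )
        prof = genotype_means(norm, samples)
        assert prof.loc["g", "WT"] == 20.0
        assert prof.loc["g", "NipblHet"] == 40.0

    def test_sample_permutation_invariance(self, small_sim):
        _, counts, samples, _ = small_sim
        norm = gr.normalize_counts(counts, gr.size_factors(counts))
        shuffled = norm.sample(frac=1.0, axis=1, random_state=1)
        pd.testing.assert_frame_equal(
            genotype_means(norm, samples), genotype_means(shuffled, samples)
        )

    def test_missing_genotype_named(self):
        norm = pd.DataFrame({"WT_1": [1.0]}, index=["g"])
        samples = pd.DataFrame({"genotype": ["WT"]}, index=["WT_1"])
        with pytest.raises(ValueError, match="NipblHet"):
            genotype_means(norm, samples)


class TestEffectRatios:
    def test_identity_and_doubling(self, toy_profile):
        eff = effect_ratios(toy_profile, pseudocount=0.0,
                            genes=["up_rescued", "down_unrescued"])
        assert eff.loc["up_rescued", "e_N"] == pytest.approx(1.0)
        assert eff.loc["up_rescued", "e_D"] == pytest.approx(0.0)
        assert eff.loc["down_unrescued", "e_N"] == pytest.approx(-1.0)

    def test_zero_over_zero_is_zero(self, toy_profile):
        eff = effect_ratios(toy_profile)
        assert eff.loc["silent"].eq(0.0).all()

    def test_antisymmetry_of_swapped_ratio(self, toy_profile):
        # log2(mut/WT) = -log2(WT/mut): swap numerator and denominator
        eff = effect_ratios(toy_profile, pseudocount=0.5)
        swapped = toy_profile.rename(
            columns={"WT": "NipblHet", "NipblHet": "WT"}
        )
        eff_sw = effect_ratios(swapped, pseudocount=0.5)
        assert np.allclose(eff["e_N"], -eff_sw["e_N"])

    def test_negative_pseudocount_rejected(self, toy_profile):
        with pytest.raises(ValueError):
            effect_ratios(toy_profile, pseudocount=-0.5)


class TestFitRescue:
    @staticmethod
    def _effects(e_n, e_d):
        return pd.DataFrame(
            {"e_N": e_n, "e_W": e_n, "e_D": e_d},
            index=[f"g{i}" for i in range(len(e_n))],
        )

    def test_no_rescue_slope_one(self):
        e = [0.5, 1.0, -0.5, 2.0]
        fit = fit_rescue(self._effects(e, e), [f"g{i}" for i in range(4)])
        assert fit.slope == pytest.approx(1.0)
        assert fit.rescue_percent == pytest.approx(0.0)

    def test_complete_rescue_slope_zero(self):
        fit = fit_rescue(
            self._effects([0.5, 1.0, -0.5], [0.0, 0.0, 0.0]), ["g0", "g1", "g2"]
        )
        assert fit.slope == pytest.approx(0.0)
        assert fit.rescue_percent == pytest.approx(100.0)

    def test_exact_half_line(self):
        fit = fit_rescue(
            self._effects([1.0, 2.0, -1.0], [0.5, 1.0, -0.5]), ["g0", "g1", "g2"]
        )
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rescue_percent == pytest.approx(50.0)

    def test_slope_invariant_to_gene_order_and_scaling(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(scale=0.1, size=30)
        eff = self._effects(x, y)
        genes = list(eff.index)
        a = fit_rescue(eff, genes)
        b = fit_rescue(eff, genes[::-1])
        assert a.slope == pytest.approx(b.slope)
        scaled = fit_rescue(self._effects(3 * x, 3 * y), genes)
        assert scaled.slope == pytest.approx(a.slope)
        assert scaled.r_squared == pytest.approx(a.r_squared)

    def test_rescue_percent_identity(self):
        rng = np.random.default_rng(4)
        eff = self._effects(rng.normal(size=10), rng.normal(size=10))
        fit = fit_rescue(eff, list(eff.index))
        assert fit.rescue_percent + 100.0 * fit.slope == pytest.approx(100.0)

    def test_degenerate_inputs_rejected(self):
        eff = self._effects([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="variance"):
            fit_rescue(eff, list(eff.index))
        with pytest.raises(ValueError, match="3 genes"):
            fit_rescue(eff, ["g0", "g1"])

    def test_parameter_recovery_from_expected_profiles(self, default_sim):
        # on the noiseless genotype profile the configured damping
        # coefficient is recovered to well within +-0.05
        cfg, _, _, effects = default_sim
        prof = gr.expected_profile(effects)
        eff = effect_ratios(prof)
        dys = list(effects.index[effects["dysregulated"]])
        fit = fit_rescue(eff, dys, axis="N")
        assert fit.slope == pytest.approx(cfg.rescue_r, abs=0.02)

    def test_deg_pipeline_slope_attenuated_but_substantial(self, default_sim,
                                                           default_de):
        # with count noise at 3 Nipbl replicates the DEG-set slope is
        # attenuated below the configured 0.58 but far from 0 and 1:
        # rescue is detected, its magnitude biased toward zero
        _, counts, samples, effects = default_sim
        norm = gr.normalize_counts(counts, gr.size_factors(counts))
        eff = effect_ratios(
            genotype_means(norm, samples).loc[default_de.index]
        )
        degs = list(default_de.index[default_de["isDEG"]])
        fit = fit_rescue(eff, degs, axis="N")
        assert 0.35 < fit.slope < 0.62
        assert fit.r_squared > 0.5


class TestRtmControl:
    def test_subset_union_identical(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        eff = pd.DataFrame(
            {"e_N": x, "e_W": x, "e_D": 0.5 * x},
            index=[f"g{i}" for i in range(40)],
        )
        primary = [f"g{i}" for i in range(40)]
        double = primary[:10]  # subset: union unchanged
        ctrl = rtm_control(eff, primary, double)
        assert isinstance(ctrl, RtmControl)
        assert ctrl.slope_difference == pytest.approx(0.0)
        assert ctrl.union.n_genes == 40

    def test_empty_double_set_rejected(self):
        eff = pd.DataFrame({"e_N": [1.0], "e_W": [1.0], "e_D": [1.0]},
                           index=["g"])
        with pytest.raises(ValueError):
            rtm_control(eff, ["g"], [])

    def test_control_slope_close_on_simulation(self, default_sim, default_de):
        _, counts, samples, _ = default_sim
        norm = gr.normalize_counts(counts, gr.size_factors(counts))
        eff = effect_ratios(genotype_means(norm, samples).loc[default_de.index])
        de_d = gr.run_de(counts, samples, ("Double", "WT"))
        primary = list(default_de.index[default_de["isDEG"]])
        double = [g for g in de_d.index[de_d["isDEG"]] if g in eff.index]
        ctrl = rtm_control(eff, primary, double)
        assert abs(ctrl.slope_difference) < 0.1


class TestOverlapAnalysis:
    @staticmethod
    def _de(flags, lfcs=None):
        idx = [f"g{i}" for i in range(len(flags))]
        return pd.DataFrame(
            {"isDEG": flags,
             "log2FC": lfcs if lfcs is not None else np.ones(len(flags))},
            index=idx,
        )

    def test_hand_chi_square(self):
        # universe 100, 2x2 table [[30,20],[20,30]]: expected 25 per cell,
        # chi2 = 4 * 25/25 = 4.000
        a = self._de([True] * 50 + [False] * 50)
        b = self._de([True] * 30 + [False] * 20 + [True] * 20 + [False] * 30)
        ov = overlap_analysis(a, b)
        assert ov.chi_square == pytest.approx(4.000)
        assert ov.n_shared == 30
        assert ov.n_universe == 100

    def test_identical_sets(self):
        flags = [True] * 10 + [False] * 30
        ov = overlap_analysis(self._de(flags), self._de(flags))
        assert ov.n_shared == ov.n_a == ov.n_b == 10
        assert ov.n_same_direction == 10

    def test_direction_partition(self):
        a = self._de([True] * 4, [1.0, 1.0, -1.0, -1.0])
        b = self._de([True] * 4, [1.0, -1.0, -1.0, 1.0])
        ov = overlap_analysis(a, b)
        assert ov.n_same_direction == 2
        assert ov.n_opposite_direction == 2
        assert ov.n_same_direction + ov.n_opposite_direction == ov.n_shared

    def test_independent_sets_null_chi_square(self):
        rng = np.random.default_rng(6)
        stats = []
        for _ in range(50):
            a = self._de(rng.random(400) < 0.3)
            b = self._de(rng.random(400) < 0.3)
            stats.append(overlap_analysis(a, b).p_value)
        # p-values roughly uniform: mean near 0.5, few tiny values
        assert 0.35 < np.mean(stats) < 0.65

    def test_disjoint_universe_rejected(self):
        a = self._de([True])
        b = self._de([True])
        b.index = ["other"]
        with pytest.raises(ValueError, match="disjoint"):
            overlap_analysis(a, b)

    def test_shared_effect_correlation_reported(self, default_sim, default_de):
        _, counts, samples, effects = default_sim
        norm = gr.normalize_counts(counts, gr.size_factors(counts))
        eff = effect_ratios(genotype_means(norm, samples).loc[default_de.index])
        de_w = gr.run_de(counts, samples, ("WaplHet", "WT"))
        ov = overlap_analysis(default_de, de_w, eff)
        assert ov.chi_square > 100  # strongly dependent DEG sets
        assert ov.correlation > 0.5  # correlated single-mutant effects


class TestEnrichment:
    def test_exact_hypergeometric(self):
        # P(both hits in a 2-gene set) = 1/C(5,2) = 0.1
        res = enrichment(["a", "b"], ["a", "b", "c", "d", "e"],
                         {"s": ["a", "b"]})
        assert res.loc["s", "pvalue"] == pytest.approx(0.1)

    def test_whole_universe_set_p_one(self):
        res = enrichment(["a"], ["a", "b", "c"], {"s": ["a", "b", "c"]})
        assert res.loc["s", "pvalue"] == pytest.approx(1.0)

    def test_disjoint_set_p_one(self):
        res = enrichment(["a"], ["a", "b"], {"s": ["x", "y"]})
        assert res.loc["s", "pvalue"] == pytest.approx(1.0)
        assert res.loc["s", "overlap"] == 0

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            enrichment(["z"], ["a", "b"], {"s": ["a"]})


class TestGenePanel:
    def test_empty_panel(self, default_de):
        report = report_gene_panel({"N": default_de}, [])
        assert len(report) == 0

    def test_unknown_gene_flagged(self, default_de):
        report = report_gene_panel({"N": default_de}, ["no_such_gene"])
        assert not report.loc["no_such_gene", "in_universe"]

    def test_downregulated_panel_reported_down(self, default_sim, default_de):
        _, _, _, effects = default_sim
        down = effects[
            effects["dysregulated"] & (effects["delta_N"] < -0.5)
            & (effects["baseline_mean"] > 200)
        ].index[:10]
        report = report_gene_panel({"N": default_de}, list(down))
        present = report[report["in_universe"]]
        assert (present["direction_N"] == "down").mean() > 0.9
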