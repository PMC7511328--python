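"""Generator contracts: determinism, calibration, phase opposition, plates."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kogrowth import synthetic as S
from kogrowth import growth as G
from kogrowth import periodicity as P
from kogrowth.errors import CalibrationError, ConfigError, PlacementError


def cfg(**kw):
    return S.SyntheticConfig(**{"n_genes": 400, "seed": 3, **kw})


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        {"genome_length_kb": 0},
        {"essential_fraction": 1.0},
        {"essential_fraction": -0.1},
        {"target_rho": 0.5},
        {"expr_noise_sd": -1.0},
        {"n_replicates": 0},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            cfg(**bad)


class TestAnnotation:
    def test_zero_essential_fraction(self):
        ann = S.generate_annotation(cfg(n_genes=4, essential_fraction=0.0,
                                        genome_length_kb=100))
        assert len(ann) == 4
        assert not ann["essential"].any()

    def test_essential_count_in_binomial_interval(self):
        ann = S.generate_annotation(cfg(n_genes=4000, essential_fraction=0.07))
        lo = stats.binom.ppf(0.005, 4000, 0.07)
        hi = stats.binom.ppf(0.995, 4000, 0.07)
        assert lo <= ann["essential"].sum() <= hi

    def test_same_seed_identical_output(self):
        a = S.generate_annotation(cfg())
        b = S.generate_annotation(cfg())
        pd.testing.assert_frame_equal(a, b)

    def test_midpoints_within_genome(self):
        ann = S.generate_annotation(cfg())
        mids = P.gene_midpoints_kb(ann, 4632)
        assert (mids >= 0).all() and (mids < 4632).all()

    def test_placement_failure(self):
        with pytest.raises(PlacementError):
            S.generate_annotation(cfg(n_genes=5000, genome_length_kb=100))


class TestExpression:
    def test_zero_amplitude_zero_noise_is_deterministic_baseline(self):
        c = cfg(positional_amplitude_expr=0.0, expr_noise_sd=0.0)
        ann = S.generate_annotation(c)
        expr = S.generate_expression(ann, c, "LB")
        reps = expr[[x for x in expr.columns if x.startswith("rep")]]
        # all replicates equal baseline + gene effect exactly
        assert (reps.nunique(axis=1) == 1).all()

    def test_sliding_window_recovers_attenuated_cosine(self):
        c = cfg(n_genes=4632, genome_length_kb=4632, expr_gene_sd=0.0,
                expr_noise_sd=0.0, positional_amplitude_expr=0.3,
                essential_fraction=0.0)
        ann = S.generate_annotation(c)
        expr = S.generate_expression(ann, c, "LB")
        sig = P.positional_signal(
            ann, expr.set_index("gene")["mean"], mode="nonessential_only",
            genome_length_kb=4632, window_kb=100,
        )
        amp, _, _ = P.fit_sinusoid(sig, c.n_periods)
        N, W, k = 4632, 100, c.n_periods
        atten = abs(np.sin(np.pi * k * W / N) / (W * np.sin(np.pi * k / N)))
        # random gene placement within bins blurs the phase slightly
        assert amp == pytest.approx(0.3 * atten, rel=0.05)

    def test_determinism(self):
        c = cfg()
        ann = S.generate_annotation(c)
        pd.testing.assert_frame_equal(
            S.generate_expression(ann, c, "M63"), S.generate_expression(ann, c, "M63")
        )


class TestGrowthTruth:
    def test_perfect_anticorrelation_limit(self):
        c = cfg(target_rho=-1.0, growth_noise_sd=0.0,
                positional_amplitude_growth=0.0)
        ann = S.generate_annotation(c)
        expr = S.generate_expression(ann, c, "LB")
        truth = S.generate_growth_truth(ann, expr, c, "LB")
        ne = ~truth["essential"]
        rho = stats.spearmanr(expr.loc[ne, "mean"], truth.loc[ne, "true_mu"])[0]
        assert rho == pytest.approx(-1.0)

    def test_null_target(self):
        c = cfg(n_genes=2000, target_rho=0.0)
        ann = S.generate_annotation(c)
        expr = S.generate_expression(ann, c, "LB")
        truth = S.generate_growth_truth(ann, expr, c, "LB")
        assert abs(truth.attrs["realized_rho"]) < 0.05

    @pytest.mark.parametrize("seed", [0, 1])
    @pytest.mark.parametrize("target", [-0.6, -0.37, -0.2])
    def test_calibration_recovers_target(self, target, seed):
        c = cfg(n_genes=2000, target_rho=target, seed=seed)
        ann = S.generate_annotation(c)
        expr = S.generate_expression(ann, c, "LB")
        truth = S.generate_growth_truth(ann, expr, c, "LB")
        assert truth.attrs["realized_rho"] == pytest.approx(target, abs=0.05)

    def test_phase_opposition_of_positional_components(self):
        # noise-free generator: expression and growth positional series are
        # anti-phase as 1-kb window means
        c = cfg(n_genes=4632, genome_length_kb=4632, expr_gene_sd=0.0,
                expr_noise_sd=0.0, growth_noise_sd=0.0, target_rho=-1.0,
                essential_fraction=0.0)
        ann = S.generate_annotation(c)
        expr = S.generate_expression(ann, c, "LB")
        truth = S.generate_growth_truth(ann, expr, c, "LB")
        sig_e = P.positional_signal(ann, expr.set_index("gene")["mean"],
                                    mode="nonessential_only", genome_length_kb=4632)
        sig_g = P.positional_signal(ann, truth.set_index("gene")["true_mu"],
                                    mode="nonessential_only", genome_length_kb=4632)
        r = np.corrcoef(sig_e.values, sig_g.values)[0, 1]
        assert r <= -0.95

    def test_planted_slow_category_depressed(self):
        c = cfg(planted_slow_category="e", planted_slow_delta=0.3)
        ann = S.generate_annotation(c)
        expr = S.generate_expression(ann, c, "LB")
        truth = S.generate_growth_truth(ann, expr, c, "LB")
        in_cat = truth["category"] == "e"
        assert truth.loc[in_cat, "true_mu"].mean() < truth.loc[~in_cat, "true_mu"].mean() - 0.2


class TestPlateCurves:
    def small_truth(self, c, n=20, medium="LB"):
        ann = S.generate_annotation(c)
        expr = S.generate_expression(ann, c, medium)
        truth = S.generate_growth_truth(ann, expr, c, medium)
        return truth[~truth["essential"]].head(n).reset_index(drop=True)

    def test_thirty_minute_interval_over_24h_gives_49_points(self):
        c = cfg(sampling_interval_h=0.5, duration_h=24.0)
        truth = self.small_truth(c, 5)
        layout = S.default_layout(truth["gene"].tolist(), "LB", 1)
        curves = S.generate_plate_curves(truth, c, layout)
        assert all(cv.times.size == 49 for cv in curves)

    def test_noiseless_unbiased_rate_recovery(self):
        c = cfg(od_noise_sd=0.0, well_bias_slope=0.0, rate_replicate_sd=0.0,
                growth_noise_sd=0.0, positional_amplitude_growth=0.0,
                target_rho=-1.0, initial_od=1e-4)
        truth = self.small_truth(c, 10)
        layout = S.default_layout(truth["gene"].tolist(), "LB", 1)
        curves = [cv for cv in S.generate_plate_curves(truth, c, layout)
                  if cv.strain != "BLANK"]
        mu_true = dict(zip(truth["gene"], truth["true_mu"]))
        for cv in curves:
            # early-phase interval rates hit the true rate while OD << K
            rates = G.interval_rates(cv, floor=0.0)
            assert rates.mu[0] == pytest.approx(mu_true[cv.strain], abs=1e-3)
            # the windowed estimate sits at or below the true rate (logistic)
            est = G.estimate_growth_rate(cv, floor=0.0)
            assert est.mu <= mu_true[cv.strain] + 1e-9
            assert est.mu == pytest.approx(mu_true[cv.strain], rel=0.05)

    def test_bias_on_capacity_not_on_rate(self):
        c = cfg(od_noise_sd=0.0, well_bias_slope=0.002, rate_replicate_sd=0.0)
        truth = self.small_truth(c, 90)
        layout = S.default_layout(truth["gene"].tolist(), "LB", 1)
        curves = [cv for cv in S.generate_plate_curves(truth, c, layout)
                  if cv.strain != "BLANK"]
        by_index = sorted(curves, key=lambda cv: G.serpentine_index(cv.well))
        max_od = [cv.od.max() for cv in by_index]
        assert np.all(np.diff(max_od) > 0)  # strictly increasing in well index

    def test_duplicate_well_assignment_errors(self):
        c = cfg()
        truth = self.small_truth(c, 2)
        layout = pd.DataFrame({
            "plate": ["p1", "p1"], "well": ["A1", "A1"],
            "strain": truth["gene"].tolist(), "medium": "LB", "replicate": [1, 1],
        })
        with pytest.raises(ConfigError):
            S.generate_plate_curves(truth, c, layout)

    def test_replicates_in_different_wells(self):
        layout = S.default_layout([f"s{i}" for i in range(30)], "LB", 3)
        strains = layout[layout["strain"] != "BLANK"]
        for _, grp in strains.groupby("strain"):
            assert grp["well"].nunique() == len(grp)

    def test_determinism_end_to_end(self):
        c = cfg()
        t1 = self.small_truth(c, 8)
        t2 = self.small_truth(c, 8)
        pd.testing.assert_frame_equal(t1, t2)
        layout = S.default_layout(t1["gene"].tolist(), "LB", 2)
        c1 = S.generate_plate_curves(t1, c, layout)
        c2 = S.generate_plate_curves(t2, c, layout)
        for a, b in zip(c1, c2):
            assert np.array_equal(a.od, b.od)
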