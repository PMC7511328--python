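"""Positional signals, periodogram, Fisher's g and sinusoid fitting."""

import numpy as np
import pandas as pd
import pytest

from kogrowth import periodicity as P
from kogrowth.errors import UndefinedStatisticError

L = 4632


def cosine_signal(k, L=L, amp=1.0, phase=0.0):
    a = np.arange(L)
    return amp * np.cos(2 * np.pi * k * a / L + phase)


def annotation_one_gene_per_kb(L=L):
    starts = np.arange(L) * 1000 + 1
    return pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(L)],
            "start_bp": starts,
            "end_bp": starts + 999,
            "strand": "+",
            "essential": False,
            "category": "e",
        }
    )


class TestPositionalSignal:
    def test_constant_values_give_constant_signal(self):
        ann = annotation_one_gene_per_kb(200)
        vals = pd.Series(1.0, index=ann["gene"])
        sig = P.positional_signal(ann, vals, genome_length_kb=200, window_kb=20)
        assert np.allclose(sig.values, 1.0)

    def test_single_gene_window_membership_and_fill(self):
        # a gene at midpoint p contributes to the 100 anchors a with
        # p in [a, a+100), i.e. the window starting up to 99 kb upstream
        ann = annotation_one_gene_per_kb(400).iloc[[250]].reset_index(drop=True)
        vals = pd.Series([5.0], index=ann["gene"])
        sig = P.positional_signal(ann, vals, genome_length_kb=400, window_kb=100)
        contributing = np.nonzero(sig.n_contributing)[0]
        assert np.array_equal(contributing, np.arange(151, 251))
        # non-empty windows hold the gene value; empty ones the global mean
        assert np.allclose(sig.values, 5.0)

    def test_two_gene_fill_policy_global_mean(self):
        ann = annotation_one_gene_per_kb(1000).iloc[[100, 600]].reset_index(drop=True)
        vals = pd.Series([2.0, 6.0], index=ann["gene"])
        sig = P.positional_signal(ann, vals, genome_length_kb=1000, window_kb=50)
        empty = sig.n_contributing == 0
        assert empty.any()
        assert np.allclose(sig.values[empty], 4.0)  # mean of non-empty windows

    def test_circular_wraparound_gene(self):
        # gene crossing the origin lands near coordinate 0
        ann = pd.DataFrame(
            {"gene": ["w"], "start_bp": [199_500], "end_bp": [500],
             "strand": ["+"], "essential": [False], "category": ["e"]}
        )
        mids = P.gene_midpoints_kb(ann, 200)
        circular_dist_to_origin = min(mids[0], 200 - mids[0])
        assert 0 <= mids[0] < 200
        assert circular_dist_to_origin == pytest.approx(0.0, abs=0.01)

    def test_essential_zero_vs_nonessential_only(self):
        ann = annotation_one_gene_per_kb(200)
        ann.loc[::2, "essential"] = True
        vals = pd.Series(3.0, index=ann["gene"])
        zeroed = P.positional_signal(ann, vals, mode="essential_zero",
                                     genome_length_kb=200, window_kb=20)
        # essential genes enter with 0 (lethal knockout), not their value
        assert np.allclose(zeroed.values, 1.5)
        only = P.positional_signal(ann, vals, mode="nonessential_only",
                                   genome_length_kb=200, window_kb=20)
        assert np.allclose(only.values, 3.0)

    def test_density_mode_counts_genes(self):
        ann = annotation_one_gene_per_kb(200)
        sig = P.positional_signal(ann, None, mode="density",
                                  genome_length_kb=200, window_kb=20)
        assert np.allclose(sig.values, 20.0)

    def test_empty_annotation_errors(self):
        ann = annotation_one_gene_per_kb(100).iloc[:0]
        with pytest.raises(UndefinedStatisticError):
            P.positional_signal(ann, pd.Series(dtype=float), genome_length_kb=100)


class TestPeriodogram:
    def test_pure_cosine_concentrates_power(self):
        sig = P.PositionalSignal(values=cosine_signal(6), genome_length_kb=L)
        pg = P.periodogram(sig)
        k_star = pg.k[np.argmax(pg.power)]
        assert k_star == 6
        assert pg.power[pg.k != 6].max() < 1e-18 * pg.power.max()

    def test_constant_signal_zero_spectrum(self):
        sig = P.PositionalSignal(values=np.full(100, 2.0), genome_length_kb=100)
        pg = P.periodogram(sig)
        assert np.allclose(pg.power, 0.0)
        with pytest.raises(UndefinedStatisticError):
            P.dominant_period(sig)

    def test_amplitude_ratio_two_harmonics(self):
        # orthogonality: amp 2 at k=3 vs amp 1 at k=9 -> power ratio 4:1
        vals = cosine_signal(3, amp=2.0) + cosine_signal(9, amp=1.0)
        pg = P.periodogram(P.PositionalSignal(values=vals, genome_length_kb=L))
        p3 = pg.power[pg.k == 3][0]
        p9 = pg.power[pg.k == 9][0]
        assert p3 / p9 == pytest.approx(4.0, rel=1e-9)
        assert pg.k[np.argmax(pg.power)] == 3

    def test_parseval(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=500)
        sig = P.PositionalSignal(values=x, genome_length_kb=500)
        pg = P.periodogram(sig)
        n = x.size
        total = 2 * pg.power[pg.k < n // 2].sum()
        if n % 2 == 0:
            total += pg.power[pg.k == n // 2][0]
        detrended = x - x.mean()
        assert total == pytest.approx((detrended**2).sum(), rel=1e-9)

    def test_rotation_equivariance(self):
        vals = cosine_signal(5) + 0.3 * cosine_signal(11, phase=1.0)
        sig = P.PositionalSignal(values=vals, genome_length_kb=L)
        rolled = P.PositionalSignal(values=np.roll(vals, 137), genome_length_kb=L)
        pg, pg_r = P.periodogram(sig), P.periodogram(rolled)
        assert np.allclose(pg.power, pg_r.power, rtol=1e-9, atol=1e-12)
        d, d_r = P.dominant_period(sig), P.dominant_period(rolled)
        assert d.dominant_k == d_r.dominant_k
        assert d.g == pytest.approx(d_r.g)
        assert d.phase != pytest.approx(d_r.phase, abs=1e-6)

    def test_smoothing_attenuation_matches_closed_form(self):
        # a W-bin circular moving average scales harmonic k by the Dirichlet
        # factor sin(pi*k*W/N) / (W * sin(pi*k/N))
        N, W, k = 4632, 100, 6
        raw = cosine_signal(k, L=N)
        smoothed = P.sliding_window_mean(raw, W)
        amp_raw, _, _ = P.fit_sinusoid(
            P.PositionalSignal(values=raw, genome_length_kb=N), k
        )
        amp_sm, _, _ = P.fit_sinusoid(
            P.PositionalSignal(values=smoothed, genome_length_kb=N), k
        )
        expected = abs(np.sin(np.pi * k * W / N) / (W * np.sin(np.pi * k / N)))
        assert amp_sm / amp_raw == pytest.approx(expected, abs=1e-6)


class TestFisherG:
    def test_single_nonzero_ordinate(self):
        g, p = P.fisher_g_test(np.array([0.0, 0.0, 7.0, 0.0]))
        assert g == 1.0
        assert p == 0.0

    def test_two_equal_ordinates_closed_form(self):
        g, p = P.fisher_g_test(np.array([1.0, 1.0]))
        assert g == pytest.approx(0.5)
        assert p == pytest.approx(1.0)

    def test_all_zero_errors(self):
        with pytest.raises(UndefinedStatisticError):
            P.fisher_g_test(np.zeros(5))

    def test_monotone_in_g(self):
        # stronger concentration -> smaller tail probability
        n = 50
        ps = []
        for peak in (3.0, 6.0, 12.0):
            powers = np.ones(n)
            powers[0] = peak
            ps.append(P.fisher_g_test(powers)[1])
        assert ps[0] > ps[1] > ps[2]


class TestFitSinusoid:
    def test_exact_recovery_of_pure_cosine(self):
        amp, phase, offset = 0.7, 0.9, 2.5
        vals = offset + cosine_signal(4, amp=amp, phase=phase)
        sig = P.PositionalSignal(values=vals, genome_length_kb=L)
        a, ph, m = P.fit_sinusoid(sig, 4)
        assert a == pytest.approx(amp, rel=1e-9)
        assert ph == pytest.approx(phase, abs=1e-9)
        assert m == pytest.approx(offset, rel=1e-9)

    def test_wrong_harmonic_gives_zero_amplitude(self):
        sig = P.PositionalSignal(values=cosine_signal(4), genome_length_kb=L)
        a, _, _ = P.fit_sinusoid(sig, 9)
        assert a == pytest.approx(0.0, abs=1e-9)

    def test_amplitude_unbiased_under_noise(self):
        rng = np.random.default_rng(3)
        n, sigma, amp = 2000, 0.5, 1.0
        amps = []
        for _ in range(20):
            vals = cosine_signal(6, L=n, amp=amp) + rng.normal(0, sigma, n)
            amps.append(P.fit_sinusoid(
                P.PositionalSignal(values=vals, genome_length_kb=n), 6)[0])
        assert abs(np.mean(amps) - amp) < 3 * sigma * np.sqrt(2 / n)


class TestDominantPeriod:
    def test_k1_exclusion_flag(self):
        vals = cosine_signal(1) + 0.1 * cosine_signal(5)
        sig = P.PositionalSignal(values=vals, genome_length_kb=L)
        with_k1 = P.dominant_period(sig, exclude_k1=False)
        assert with_k1.dominant_k == 1
        assert with_k1.dominant_wavelength_kb == pytest.approx(L)
        without = P.dominant_period(sig, exclude_k1=True)
        assert without.dominant_k == 5
        assert without.k1_excluded

    def test_tie_goes_to_smaller_k(self):
        vals = cosine_signal(3) + cosine_signal(8)
        sig = P.PositionalSignal(values=vals, genome_length_kb=L)
        assert P.dominant_period(sig).dominant_k == 3


class TestEssentialDensityCorrelation:
    def test_exact_anticorrelation(self):
        a = P.PositionalSignal(values=cosine_signal(2, L=300), genome_length_kb=300)
        b = P.PositionalSignal(values=-cosine_signal(2, L=300), genome_length_kb=300)
        r, _ = P.essential_density_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_mismatched_lengths_error(self):
        a = P.PositionalSignal(values=np.random.default_rng(0).normal(size=100),
                               genome_length_kb=100)
        b = P.PositionalSignal(values=np.random.default_rng(1).normal(size=200),
                               genome_length_kb=200)
        with pytest.raises(UndefinedStatisticError):
            P.essential_density_correlation(a, b)

    def test_constant_signal_error(self):
        a = P.PositionalSignal(values=np.ones(50), genome_length_kb=50)
        b = P.PositionalSignal(values=np.arange(50.0), genome_length_kb=50)
        with pytest.raises(UndefinedStatisticError):
            P.essential_density_correlation(a, b)
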