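"""Synthetic-cohort generators: HWE structure, case-control sampling,
planted eQTLs, annotation tracks, and promoter assembly."""

from __future__ import annotations

import numpy as np
import pytest

from enhscreen.cohortsim import (
    ExpressionSimConfig,
    SimCohortConfig,
    TrackSimConfig,
    simulate_case_control,
    simulate_correlated_pair,
    simulate_expression,
    simulate_genotypes,
    simulate_promoters,
    simulate_tracks,
)
from enhscreen.assoc import fit_additive_logistic
from enhscreen.qc import VariantRecord, hwe_chisq_test, pairwise_r2
from enhscreen.regscreen import cis_eqtl, variant_in_track
from enhscreen.seqmotif import scan_fixed_motif


class TestSimulateGenotypes:
    def test_zero_frequency_gives_all_reference(self):
        assert not simulate_genotypes(0.0, 100, seed=1).any()

    def test_mean_dosage_matches_binomial_closed_form(self):
        # Binomial(2, p): mean 2p, variance 2p(1-p)
        p, n = 0.5, 100_000
        g = simulate_genotypes(p, n, seed=2)
        se = np.sqrt(2 * p * (1 - p) / n)
        assert abs(g.mean() - 2 * p) < 3 * se

    def test_seeded_determinism(self):
        a = simulate_genotypes(0.3, 500, seed=42)
        b = simulate_genotypes(0.3, 500, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_frequency_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(0.7, 10, seed=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_genotype_frequencies_consistent_with_hwe(self, seed):
        # chi-square goodness of fit to (1-p)^2 : 2p(1-p) : p^2 should be
        # non-significant at alpha = 0.001 for a faithful generator
        g = simulate_genotypes(0.3, 100_000, seed=seed)
        n0 = int((g == 0).sum())
        n1 = int((g == 1).sum())
        n2 = int((g == 2).sum())
        assert hwe_chisq_test(n0, n1, n2) > 0.001


class TestSimulateCaseControl:
    def _cfg(self, **kw):
        base = dict(
            cohort_label="unit",
            n_cases=150,
            n_controls=150,
            variant_freqs=[0.3],
            per_allele_or=[1.0],
            seed=0,
        )
        base.update(kw)
        return SimCohortConfig(**base)

    def test_exact_counts_and_sample_table_columns(self):
        gm, samples = simulate_case_control(self._cfg(seed=3))
        assert samples.n_cases == 150 and samples.n_controls == 150
        assert gm.n_samples == 300
        assert set(samples.df["sex"]) <= {"male", "female"}
        assert samples.df["age"].between(18, 90).all()
        assert (samples.df["cohort"] == "unit").all()

    def test_zero_cases_rejected(self):
        with pytest.raises(ValueError):
            self._cfg(n_cases=0)

    def test_unattainable_counts_raise_budget_error(self):
        cfg = self._cfg(baseline_log_odds=-30.0, n_cases=500, seed=1)
        with pytest.raises(RuntimeError, match="budget"):
            simulate_case_control(cfg, max_batches=3)

    def test_null_model_ci_coverage(self):
        # OR = 1: the fitted 95% CI should cover 1.0 in >= 90% of replicates
        covered = 0
        reps = 100
        for i in range(reps):
            gm, samples = simulate_case_control(self._cfg(seed=1000 + i))
            res = fit_additive_logistic(gm.dosages[:, 0], samples)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 0.90 * reps

    def test_recovers_planted_or_at_discovery_size(self):
        # per-allele OR 1.41 at the discovery-stage sample size: the mean
        # fitted log OR over replicates sits within 3 MC SE of the truth
        truth = np.log(1.41)
        betas = []
        for i in range(60):
            cfg = self._cfg(
                n_cases=1161, n_controls=1353, per_allele_or=[1.41], seed=2000 + i
            )
            gm, samples = simulate_case_control(cfg)
            betas.append(fit_additive_logistic(gm.dosages[:, 0], samples).beta)
        betas = np.asarray(betas)
        mc_se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - truth) < 3 * mc_se

    def test_seeded_determinism(self):
        gm1, s1 = simulate_case_control(self._cfg(seed=7))
        gm2, s2 = simulate_case_control(self._cfg(seed=7))
        np.testing.assert_array_equal(gm1.dosages, gm2.dosages)
        assert s1.df.equals(s2.df)


class TestSimulateExpression:
    def test_noiseless_limit_recovers_slope_exactly(self):
        g = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0] * 10)
        cfg = ExpressionSimConfig(eqtl_beta=1.0, noise_sd=1e-12, seed=0)
        expr = simulate_expression(g, cfg)
        res = cis_eqtl(g, expr["gene_target"].to_numpy())
        assert res.slope == pytest.approx(1.0, abs=1e-6)

    def test_null_eqtl_ci_coverage(self):
        g = simulate_genotypes(0.3, 150, seed=5)
        covered = 0
        reps = 100
        for i in range(reps):
            cfg = ExpressionSimConfig(eqtl_beta=0.0, noise_sd=1.0, seed=3000 + i)
            expr = simulate_expression(g, cfg)
            res = cis_eqtl(g, expr["gene_target"].to_numpy())
            covered += (res.slope - 1.96 * res.se) <= 0.0 <= (res.slope + 1.96 * res.se)
        assert covered >= 0.90 * reps

    def test_other_genes_are_pure_noise(self):
        g = simulate_genotypes(0.4, 4000, seed=8)
        cfg = ExpressionSimConfig(eqtl_beta=2.0, noise_sd=1.0, n_genes=3, seed=8)
        expr = simulate_expression(g, cfg)
        null_res = cis_eqtl(g, expr["gene_null001"].to_numpy())
        assert abs(null_res.slope) < 5 * null_res.se

    def test_seeded_determinism(self):
        g = simulate_genotypes(0.2, 50, seed=1)
        cfg = ExpressionSimConfig(seed=9)
        assert simulate_expression(g, cfg).equals(simulate_expression(g, cfg))


class TestSimulateTracks:
    def test_planted_interval_covers_designated_variant(self):
        var = VariantRecord("v", "chr1", 1000)
        cfg = TrackSimConfig(
            chrom_lengths={"chr1": 10_000},
            planted_intervals={"H3K4me1": [("chr1", 900, 1100)]},
            seed=0,
        )
        tracks = simulate_tracks(cfg)
        assert variant_in_track(var, tracks["H3K4me1"])

    def test_empty_planted_list_gives_empty_track(self):
        cfg = TrackSimConfig(
            chrom_lengths={"chr1": 1000}, planted_intervals={"empty": []}, seed=0
        )
        track = simulate_tracks(cfg)["empty"]
        assert track.n_intervals() == 0
        assert not track.contains("chr1", 500)

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            TrackSimConfig(
                chrom_lengths={"chr1": 1000},
                planted_intervals={"t": [("chr1", 500, 2000)]},
                seed=0,
            )

    def test_random_tracks_match_brute_force_overlap(self):
        cfg = TrackSimConfig(
            chrom_lengths={"chr1": 100_000},
            planted_intervals={"t": [("chr1", 10, 20)]},
            n_random=50,
            random_len=200,
            seed=4,
        )
        track = simulate_tracks(cfg)["t"]
        flat = [(s, e) for s, e in track.intervals.get("chr1", [])]
        rng = np.random.default_rng(5)
        for pos0 in rng.integers(0, 100_000, size=2000):
            brute = any(s <= pos0 < e for s, e in flat)
            assert track.contains("chr1", int(pos0)) == brute


class TestSimulatePromoters:
    def test_planted_counts_are_exact(self):
        records = simulate_promoters(3, 600, [3, 0, 1], "CAGCTG", seed=0)
        for (_, seq), expected in zip(records, [3, 0, 1]):
            assert len(scan_fixed_motif(seq, "CAGCTG")) == expected

    def test_non_palindromic_motif_counts_include_reverse_strand(self):
        records = simulate_promoters(2, 400, [2, 0], "CCGGAA", seed=1)
        # forward plants only; reverse-complement occurrences were scrubbed
        for (_, seq), expected in zip(records, [2, 0]):
            assert len(scan_fixed_motif(seq, "CCGGAA")) == expected

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            simulate_promoters(1, 10, [3], "CAGCTG", seed=0)

    def test_seeded_determinism(self):
        a = simulate_promoters(2, 300, [1, 2], "CAGCTG", seed=6)
        b = simulate_promoters(2, 300, [1, 2], "CAGCTG", seed=6)
        assert a == b


class TestCorrelatedPair:
    def test_zero_swap_probability_gives_perfect_ld(self):
        d1, d2 = simulate_correlated_pair(0.3, 500, swap_prob=0.0, seed=0)
        assert pairwise_r2(d1, d2) == pytest.approx(1.0)

    def test_ld_decreases_with_swap_probability(self):
        r2 = []
        for swap in (0.1, 0.5, 1.0):
            d1, d2 = simulate_correlated_pair(0.3, 20_000, swap, seed=1)
            r2.append(pairwise_r2(d1, d2))
        assert r2[0] > r2[1] > r2[2]
        assert r2[2] < 0.01
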