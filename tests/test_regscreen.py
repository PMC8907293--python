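"""Regulatory filter cascade: cis-eQTL, window queries, track overlap,
candidate selection, and stratified co-expression."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from enhscreen.assoc import AssociationResult
from enhscreen.qc import VariantRecord
from enhscreen.regscreen import (
    AnnotationTrack,
    EQTLResult,
    GeneModel,
    ScreenConfig,
    cis_eqtl,
    cis_window_genes,
    coexpression_spearman,
    screen_candidates,
    variant_in_track,
)


class TestCisEqtl:
    def test_constant_expression_flagged_non_significant(self):
        g = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        res = cis_eqtl(g, np.full(5, 7.0))
        assert res.zero_variance
        assert res.slope == 0.0 and res.p == 1.0

    def test_six_point_dataset_matches_normal_equations(self):
        g = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        e = np.array([9.8, 10.1, 10.6, 10.4, 11.2, 11.0])
        res = cis_eqtl(g, e)
        # direct normal-equation evaluation
        X = np.column_stack([np.ones(6), g])
        beta = np.linalg.solve(X.T @ X, X.T @ e)
        resid = e - X @ beta
        sigma2 = resid @ resid / (6 - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        p = 2 * stats.t.sf(abs(t), df=4)
        assert res.slope == pytest.approx(beta[1], rel=1e-12)
        assert res.se == pytest.approx(se, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_slope_recovery_over_replicates(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, 200).astype(float)
        slopes = []
        for i in range(200):
            e = 10 + 0.5 * g + np.random.default_rng(100 + i).normal(0, 1, 200)
            slopes.append(cis_eqtl(g, e).slope)
        slopes = np.asarray(slopes)
        mc_se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 0.5) < 3 * mc_se

    def test_scaling_expression_scales_slope_not_p(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.4, 50).astype(float)
        e = 5 + 0.3 * g + rng.normal(0, 1, 50)
        base = cis_eqtl(g, e)
        scaled = cis_eqtl(g, 10 * e)
        assert scaled.slope == pytest.approx(10 * base.slope, rel=1e-10)
        assert scaled.se == pytest.approx(10 * base.se, rel=1e-10)
        assert scaled.p == pytest.approx(base.p, abs=1e-10)

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cis_eqtl(np.ones(10), np.arange(10.0))


class TestCisWindowGenes:
    def test_boundary_tss_is_included(self):
        var = VariantRecord("v", "chr1", 2_000_000)
        genes = [GeneModel("edge", "chr1", 3_000_000)]
        assert [g.gene_id for g in cis_window_genes(var, genes, 1_000_000)] == ["edge"]

    def test_other_chromosome_excluded(self):
        var = VariantRecord("v", "chr1", 500)
        genes = [GeneModel("far", "chr2", 500)]
        assert cis_window_genes(var, genes, 1_000_000) == []

    def test_matches_brute_force_distance_filter(self):
        rng = np.random.default_rng(7)
        var = VariantRecord("v", "chr5", 5_000_000)
        genes = [
            GeneModel(f"g{i}", "chr5" if rng.random() < 0.8 else "chr6",
                      int(rng.integers(1, 10_000_000)))
            for i in range(300)
        ]
        window = 750_000
        got = {g.gene_id for g in cis_window_genes(var, genes, window)}
        brute = {
            g.gene_id
            for g in genes
            if g.chrom == var.chrom and abs(g.tss_pos - var.pos) <= window
        }
        assert got == brute


class TestVariantInTrack:
    def test_one_based_boundary_semantics(self):
        track = AnnotationTrack.from_intervals("t", [("chr1", 100, 200)])
        # variant at 1-based pos 101 -> 0-based 100: inside (closed start)
        assert variant_in_track(VariantRecord("a", "chr1", 101), track)
        # 1-based pos 201 -> 0-based 200: outside (exclusive end)
        assert not variant_in_track(VariantRecord("b", "chr1", 201), track)
        assert not variant_in_track(VariantRecord("c", "chr2", 101), track)

    def test_merging_collapses_overlapping_intervals(self):
        track = AnnotationTrack.from_intervals(
            "t", [("chr1", 10, 50), ("chr1", 40, 80), ("chr1", 80, 90)]
        )
        assert track.intervals["chr1"] == [(10, 90)]

    def test_matches_linear_scan_on_random_fixture(self):
        rng = np.random.default_rng(11)
        raw = [
            ("chr1", int(s), int(s) + int(rng.integers(1, 500)))
            for s in rng.integers(0, 50_000, size=200)
        ]
        track = AnnotationTrack.from_intervals("t", raw)
        for pos0 in rng.integers(0, 51_000, size=5000):
            brute = any(s <= pos0 < e and c == "chr1" for c, s, e in raw)
            assert track.contains("chr1", int(pos0)) == brute


def _assoc(vid, p=1e-5):
    return AssociationResult(vid, 0.34, 0.06, p, 2500, 0.3, 0.26)


def _tracks_for(positions: dict[str, int], include: dict[str, set[str]]):
    """Tracks covering only the listed variant ids per track name."""
    tracks = {}
    for name in ("H3K4me1", "H3K27ac", "TxnFactorMotif"):
        ivs = [
            ("chr1", positions[v] - 1, positions[v])
            for v in include.get(name, set())
        ]
        tracks[name] = (
            AnnotationTrack.from_intervals(name, ivs) if ivs else AnnotationTrack(name)
        )
    return tracks


class TestScreenCandidates:
    def test_empty_association_list_gives_no_candidates(self):
        tracks = _tracks_for({"v": 100}, {})
        assert screen_candidates([], [], tracks, ScreenConfig(), {}) == []

    def test_exact_set_of_constructed_passers(self):
        # 50 variants; exactly 6 constructed to satisfy all four criteria
        rng = np.random.default_rng(13)
        n = 50
        vids = [f"v{i:02d}" for i in range(n)]
        positions = {v: 1000 + 10 * i for i, v in enumerate(vids)}
        variants = {v: VariantRecord(v, "chr1", positions[v]) for v in vids}
        passers = set(rng.choice(vids, size=6, replace=False))
        assoc_results, eqtls = [], []
        include = {"H3K4me1": set(passers), "H3K27ac": set(passers),
                   "TxnFactorMotif": set(passers)}
        for v in vids:
            is_pass = v in passers
            assoc_results.append(_assoc(v, p=1e-5 if is_pass else 0.5))
            eqtls.append(
                EQTLResult("gene", v, 0.5, 0.1, 1e-6 if is_pass else 0.9, 200)
            )
            # non-passers randomly get some (but never all) criteria
            if not is_pass and rng.random() < 0.5:
                include["H3K4me1"].add(v)
        tracks = _tracks_for(positions, include)
        calls = screen_candidates(assoc_results, eqtls, tracks, ScreenConfig(), variants)
        got = {c.variant_id for c in calls if c.passes}
        # brute-force per-criterion application
        brute = {
            c.variant_id
            for c in calls
            if c.pass_assoc and c.pass_eqtl and c.pass_marks and c.pass_motif
        }
        assert got == passers == brute

    def test_missing_one_mark_excluded_with_flag_pattern(self):
        positions = {"v": 100}
        variants = {"v": VariantRecord("v", "chr1", 100)}
        tracks = _tracks_for(
            positions, {"H3K4me1": {"v"}, "TxnFactorMotif": {"v"}}  # no H3K27ac
        )
        calls = screen_candidates(
            [_assoc("v")], [EQTLResult("g", "v", 0.4, 0.1, 1e-5, 100)],
            tracks, ScreenConfig(), variants,
        )
        call = calls[0]
        assert (call.pass_assoc, call.pass_eqtl, call.pass_marks, call.pass_motif) == (
            True, True, False, True,
        )
        assert not call.passes

    def test_result_invariant_to_input_order(self):
        positions = {f"v{i}": 100 + i for i in range(10)}
        variants = {v: VariantRecord(v, "chr1", p) for v, p in positions.items()}
        tracks = _tracks_for(positions, {
            "H3K4me1": {"v3"}, "H3K27ac": {"v3"}, "TxnFactorMotif": {"v3"}})
        assoc_results = [_assoc(v, 1e-5 if v == "v3" else 0.4) for v in positions]
        eqtls = [EQTLResult("g", v, 0.3, 0.1, 1e-5 if v == "v3" else 0.8, 100)
                 for v in positions]
        fwd = screen_candidates(assoc_results, eqtls, tracks, ScreenConfig(), variants)
        rev = screen_candidates(assoc_results[::-1], eqtls[::-1], tracks,
                                ScreenConfig(), variants)
        assert {c.variant_id for c in fwd if c.passes} == \
               {c.variant_id for c in rev if c.passes} == {"v3"}

    def test_missing_required_track_is_configuration_error(self):
        with pytest.raises(ValueError, match="missing annotation tracks"):
            screen_candidates([_assoc("v")], [], {}, ScreenConfig(), {})


class TestCoexpressionSpearman:
    def test_monotone_relationships(self):
        x = np.arange(10.0)
        rho, _ = coexpression_spearman(x, x**3)["all"]
        assert rho == pytest.approx(1.0)
        rho, _ = coexpression_spearman(x, -x)["all"]
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_average_rank_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 6.0])
        rho, _ = coexpression_spearman(x, y)["all"]
        # direct rank arithmetic with average ranks
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_genotype_strata_and_small_stratum_flag(self):
        rng = np.random.default_rng(17)
        n = 60
        d = np.array([0.0] * 30 + [1.0] * 28 + [2.0] * 2)
        x = rng.normal(size=n)
        y = x + rng.normal(scale=0.5, size=n)
        out = coexpression_spearman(x, y, strata=d)
        assert set(out) == {"ref_homozygotes", "carriers"}
        assert out["ref_homozygotes"][0] > 0.5
        only_two = coexpression_spearman(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]),
            strata=np.array([0.0, 0.0, 1.0]),
        )
        assert np.isnan(only_two["carriers"][0])
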