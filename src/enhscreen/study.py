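"""Assembly of a complete synthetic five-cohort study on disk.

Builds everything :func:`enhscreen.pipeline.run_pipeline` consumes: five
case-control cohorts at the study's per-stage sample sizes with one
planted risk variant among null variants, expression with a planted
cis-eQTL for the target gene, enhancer-mark and motif tracks covering the
planted variant, a gene-TSS table, and promoter FASTA with planted motif
occurrences. Used by the analysis drivers, the test suite, and the
acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from enhscreen import io as eio
from enhscreen.cohortsim import (
    ExpressionSimConfig,
    SimCohortConfig,
    TrackSimConfig,
    simulate_case_control,
    simulate_expression,
    simulate_genotypes,
    simulate_promoters,
    simulate_tracks,
)
from enhscreen.pipeline import PipelineConfig, StageFiles
from enhscreen.qc import GenotypeMatrix, VariantRecord
from enhscreen.regscreen import GeneModel, ScreenConfig

__all__ = ["StudyDesign", "STAGE_SIZES", "build_study", "pooled_or_recovery"]

#: Per-stage (n_cases, n_controls) of the five-cohort three-stage design
STAGE_SIZES: dict[str, tuple[int, int]] = {
    "discovery": (1161, 1353),
    "replication1": (576, 721),
    "replication2a": (1942, 2812),
    "replication2b": (393, 1314),
    "replication2c": (826, 860),
}


@dataclass
class StudyDesign:
    """Design knobs of the synthetic study.

    Defaults are the study conditions: five cohorts at the design's stage
    sizes, one risk variant with per-allele OR 1.41 at MAF 0.25 among
    null variants, sex/age covariate effects, and a planted regulatory
    context (cis-eQTL on the target gene, enhancer marks and a TF motif
    covering the variant).
    """

    stage_sizes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(STAGE_SIZES)
    )
    n_null_variants: int = 50
    planted_or: float = 1.41
    planted_maf: float = 0.25
    null_maf_range: tuple[float, float] = (0.08, 0.5)
    eqtl_beta: float = 0.6
    eqtl_noise_sd: float = 1.0
    n_null_genes: int = 10
    chrom: str = "chr16"
    chrom_length: int = 3_000_000
    planted_pos: int = 1_500_000
    region_span: int = 2_000_000
    add_qc_failures: bool = True
    promoter_counts: tuple[int, ...] = (3, 0, 1)
    promoter_length: int = 600
    motif: str = "CAGCTG"
    seed: int = 0


def _variant_layout(design: StudyDesign, rng: np.random.Generator):
    m = design.n_null_variants + 1
    lo = design.planted_pos - design.region_span // 2
    positions = np.sort(
        rng.choice(np.arange(lo, lo + design.region_span), size=m, replace=False)
    )
    planted_idx = int(np.argmin(np.abs(positions - design.planted_pos)))
    positions[planted_idx] = design.planted_pos
    variants = []
    for j, pos in enumerate(positions):
        vid = "rs_planted" if j == planted_idx else f"rs_null{j:03d}"
        variants.append(VariantRecord(vid, design.chrom, int(pos), "G", "T"))
    freqs = rng.uniform(*design.null_maf_range, size=m)
    freqs[planted_idx] = design.planted_maf
    ors = np.ones(m)
    ors[planted_idx] = design.planted_or
    return variants, freqs, ors, planted_idx


def build_study(out_dir: str | Path, design: StudyDesign | None = None) -> PipelineConfig:
    """Write a full synthetic study under ``out_dir``; return its pipeline config."""
    design = design or StudyDesign()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(design.seed)
    variants, freqs, ors, planted_idx = _variant_layout(design, root)
    vids = [v.variant_id for v in variants]
    eio.write_variant_table(variants, out / "variants.tsv")

    stages: dict[str, StageFiles] = {}
    discovery_gm = None
    for name, (n_cases, n_controls) in design.stage_sizes.items():
        cfg = SimCohortConfig(
            cohort_label=name,
            n_cases=n_cases,
            n_controls=n_controls,
            variant_freqs=list(freqs),
            per_allele_or=list(ors),
            seed=int(root.integers(2**31)),
        )
        gm, samples = simulate_case_control(cfg)
        gm = GenotypeMatrix(gm.sample_ids, vids, gm.dosages)
        if name == "discovery" and design.add_qc_failures:
            # overwrite two null columns with QC-failing data: a rare
            # variant (MAF < 0.05) and a gross HWE violation (all hets)
            null_idx = [j for j in range(len(vids)) if j != planted_idx]
            rare_j, het_j = null_idx[0], null_idx[1]
            gm.dosages[:, rare_j] = simulate_genotypes(
                0.01, gm.n_samples, int(root.integers(2**31))
            )
            gm.dosages[:, het_j] = 1.0
        gpath, spath = out / f"{name}_genotypes.tsv", out / f"{name}_samples.tsv"
        eio.write_genotype_tsv(gm, gpath)
        eio.write_sample_tsv(samples, spath)
        stages[name] = StageFiles(str(gpath), str(spath))
        if name == "discovery":
            discovery_gm = gm

    # expression for discovery samples: target gene eQTL on the planted variant
    expr_cfg = ExpressionSimConfig(
        eqtl_beta=design.eqtl_beta,
        noise_sd=design.eqtl_noise_sd,
        n_genes=design.n_null_genes + 1,
        target_gene="gene_target",
        seed=int(root.integers(2**31)),
    )
    expr = simulate_expression(discovery_gm.dosages[:, planted_idx], expr_cfg)
    expr.index = discovery_gm.sample_ids
    expr.index.name = "sample_id"
    expr.to_csv(out / "expression.tsv", sep="\t")

    # gene TSS table: target gene near the planted variant, nulls spread out
    genes = [GeneModel("gene_target", design.chrom, design.planted_pos + 50_000)]
    lo = design.planted_pos - design.region_span // 2
    for j in range(1, design.n_null_genes + 1):
        tss = lo + int(root.integers(1, design.region_span))
        genes.append(GeneModel(f"gene_null{j:03d}", design.chrom, tss))
    eio.write_gene_tss(genes, out / "gene_tss.tsv")

    # annotation tracks covering the planted variant (plus decoys)
    pos0 = design.planted_pos - 1
    planted_iv = (design.chrom, max(pos0 - 250, 0), pos0 + 250)
    track_cfg = TrackSimConfig(
        chrom_lengths={design.chrom: design.chrom_length},
        planted_intervals={
            "H3K4me1": [planted_iv],
            "H3K27ac": [planted_iv],
            "TxnFactorMotif": [(design.chrom, pos0 - 8, pos0 + 8)],
        },
        n_random=20,
        seed=int(root.integers(2**31)),
    )
    tracks = simulate_tracks(track_cfg)
    track_paths = {}
    for name, track in tracks.items():
        path = out / f"{name}.bed"
        eio.write_bed(track, path)
        track_paths[name] = str(path)

    # promoter FASTA with planted motif counts
    promoters = simulate_promoters(
        n=len(design.promoter_counts),
        length=design.promoter_length,
        planted_counts=list(design.promoter_counts),
        motif=design.motif,
        seed=int(root.integers(2**31)),
    )
    eio.write_fasta(promoters, out / "promoters.fa")

    return PipelineConfig(
        stages=stages,
        variant_table=str(out / "variants.tsv"),
        expression=str(out / "expression.tsv"),
        gene_tss=str(out / "gene_tss.tsv"),
        tracks=track_paths,
        out_dir=str(out / "results"),
        screen=ScreenConfig(),
        seed=design.seed,
    )


def pooled_or_recovery(
    n_replicates: int,
    seed: int,
    true_or: float = 1.41,
    maf: float = 0.25,
    stage_sizes: dict[str, tuple[int, int]] | None = None,
):
    """Parameter-recovery experiment for the five-cohort pooled odds ratio.

    Each replicate simulates the five cohorts at the study's stage sizes
    with one variant at the given per-allele OR, fits the sex/age-adjusted
    additive logistic model per cohort, pools the log ORs by inverse
    variance, and also pools the raw allele-count tables by
    Mantel-Haenszel. Returns a DataFrame with one row per replicate:
    pooled log OR, SE, CI bounds and truth-coverage flags for both
    estimators.
    """
    import pandas as pd

    from enhscreen.assoc import fit_additive_logistic
    from enhscreen.meta import allele_count_table, inverse_variance_meta, mantel_haenszel_or

    sizes = stage_sizes or STAGE_SIZES
    root = np.random.default_rng(seed)
    truth = float(np.log(true_or))
    rows = []
    for _ in range(n_replicates):
        estimates, strata = [], []
        for name, (n_cases, n_controls) in sizes.items():
            cfg = SimCohortConfig(
                cohort_label=name,
                n_cases=n_cases,
                n_controls=n_controls,
                variant_freqs=[maf],
                per_allele_or=[true_or],
                seed=int(root.integers(2**31)),
            )
            gm, samples = simulate_case_control(cfg)
            fit = fit_additive_logistic(gm.dosages[:, 0], samples)
            estimates.append((fit.beta, fit.se))
            strata.append(allele_count_table(gm.dosages[:, 0], samples.is_case, name))
        iv = inverse_variance_meta(estimates)
        mh = mantel_haenszel_or(strata)
        rows.append(
            dict(
                iv_beta=iv.pooled_beta,
                iv_se=(np.log(iv.ci_high) - np.log(iv.ci_low)) / (2 * 1.959964),
                iv_covered=iv.ci_low <= true_or <= iv.ci_high,
                mh_beta=mh.pooled_beta,
                mh_covered=mh.ci_low <= true_or <= mh.ci_high,
            )
        )
    df = pd.DataFrame(rows)
    df.attrs["truth_log_or"] = truth
    return df
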