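"""End-to-end orchestration of the three-stage prioritization pipeline.

Discovery QC and association, the regulatory candidate screen,
same-direction replication across the later stages, fixed-effects
meta-analysis of all cohorts, and reporting (forest table, regional
association/LD table, run manifest). Every intermediate table is written
as TSV under the configured output directory; the run is deterministic
given the inputs and seed.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from enhscreen import io as eio
from enhscreen import __version__
from enhscreen.assoc import (
    AssociationResult,
    ReplicationVerdict,
    SampleTable,
    discovery_screen,
    fit_additive_logistic,
    replication_check,
)
from enhscreen.meta import (
    MetaResult,
    StratumTable,
    allele_count_table,
    bonferroni_threshold,
    forest_table,
    inverse_variance_meta,
    mantel_haenszel_or,
)
from enhscreen.qc import GenotypeMatrix, QCReport, VariantRecord, apply_variant_filters, pairwise_r2
from enhscreen.regscreen import (
    CandidateCall,
    ScreenConfig,
    cis_eqtl,
    cis_window_genes,
    screen_candidates,
)

__all__ = ["StageFiles", "PipelineConfig", "PipelineResult", "PipelineError", "run_pipeline", "regional_table"]

log = logging.getLogger("enhscreen.pipeline")


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class StageFiles:
    """Genotype + phenotype file pair for one cohort stage."""

    genotypes: str
    samples: str


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``stages`` maps stage names to file pairs; the stage named
    ``discovery_stage`` feeds QC, association and the regulatory screen,
    all others are replication cohorts, validated in their listed order.
    ``n_tests`` sets the Bonferroni denominator for joint significance;
    by default the number of variants entering discovery association.
    """

    stages: dict[str, StageFiles]
    variant_table: str
    expression: str
    gene_tss: str
    tracks: dict[str, str]
    out_dir: str
    discovery_stage: str = "discovery"
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    maf_min: float = 0.05
    hwe_p_min: float = 1e-4
    disc_p: float = 0.001
    rep_alpha: float = 0.05
    joint_alpha: float = 0.05
    n_tests: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate_files(self) -> None:
        paths = [self.variant_table, self.expression, self.gene_tss]
        paths += list(self.tracks.values())
        for sf in self.stages.values():
            paths += [sf.genotypes, sf.samples]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise PipelineError("config", f"missing input files: {missing}")
        if self.discovery_stage not in self.stages:
            raise PipelineError("config", f"no stage named {self.discovery_stage!r}")


@dataclass
class PipelineResult:
    """Bundle of every table the pipeline emits."""

    qc_report: QCReport
    discovery_table: pd.DataFrame
    candidate_calls: list[CandidateCall]
    replication_verdicts: dict[str, list[ReplicationVerdict]]
    final_candidates: list[str]
    meta_results: dict[str, dict[str, MetaResult]]
    forest: pd.DataFrame | None
    regional: pd.DataFrame | None
    joint_threshold: float
    manifest: dict


def _assoc_to_row(res: AssociationResult) -> dict:
    return dict(
        variant_id=res.variant_id,
        beta=res.beta,
        se=res.se,
        or_=res.or_,
        ci_low=res.ci_low,
        ci_high=res.ci_high,
        p=res.p,
        n_used=res.n_used,
        maf_cases=res.maf_cases,
        maf_controls=res.maf_controls,
        direction=res.direction,
        converged=res.converged,
    )


def _fit_stage(
    gm: GenotypeMatrix,
    samples: SampleTable,
    variants: dict[str, VariantRecord],
    variant_ids: list[str] | None = None,
) -> dict[str, AssociationResult]:
    out = {}
    for vid in variant_ids if variant_ids is not None else gm.variant_ids:
        var = variants.get(vid)
        out[vid] = fit_additive_logistic(
            gm.column(vid),
            samples,
            variant_id=vid,
            effect_allele=var.effect_allele if var else "A",
            other_allele=var.other_allele if var else "G",
        )
    return out


def regional_table(
    assoc_results: list[AssociationResult],
    index_variant: str,
    gm: GenotypeMatrix,
    variants: dict[str, VariantRecord],
    window_bp: int = 100_000,
) -> pd.DataFrame:
    """Regional association/LD table around an index variant.

    One row per variant within ``window_bp`` of the index on its
    chromosome: position, -log10 P, and dosage r-squared to the index.
    """
    if index_variant not in variants:
        raise KeyError(f"index variant {index_variant!r} not in variant table")
    idx_var = variants[index_variant]
    idx_dos = gm.column(index_variant)
    rows = []
    for res in assoc_results:
        var = variants.get(res.variant_id)
        if var is None or var.chrom != idx_var.chrom:
            continue
        if abs(var.pos - idx_var.pos) > window_bp:
            continue
        try:
            r2 = pairwise_r2(gm.column(res.variant_id), idx_dos)
        except ValueError:
            r2 = float("nan")
        rows.append(
            dict(
                variant_id=res.variant_id,
                pos=var.pos,
                neg_log10_p=-np.log10(res.p) if res.converged else float("nan"),
                r2_to_index=r2,
                is_index=res.variant_id == index_variant,
            )
        )
    rows.sort(key=lambda r: r["pos"])
    return pd.DataFrame(
        rows, columns=["variant_id", "pos", "neg_log10_p", "r2_to_index", "is_index"]
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full three-stage prioritization pipeline.

    Stage order: input validation, discovery QC, discovery association,
    regulatory screen, replication of each passing candidate in every
    replication stage (same-direction P < alpha), Mantel-Haenszel and
    inverse-variance meta-analysis across all stages, joint-significance
    call, and report emission. Any stage failure aborts with a
    stage-tagged error; tables written before the failure are retained.
    """
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(name)s %(levelname)s %(message)s",
    )
    config.validate_files()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    variants = {v.variant_id: v for v in eio.read_variant_table(config.variant_table)}
    genes = eio.read_gene_tss(config.gene_tss)
    tracks = {name: eio.read_bed(path, name) for name, path in config.tracks.items()}

    # --- discovery QC ---
    stage = "qc"
    disc_files = config.stages[config.discovery_stage]
    gm = eio.read_genotype_tsv(disc_files.genotypes)
    disc_samples = eio.read_sample_tsv(disc_files.samples)
    try:
        gm_qc, qc_report = apply_variant_filters(
            gm, disc_samples.is_case, config.maf_min, config.hwe_p_min
        )
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc
    qc_report.table.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    log.info("[qc] %d/%d variants pass QC", gm_qc.n_variants, gm.n_variants)

    # --- discovery association ---
    stage = "discovery"
    try:
        disc_fits = _fit_stage(gm_qc, disc_samples, variants)
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc
    disc_table = pd.DataFrame([_assoc_to_row(r) for r in disc_fits.values()])
    disc_table.to_csv(out / "discovery_assoc.tsv", sep="\t", index=False)
    retained = discovery_screen(list(disc_fits.values()), config.disc_p)
    log.info("[discovery] %d variants at P < %g", len(retained), config.disc_p)

    # --- regulatory screen ---
    stage = "screen"
    expr = pd.read_csv(config.expression, sep="\t", index_col=0)
    expr = expr.loc[gm_qc.sample_ids]
    eqtls = []
    for vid in sorted(retained):
        var = variants.get(vid)
        if var is None:
            continue
        cis_genes = cis_window_genes(var, genes, config.screen.cis_window_bp)
        for gene in cis_genes:
            if gene.gene_id not in expr.columns:
                continue
            try:
                eqtls.append(
                    cis_eqtl(
                        gm_qc.column(vid),
                        expr[gene.gene_id].to_numpy(),
                        gene_id=gene.gene_id,
                        variant_id=vid,
                    )
                )
            except ValueError as exc:
                raise PipelineError(stage, f"{vid}/{gene.gene_id}: {exc}") from exc
    try:
        calls = screen_candidates(
            list(disc_fits.values()), eqtls, tracks, config.screen, variants
        )
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc
    pd.DataFrame(
        [
            dict(
                variant_id=c.variant_id,
                pass_assoc=c.pass_assoc,
                pass_eqtl=c.pass_eqtl,
                pass_marks=c.pass_marks,
                pass_motif=c.pass_motif,
                passes=c.passes,
                best_eqtl_gene=c.best_eqtl_gene or "",
            )
            for c in calls
        ]
    ).to_csv(out / "candidates.tsv", sep="\t", index=False)
    candidates = [c.variant_id for c in calls if c.passes]
    log.info("[screen] %d candidate enhancer variants", len(candidates))

    # --- replication ---
    stage = "replication"
    rep_stages = [s for s in config.stages if s != config.discovery_stage]
    rep_fits: dict[str, dict[str, AssociationResult]] = {}
    verdicts: dict[str, list[ReplicationVerdict]] = {s: [] for s in rep_stages}
    survivors = list(candidates)
    for rep_name in rep_stages:
        files = config.stages[rep_name]
        rep_gm = eio.read_genotype_tsv(files.genotypes)
        rep_samples = eio.read_sample_tsv(files.samples)
        try:
            fits = _fit_stage(rep_gm, rep_samples, variants, survivors)
        except ValueError as exc:
            raise PipelineError(stage, f"{rep_name}: {exc}") from exc
        rep_fits[rep_name] = fits
        still = []
        for vid in survivors:
            verdict = replication_check(disc_fits[vid], fits[vid], config.rep_alpha)
            verdicts[rep_name].append(verdict)
            if verdict.passed:
                still.append(vid)
        survivors = still
        log.info("[replication] %s: %d candidates remain", rep_name, len(survivors))
    rows = [
        dict(stage=s, variant_id=v.variant_id, passed=v.passed, reason=v.reason)
        for s, vs in verdicts.items()
        for v in vs
    ]
    pd.DataFrame(rows, columns=["stage", "variant_id", "passed", "reason"]).to_csv(
        out / "replication.tsv", sep="\t", index=False
    )

    # --- joint meta-analysis ---
    stage = "meta"
    n_tests = config.n_tests if config.n_tests is not None else gm_qc.n_variants
    threshold = bonferroni_threshold(config.joint_alpha, n_tests)
    meta_results: dict[str, dict[str, MetaResult]] = {}
    final: list[str] = []
    forest_df = None
    stage_data = {}
    for name in config.stages:
        files = config.stages[name]
        stage_data[name] = (
            eio.read_genotype_tsv(files.genotypes),
            eio.read_sample_tsv(files.samples),
        )
    for vid in survivors:
        strata = []
        estimates = []
        for name, (sgm, ssamp) in stage_data.items():
            strata.append(allele_count_table(sgm.column(vid), ssamp.is_case, name))
            fit = disc_fits[vid] if name == config.discovery_stage else rep_fits[name][vid]
            estimates.append((fit.beta, fit.se))
        try:
            mh = mantel_haenszel_or(strata)
        except ValueError as exc:
            raise PipelineError(stage, f"{vid}: {exc}") from exc
        iv = inverse_variance_meta(estimates)
        meta_results[vid] = {"mantel_haenszel": mh, "inverse_variance": iv}
        if mh.p < threshold:
            final.append(vid)
        if forest_df is None:
            forest_df = forest_table(strata, mh)
            forest_df.to_csv(out / "forest.tsv", sep="\t", index=False)
    log.info(
        "[meta] %d/%d candidates jointly significant at P < %.3g",
        len(final), len(survivors), threshold,
    )

    # --- regional table around the top final candidate ---
    stage = "report"
    regional = None
    if final:
        regional = regional_table(list(disc_fits.values()), final[0], gm_qc, variants)
        regional.to_csv(out / "regional.tsv", sep="\t", index=False)
    pd.DataFrame({"variant_id": final}).to_csv(
        out / "final_candidates.tsv", sep="\t", index=False
    )

    manifest = dict(
        package="enhscreen",
        version=__version__,
        seed=config.seed,
        stages={s: vars(f) for s, f in config.stages.items()},
        inputs=dict(
            variant_table=config.variant_table,
            expression=config.expression,
            gene_tss=config.gene_tss,
            tracks=config.tracks,
        ),
        thresholds=dict(
            maf_min=config.maf_min,
            hwe_p_min=config.hwe_p_min,
            disc_p=config.disc_p,
            rep_alpha=config.rep_alpha,
            joint_alpha=config.joint_alpha,
            n_tests=n_tests,
            joint_threshold=threshold,
            eqtl_fdr_max=config.screen.eqtl_fdr_max,
            required_marks=list(config.screen.required_marks),
            require_motif=config.screen.require_motif,
            cis_window_bp=config.screen.cis_window_bp,
        ),
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        qc_report=qc_report,
        discovery_table=disc_table,
        candidate_calls=calls,
        replication_verdicts=verdicts,
        final_candidates=final,
        meta_results=meta_results,
        forest=forest_df,
        regional=regional,
        joint_threshold=threshold,
        manifest=manifest,
    )
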