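"""Regulatory filter cascade for candidate enhancer variants.

Candidate selection requires, jointly: a discovery association below the
retention threshold, at least one cis-eQTL gene at Benjamini-Hochberg
FDR <= 0.05, overlap with every required enhancer histone-mark track
(H3K4me1 and H3K27ac by default), and overlap with a transcription-factor
motif track. Also provides genotype-stratified Spearman co-expression.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from enhscreen.assoc import AssociationResult
from enhscreen.qc import VariantRecord

__all__ = [
    "AnnotationTrack",
    "GeneModel",
    "EQTLResult",
    "ScreenConfig",
    "CandidateCall",
    "cis_eqtl",
    "cis_window_genes",
    "variant_in_track",
    "screen_candidates",
    "coexpression_spearman",
]


@dataclass
class AnnotationTrack:
    """Named genomic intervals, 0-based half-open, sorted and merged per chromosome."""

    name: str
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, name: str, intervals: list[tuple[str, int, int]]
    ) -> "AnnotationTrack":
        """Build a track, sorting and merging overlapping/adjacent intervals."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty/inverted interval ({chrom},{start},{end})")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out = [ivs[0]]
            for s, e in ivs[1:]:
                ls, le = out[-1]
                if s <= le:
                    out[-1] = (ls, max(le, e))
                else:
                    out.append((s, e))
            merged[chrom] = out
        return cls(name, merged)

    def n_intervals(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position, by binary search."""
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (pos0, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos0 < ivs[i][1]


@dataclass(frozen=True)
class GeneModel:
    """Gene anchor for the cis window: TSS position, 1-based."""

    gene_id: str
    chrom: str
    tss_pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss_pos < 1:
            raise ValueError("TSS position is 1-based, must be >= 1")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")


@dataclass
class EQTLResult:
    """Linear-regression eQTL summary: expression-unit slope per dosage."""

    gene_id: str
    variant_id: str
    slope: float
    se: float
    p: float
    n: int
    zero_variance: bool = False


@dataclass
class ScreenConfig:
    """Thresholds for the four-criterion candidate screen."""

    assoc_p_max: float = 0.001
    eqtl_fdr_max: float = 0.05
    required_marks: tuple[str, ...] = ("H3K4me1", "H3K27ac")
    require_motif: bool = True
    motif_track: str = "TxnFactorMotif"
    cis_window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        for thr in (self.assoc_p_max, self.eqtl_fdr_max):
            if not 0.0 < thr < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.cis_window_bp <= 0:
            raise ValueError("cis window must be positive")


@dataclass
class CandidateCall:
    """Per-variant screen outcome with one boolean flag per criterion."""

    variant_id: str
    pass_assoc: bool
    pass_eqtl: bool
    pass_marks: bool
    pass_motif: bool
    best_eqtl_gene: str | None = None

    @property
    def passes(self) -> bool:
        return self.pass_assoc and self.pass_eqtl and self.pass_marks and self.pass_motif


def cis_eqtl(
    dosages: np.ndarray,
    expression: np.ndarray,
    covariates: np.ndarray | None = None,
    gene_id: str = "gene",
    variant_id: str = "variant",
) -> EQTLResult:
    """OLS of expression on dosage; two-sided t test on the slope.

    Degrees of freedom are ``n - k - 1`` for ``k`` regressors plus
    intercept. Expression constant across samples is reported as a
    non-significant zero-variance result rather than an error; a constant
    dosage is a degenerate design and raises.
    """
    g = np.asarray(dosages, dtype=float)
    e = np.asarray(expression, dtype=float)
    if g.shape != e.shape:
        raise ValueError("dosage and expression lengths differ")
    mask = np.isfinite(g) & np.isfinite(e)
    g, e = g[mask], e[mask]
    if g.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(g) == 0:
        raise ValueError("constant dosage: degenerate design")
    if np.ptp(e) == 0:
        return EQTLResult(gene_id, variant_id, 0.0, 0.0, 1.0, int(g.size), zero_variance=True)

    X = np.column_stack([np.ones_like(g), g])
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)[mask]
        X = np.column_stack([X, cov])
    fit = sm.OLS(e, X).fit()
    return EQTLResult(
        gene_id=gene_id,
        variant_id=variant_id,
        slope=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n=int(g.size),
    )


def cis_window_genes(
    variant: VariantRecord, genes: list[GeneModel], window_bp: int = 1_000_000
) -> list[GeneModel]:
    """Genes whose TSS lies within +/- ``window_bp`` of the variant, inclusive."""
    lo, hi = variant.pos - window_bp, variant.pos + window_bp
    return [
        g for g in genes if g.chrom == variant.chrom and lo <= g.tss_pos <= hi
    ]


def variant_in_track(variant: VariantRecord, track: AnnotationTrack) -> bool:
    """True iff the variant falls in a track interval.

    This is the single place where the 1-based variant coordinate is
    converted to the 0-based half-open track space.
    """
    return track.contains(variant.chrom, variant.pos - 1)


def screen_candidates(
    assoc_results: list[AssociationResult],
    eqtl_results: list[EQTLResult],
    tracks: dict[str, AnnotationTrack],
    cfg: ScreenConfig,
    variants: dict[str, VariantRecord],
) -> list[CandidateCall]:
    """Apply the four-criterion enhancer-variant screen.

    eQTL multiplicity is controlled by Benjamini-Hochberg across all
    tested gene-variant pairs; a variant satisfies the eQTL criterion if
    any of its genes is significant at ``eqtl_fdr_max``, and the smallest-q
    gene is reported as ``best_eqtl_gene``. Output order follows the
    association input; the pass set is independent of input order.
    """
    needed = set(cfg.required_marks) | ({cfg.motif_track} if cfg.require_motif else set())
    missing = needed - set(tracks)
    if missing:
        raise ValueError(f"missing annotation tracks: {sorted(missing)}")

    # BH across all tested pairs
    pair_q: dict[str, list[tuple[float, str]]] = {}
    if eqtl_results:
        ps = np.array([r.p for r in eqtl_results])
        _, qvals, _, _ = multipletests(ps, method="fdr_bh")
        for r, q in zip(eqtl_results, qvals):
            pair_q.setdefault(r.variant_id, []).append((float(q), r.gene_id))

    calls = []
    for res in assoc_results:
        vid = res.variant_id
        pass_assoc = bool(res.converged and res.p < cfg.assoc_p_max)
        pairs = sorted(pair_q.get(vid, []))
        pass_eqtl = bool(pairs and pairs[0][0] <= cfg.eqtl_fdr_max)
        best_gene = pairs[0][1] if pass_eqtl else None
        var = variants.get(vid)
        if var is None:
            pass_marks = pass_motif = False
        else:
            pass_marks = all(
                variant_in_track(var, tracks[m]) for m in cfg.required_marks
            )
            pass_motif = (
                variant_in_track(var, tracks[cfg.motif_track])
                if cfg.require_motif
                else True
            )
        calls.append(
            CandidateCall(vid, pass_assoc, pass_eqtl, pass_marks, pass_motif, best_gene)
        )
    return calls


def coexpression_spearman(
    x: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Spearman rank correlation of two expression vectors, optionally per stratum.

    With ``strata`` a dosage vector, samples are split into reference
    homozygotes (dosage 0) and effect-allele carriers (dosage >= 1),
    matching the usual genotype-stratified co-expression display. Strata
    with fewer than 3 complete pairs are reported as (nan, nan) rather
    than failing globally. Ties get average ranks; P from the t
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expression vectors must have equal length")

    def one(mask: np.ndarray) -> tuple[float, float]:
        ok = mask & np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            return (float("nan"), float("nan"))
        rho, p = stats.spearmanr(x[ok], y[ok])
        return (float(rho), float(p))

    if strata is None:
        return {"all": one(np.ones_like(x, dtype=bool))}
    d = np.asarray(strata, dtype=float)
    return {
        "ref_homozygotes": one(np.isfinite(d) & (d == 0)),
        "carriers": one(np.isfinite(d) & (d >= 1)),
    }
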