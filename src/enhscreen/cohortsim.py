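"""Seeded synthetic-cohort generators.

Everything the pipeline consumes can be simulated here with the
statistical structure the analysis assumes: biallelic genotypes under
Hardy-Weinberg equilibrium, case/control status under a per-allele
odds-ratio logistic model with sex and age covariates (retrospective
sampling to fixed case/control counts), expression with planted
genotype-linear eQTL effects, annotation tracks with planted enhancer
intervals, and promoter sequences with planted motif occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from enhscreen.assoc import SampleTable
from enhscreen.qc import GenotypeMatrix
from enhscreen.regscreen import AnnotationTrack

__all__ = [
    "SimCohortConfig",
    "ExpressionSimConfig",
    "TrackSimConfig",
    "simulate_genotypes",
    "simulate_case_control",
    "simulate_expression",
    "simulate_tracks",
    "simulate_promoters",
    "simulate_correlated_pair",
]


@dataclass
class SimCohortConfig:
    """Design of one simulated case-control cohort.

    ``per_allele_or`` holds the odds ratio per dosage unit for each variant
    (1.0 = null). ``covariate_effects`` are log-odds coefficients for male
    sex and per-year age. Age is Normal(``age_mean``, ``age_sd``) truncated
    to [18, 90]; sex is Bernoulli(``p_male``).
    """

    cohort_label: str
    n_cases: int
    n_controls: int
    variant_freqs: list[float]
    per_allele_or: list[float]
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.5, "age": 0.02}
    )
    baseline_log_odds: float = -2.0
    age_mean: float = 55.0
    age_sd: float = 10.0
    p_male: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if len(self.variant_freqs) != len(self.per_allele_or):
            raise ValueError("variant_freqs and per_allele_or length mismatch")
        if any(not 0.0 < f <= 0.5 for f in self.variant_freqs):
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
        if any(o <= 0 for o in self.per_allele_or):
            raise ValueError("odds ratios must be positive")


@dataclass
class ExpressionSimConfig:
    """Planted cis-eQTL: target gene = intercept + eqtl_beta*dosage + noise."""

    eqtl_beta: float = 0.5
    noise_sd: float = 1.0
    n_genes: int = 1
    intercept: float = 10.0
    target_gene: str = "gene_target"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")


@dataclass
class TrackSimConfig:
    """Planted annotation tracks over named chromosomes.

    ``planted_intervals`` maps track name -> list of (chrom, start, end) in
    0-based half-open coordinates; ``n_random`` decoy intervals of length
    ``random_len`` are added per track.
    """

    chrom_lengths: dict[str, int]
    planted_intervals: dict[str, list[tuple[str, int, int]]]
    n_random: int = 0
    random_len: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name, ivs in self.planted_intervals.items():
            for chrom, start, end in ivs:
                length = self.chrom_lengths.get(chrom)
                if length is None:
                    raise ValueError(f"{name}: unknown chromosome {chrom}")
                if not 0 <= start < end <= length:
                    raise ValueError(
                        f"{name}: interval ({chrom},{start},{end}) out of bounds"
                    )


def simulate_genotypes(freq: float, n: int, seed: int) -> np.ndarray:
    """Hard-call dosages for a biallelic variant under HWE.

    Genotypes 0/1/2 are drawn with probabilities (1-p)^2, 2p(1-p), p^2,
    i.e. Binomial(2, p) per sample. Bit-reproducible for a fixed seed.
    """
    if not 0.0 <= freq <= 0.5:
        raise ValueError("minor-allele frequency must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    return rng.binomial(2, freq, size=n).astype(float)


def _simulate_covariates(rng: np.random.Generator, n: int, cfg: SimCohortConfig):
    sex_male = rng.random(n) < cfg.p_male
    age = rng.normal(cfg.age_mean, cfg.age_sd, size=n)
    # truncate by redraw; a couple of passes suffice at these tail masses
    for _ in range(100):
        bad = (age < 18) | (age > 90)
        if not bad.any():
            break
        age[bad] = rng.normal(cfg.age_mean, cfg.age_sd, size=int(bad.sum()))
    return sex_male, np.clip(age, 18, 90)


def simulate_case_control(
    cfg: SimCohortConfig, max_batches: int = 200
) -> tuple[GenotypeMatrix, SampleTable]:
    """Retrospective sampling of a cohort to fixed case/control counts.

    A source population is simulated under the logistic disease model
    ``logit P(case) = baseline + sum_j log(OR_j)*g_j + b_sex*male + b_age*age``
    and individuals are accumulated until ``n_cases`` cases and
    ``n_controls`` controls are reached. Raises a sampling-budget error
    with a diagnostic if the requested counts are unattainable within the
    batch budget (e.g. a baseline making cases vanishingly rare).
    """
    rng = np.random.default_rng(cfg.seed)
    m = len(cfg.variant_freqs)
    log_or = np.log(cfg.per_allele_or)
    b_sex = cfg.covariate_effects.get("sex", 0.0)
    b_age = cfg.covariate_effects.get("age", 0.0)

    need = cfg.n_cases + cfg.n_controls
    geno_parts, sex_parts, age_parts, case_parts = [], [], [], []
    got_cases = got_controls = 0
    batch = max(need, 1000)
    for it in range(max_batches):
        g = rng.binomial(2, np.asarray(cfg.variant_freqs), size=(batch, m)).astype(float)
        sex_male, age = _simulate_covariates(rng, batch, cfg)
        eta = (
            cfg.baseline_log_odds
            + g @ log_or
            + b_sex * sex_male
            + b_age * (age - cfg.age_mean)
        )
        is_case = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        geno_parts.append(g)
        sex_parts.append(sex_male)
        age_parts.append(age)
        case_parts.append(is_case)
        got_cases += int(is_case.sum())
        got_controls += int((~is_case).sum())
        if got_cases >= cfg.n_cases and got_controls >= cfg.n_controls:
            break
    else:
        raise RuntimeError(
            f"sampling budget exhausted after {max_batches} batches of {batch}: "
            f"obtained {got_cases}/{cfg.n_cases} cases and "
            f"{got_controls}/{cfg.n_controls} controls; adjust baseline_log_odds"
        )

    g = np.vstack(geno_parts)
    sex_male = np.concatenate(sex_parts)
    age = np.concatenate(age_parts)
    is_case = np.concatenate(case_parts)

    case_idx = np.flatnonzero(is_case)[: cfg.n_cases]
    ctrl_idx = np.flatnonzero(~is_case)[: cfg.n_controls]
    idx = np.concatenate([case_idx, ctrl_idx])

    sample_ids = [f"{cfg.cohort_label}_s{i:05d}" for i in range(len(idx))]
    variant_ids = [f"var{j:04d}" for j in range(m)]
    gm = GenotypeMatrix(sample_ids, variant_ids, g[idx])
    table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "status": ["case"] * cfg.n_cases + ["control"] * cfg.n_controls,
            "sex": np.where(sex_male[idx], "male", "female"),
            "age": np.round(age[idx], 1),
            "cohort": cfg.cohort_label,
        }
    )
    return gm, SampleTable(table)


def simulate_expression(
    genotypes: np.ndarray, cfg: ExpressionSimConfig
) -> pd.DataFrame:
    """Expression matrix (samples x genes) with one planted eQTL.

    The target gene follows ``intercept + eqtl_beta*dosage + N(0, sd)``;
    all other genes are pure noise around the intercept.
    """
    g = np.asarray(genotypes, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    n = g.shape[0]
    expr = cfg.intercept + rng.normal(0.0, cfg.noise_sd, size=(n, cfg.n_genes))
    expr[:, 0] += cfg.eqtl_beta * g
    genes = [cfg.target_gene] + [f"gene_null{j:03d}" for j in range(1, cfg.n_genes)]
    return pd.DataFrame(expr, columns=genes)


def simulate_tracks(cfg: TrackSimConfig) -> dict[str, AnnotationTrack]:
    """Annotation tracks containing every planted interval plus decoys.

    Output tracks are sorted and merged, so each planted interval is
    guaranteed to be covered (possibly within a merged superset interval).
    """
    rng = np.random.default_rng(cfg.seed)
    tracks: dict[str, AnnotationTrack] = {}
    for name, planted in cfg.planted_intervals.items():
        ivs = list(planted)
        for _ in range(cfg.n_random):
            chrom = list(cfg.chrom_lengths)[rng.integers(len(cfg.chrom_lengths))]
            length = cfg.chrom_lengths[chrom]
            span = min(cfg.random_len, length)
            start = int(rng.integers(0, max(length - span, 1)))
            ivs.append((chrom, start, start + span))
        tracks[name] = AnnotationTrack.from_intervals(name, ivs)
    return tracks


_BASES = np.array(list("ACGT"))


def simulate_promoters(
    n: int,
    length: int,
    planted_counts: list[int],
    motif: str,
    seed: int,
) -> list[tuple[str, str]]:
    """FASTA-style promoter records with exact planted motif counts.

    Record ``i`` contains exactly ``planted_counts[i]`` forward-strand
    occurrences of ``motif``. Random background is rejection-sampled so
    that no accidental occurrence (on either strand) survives assembly.
    Returns ``(seq_id, sequence)`` pairs.
    """
    if len(planted_counts) != n:
        raise ValueError("planted_counts must have length n")
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValueError("motif must be a non-empty string over ACGT")
    rc = str(Seq(motif).reverse_complement())
    for c in planted_counts:
        if c * len(motif) > length:
            raise ValueError(f"cannot pack {c} copies of {motif} into length {length}")
    rng = np.random.default_rng(seed)

    records = []
    for i, count in enumerate(planted_counts):
        for _attempt in range(1000):
            seq = "".join(rng.choice(_BASES, size=length))
            # scrub accidental occurrences on either strand
            for word in {motif, rc}:
                while word in seq:
                    j = seq.index(word)
                    repl = "".join(rng.choice(_BASES, size=len(word)))
                    seq = seq[:j] + repl + seq[j + len(word):]
            if motif in seq or rc in seq:
                continue
            # plant copies at non-overlapping slots, then re-check junctions
            if count:
                slot = length // count
                if slot < len(motif):
                    raise ValueError("infeasible packing")
                chars = list(seq)
                for k in range(count):
                    off = k * slot + int(rng.integers(0, slot - len(motif) + 1))
                    chars[off : off + len(motif)] = motif
                seq = "".join(chars)
                if seq.count(motif) != count or (rc != motif and rc in seq):
                    continue
            records.append((f"promoter_{i:03d}", seq))
            break
        else:
            raise RuntimeError("failed to assemble promoter without spurious motifs")
    return records


def simulate_correlated_pair(
    freq: float, n: int, swap_prob: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """A pair of variants in linkage disequilibrium, for r-squared tests.

    The second variant copies the first's alleles and independently flips
    each of the two allele copies with probability ``swap_prob`` to a fresh
    HWE draw; ``swap_prob=0`` gives r^2 = 1, ``swap_prob=1`` independence.
    """
    if not 0.0 <= swap_prob <= 1.0:
        raise ValueError("swap_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a1 = rng.random(n) < freq
    a2 = rng.random(n) < freq
    flip1 = rng.random(n) < swap_prob
    flip2 = rng.random(n) < swap_prob
    b1 = np.where(flip1, rng.random(n) < freq, a1)
    b2 = np.where(flip2, rng.random(n) < freq, a2)
    return (a1 + a2).astype(float), (b1 + b2).astype(float)
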