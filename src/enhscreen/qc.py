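"""Per-variant genotype quality control.

Allele-frequency computation, the Hardy-Weinberg exact test (two-sided,
conditional on allele counts), threshold filtering, and pairwise dosage
r-squared for regional linkage-disequilibrium tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "VariantRecord",
    "QCReport",
    "minor_allele_freq",
    "genotype_counts",
    "hwe_exact_test",
    "hwe_chisq_test",
    "apply_variant_filters",
    "pairwise_r2",
]


@dataclass
class GenotypeMatrix:
    """Samples x variants hard-call minor-allele dosages.

    ``dosages`` is a float array with values in {0, 1, 2} and NaN for
    missing genotypes. Continuous dosages in [0, 2] (e.g. imputed) are
    accepted by the association layer but the QC layer assumes hard calls.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant IDs")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2] (NaN for missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_ids.index(variant_id)]

    def subset_variants(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.variant_ids.index(v) for v in keep]
        return GenotypeMatrix(self.sample_ids, list(keep), self.dosages[:, idx])


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant with 1-based position (VCF convention)."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position is 1-based, must be >= 1")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")


@dataclass
class QCReport:
    """Per-variant QC metrics and pass/fail verdicts with reasons."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_removed(self) -> int:
        return int((~self.table["pass"]).sum())

    def reasons(self, variant_id: str) -> list[str]:
        row = self.table.loc[self.table["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        r = row.iloc[0]["fail_reasons"]
        return r.split(";") if r else []


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype counts (n_ref_hom, n_het, n_alt_hom), ignoring NaN."""
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    n0 = int(np.sum(d == 0))
    n1 = int(np.sum(d == 1))
    n2 = int(np.sum(d == 2))
    if n0 + n1 + n2 != d.size:
        raise ValueError("non-integer dosages; QC expects hard calls in {0,1,2}")
    return n0, n1, n2


def minor_allele_freq(dosages: np.ndarray) -> tuple[float, bool]:
    """Minor-allele frequency of a dosage vector.

    Returns ``(maf, minor_is_effect)`` where ``minor_is_effect`` flags
    whether the coded (counted) allele is the minor one. Missing genotypes
    are excluded from the denominator.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("all genotypes missing: allele frequency undefined")
    q = float(d.sum()) / (2.0 * d.size)  # coded (effect) allele frequency
    maf = min(q, 1.0 - q)
    return maf, q <= 0.5


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test P-value.

    Conditions on the observed allele counts and sums the conditional
    probabilities of every heterozygote count whose probability does not
    exceed that of the observed table. Monomorphic data return 1.0.

    The conditional distribution over heterozygote counts ``h`` (with the
    rarer-allele count ``r`` fixed) is evaluated with log-factorials:

        P(h) = N! / (n_AA! n_Aa! n_aa!) * 2^h * r! (2N-r)! / (2N)!
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0

    lgamma = math.lgamma

    def log_prob(h: int) -> float:
        # h heterozygotes given `rare` copies of the rarer allele among 2n
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            lgamma(n + 1)
            - lgamma(hom_rare + 1)
            - lgamma(h + 1)
            - lgamma(hom_common + 1)
            + h * math.log(2.0)
            + lgamma(rare + 1)
            + lgamma(2 * n - rare + 1)
            - lgamma(2 * n + 1)
        )

    hs = np.arange(rare % 2, rare + 1, 2)
    logp = np.array([log_prob(int(h)) for h in hs])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, n_Aa)]
    # small relative guard against FP noise when summing "as or less probable"
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def hwe_chisq_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit to HWE proportions (cross-check)."""
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * n_AA + n_Aa) / (2.0 * n)
    exp = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]) * n
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(exp == 0):
        return 1.0
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def apply_variant_filters(
    gm: GenotypeMatrix,
    statuses: np.ndarray | list | None = None,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-4,
    hwe_in_controls: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove variants with MAF < ``maf_min`` or HWE P < ``hwe_p_min``.

    Both inequalities are strict, so a variant sitting exactly at a
    threshold is retained. The HWE test is computed in controls only by
    default (``statuses`` is a case/control vector aligned with samples,
    truthy = case); pass ``hwe_in_controls=False`` or ``statuses=None`` to
    use all samples. Call rate is reported but not filtered on.
    """
    for thr in (maf_min, hwe_p_min):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    if statuses is not None:
        statuses = np.asarray(statuses).astype(bool)
        if statuses.shape[0] != gm.n_samples:
            raise ValueError("statuses not aligned with samples")

    rows = []
    keep: list[str] = []
    for j, vid in enumerate(gm.variant_ids):
        col = gm.dosages[:, j]
        maf, _ = minor_allele_freq(col)
        if statuses is not None and hwe_in_controls:
            hwe_col = col[~statuses]
        else:
            hwe_col = col
        n0, n1, n2 = genotype_counts(hwe_col)
        hwe_p = hwe_exact_test(n0, n1, n2) if (n0 + n1 + n2) else 1.0
        call_rate = float(np.isfinite(col).mean())
        reasons = []
        if maf < maf_min:
            reasons.append(f"maf<{maf_min:g}")
        if hwe_p < hwe_p_min:
            reasons.append(f"hwe_p<{hwe_p_min:g}")
        ok = not reasons
        rows.append(
            dict(
                variant_id=vid,
                maf=maf,
                hwe_p=hwe_p,
                call_rate=call_rate,
                **{"pass": ok},
                fail_reasons=";".join(reasons),
            )
        )
        if ok:
            keep.append(vid)
    report = QCReport(pd.DataFrame(rows))
    return gm.subset_variants(keep), report


def pairwise_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (LD r-squared).

    Missing genotypes are excluded pairwise-complete. Raises on constant
    vectors, where the correlation is undefined.
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: constant or too-short vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
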