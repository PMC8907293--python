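"""Fixed-effects meta-analysis across cohorts.

Mantel-Haenszel pooling of per-cohort 2x2 effect-allele tables with the
Robins-Breslow-Greenland variance, inverse-variance pooling of
covariate-adjusted log odds ratios, Cochran's Q / I-squared heterogeneity,
Bonferroni multiplicity thresholds, and forest-table emission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from enhscreen.assoc import Z_95, AssociationResult

__all__ = [
    "StratumTable",
    "MetaResult",
    "allele_count_table",
    "mantel_haenszel_or",
    "inverse_variance_meta",
    "cochran_q",
    "bonferroni_threshold",
    "forest_table",
]


@dataclass(frozen=True)
class StratumTable:
    """Per-cohort 2x2 allele-count table.

    ``a``/``b`` are effect/other allele counts in cases, ``c``/``d`` the
    same in controls.
    """

    cohort: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")
        if self.n < 1:
            raise ValueError("empty stratum")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        """Cross-product ratio with Haldane-Anscombe 0.5 correction on zero cells."""
        a, b, c, d = self.a, self.b, self.c, self.d
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)

    @property
    def log_or_se(self) -> float:
        """Woolf SE of the (corrected) log odds ratio."""
        a, b, c, d = self.a, self.b, self.c, self.d
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


@dataclass
class MetaResult:
    """Pooled fixed-effects summary with heterogeneity diagnostics."""

    pooled_or: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    per_stratum: list[tuple[str, float, float, float]] = field(default_factory=list)
    q_stat: float = float("nan")
    i_squared: float = float("nan")

    @property
    def pooled_beta(self) -> float:
        return math.log(self.pooled_or)


def allele_count_table(
    dosages: np.ndarray, is_case: np.ndarray, cohort: str = "cohort"
) -> StratumTable:
    """Collapse hard-call dosages to a 2x2 effect-allele count table."""
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    ok = np.isfinite(d)
    d, y = d[ok], y[ok]
    a = int(d[y].sum())
    b = int(2 * y.sum() - a)
    c = int(d[~y].sum())
    dd = int(2 * (~y).sum() - c)
    return StratumTable(cohort, a, b, c, dd)


def mantel_haenszel_or(strata: list[StratumTable]) -> MetaResult:
    """Mantel-Haenszel pooled odds ratio over stratified 2x2 tables.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the CI uses the
    Robins-Breslow-Greenland variance of log OR_MH; the P-value is the
    Mantel-Haenszel chi-square without continuity correction. Strata are
    used with raw counts (no zero-cell correction in the pooling).
    """
    if not strata:
        raise ValueError("need at least one stratum")
    a = np.array([s.a for s in strata], float)
    b = np.array([s.b for s in strata], float)
    c = np.array([s.c for s in strata], float)
    d = np.array([s.d for s in strata], float)
    n = a + b + c + d

    R = a * d / n
    S = b * c / n
    sum_R, sum_S = R.sum(), S.sum()
    if sum_S == 0 or sum_R == 0:
        raise ValueError("degenerate tables: MH odds ratio undefined")
    or_mh = sum_R / sum_S

    # Robins-Breslow-Greenland variance of log(OR_MH)
    P = (a + d) / n
    Q = (b + c) / n
    var = (
        (P * R).sum() / (2 * sum_R**2)
        + ((P * S + Q * R)).sum() / (2 * sum_R * sum_S)
        + (Q * S).sum() / (2 * sum_S**2)
    )
    se = math.sqrt(var)
    log_or = math.log(or_mh)

    # MH chi-square (no continuity correction)
    e_a = (a + b) * (a + c) / n
    v_a = (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
    chi2 = (a.sum() - e_a.sum()) ** 2 / v_a.sum()
    p = float(stats.chi2.sf(chi2, df=1))

    per = [(s.cohort, s.odds_ratio, *_woolf_ci(s)) for s in strata]
    q, i2 = (float("nan"), float("nan"))
    if len(strata) >= 2:
        q, i2 = cochran_q(
            [(math.log(s.odds_ratio), s.log_or_se) for s in strata]
        )
    return MetaResult(
        pooled_or=or_mh,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        p=max(p, np.nextafter(0, 1)),
        method="mantel_haenszel",
        per_stratum=per,
        q_stat=q,
        i_squared=i2,
    )


def _woolf_ci(s: StratumTable) -> tuple[float, float]:
    lo = math.log(s.odds_ratio)
    return (math.exp(lo - Z_95 * s.log_or_se), math.exp(lo + Z_95 * s.log_or_se))


def inverse_variance_meta(estimates: list[tuple[float, float]]) -> MetaResult:
    """Inverse-variance fixed-effects pooling of (log OR, SE) pairs."""
    if not estimates:
        raise ValueError("need at least one estimate")
    betas = np.array([e[0] for e in estimates], float)
    ses = np.array([e[1] for e in estimates], float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = ses**-2
    beta = float((w * betas).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q, i2 = cochran_q(estimates) if len(estimates) >= 2 else (float("nan"), float("nan"))
    return MetaResult(
        pooled_or=math.exp(beta),
        ci_low=math.exp(beta - Z_95 * se),
        ci_high=math.exp(beta + Z_95 * se),
        p=max(p, np.nextafter(0, 1)),
        method="inverse_variance",
        per_stratum=[
            (f"stratum{i}", math.exp(b), math.exp(b - Z_95 * s), math.exp(b + Z_95 * s))
            for i, (b, s) in enumerate(estimates)
        ],
        q_stat=q,
        i_squared=i2,
    )


def cochran_q(estimates: list[tuple[float, float]]) -> tuple[float, float]:
    """Cochran's Q and I-squared (%) for a set of (beta, se) estimates.

    Q = sum w_i (beta_i - beta_pooled)^2 with inverse-variance weights;
    I^2 = max(0, (Q - df)/Q) * 100.
    """
    if len(estimates) < 2:
        raise ValueError("heterogeneity needs at least 2 estimates")
    betas = np.array([e[0] for e in estimates], float)
    ses = np.array([e[1] for e in estimates], float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = ses**-2
    pooled = (w * betas).sum() / w.sum()
    q = float((w * (betas - pooled) ** 2).sum())
    df = len(estimates) - 1
    i2 = 0.0 if q == 0 else max(0.0, (q - df) / q) * 100.0
    return q, i2


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("test count must be >= 1")
    return alpha / m


def forest_table(
    per_cohort: list[AssociationResult] | list[StratumTable],
    pooled: MetaResult,
) -> pd.DataFrame:
    """Forest-plot-ready table: one row per cohort plus the pooled row."""
    rows = []
    for item in per_cohort:
        if isinstance(item, AssociationResult):
            rows.append(
                dict(
                    cohort=item.variant_id,
                    maf_cases=item.maf_cases,
                    maf_controls=item.maf_controls,
                    odds_ratio=item.or_,
                    ci_low=item.ci_low,
                    ci_high=item.ci_high,
                    p=item.p,
                )
            )
        else:
            lo, hi = _woolf_ci(item)
            n_case_alleles = item.a + item.b
            n_ctrl_alleles = item.c + item.d
            rows.append(
                dict(
                    cohort=item.cohort,
                    maf_cases=item.a / n_case_alleles if n_case_alleles else float("nan"),
                    maf_controls=item.c / n_ctrl_alleles if n_ctrl_alleles else float("nan"),
                    odds_ratio=item.odds_ratio,
                    ci_low=lo,
                    ci_high=hi,
                    p=float("nan"),
                )
            )
    rows.append(
        dict(
            cohort=f"pooled ({pooled.method})",
            maf_cases=float("nan"),
            maf_controls=float("nan"),
            odds_ratio=pooled.pooled_or,
            ci_low=pooled.ci_low,
            ci_high=pooled.ci_high,
            p=pooled.p,
        )
    )
    cols = ["cohort", "maf_cases", "maf_controls", "odds_ratio", "ci_low", "ci_high", "p"]
    return pd.DataFrame(rows, columns=cols)
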