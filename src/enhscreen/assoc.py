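"""Additive-model case-control association.

Per-variant logistic regression of disease status on effect-allele dosage
with sex/age adjustment, discovery-stage retention, and same-direction
replication validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "SampleTable",
    "AssociationResult",
    "ReplicationVerdict",
    "fit_additive_logistic",
    "discovery_screen",
    "replication_check",
    "harmonize_to",
]

#: 95% normal CI multiplier; fixed so reported CIs have stable two-decimal formatting
Z_95 = 1.959964


@dataclass
class SampleTable:
    """Phenotype/covariate table: one row per sample.

    Columns: ``sample_id``, ``status`` ("case"/"control"), ``sex``
    ("male"/"female"), ``age`` (years), ``cohort``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "status", "sex", "age", "cohort"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        bad = set(self.df["status"].unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"status must be case/control, got {bad}")
        if (self.df["age"] <= 0).any():
            raise ValueError("ages must be positive")

    @property
    def is_case(self) -> np.ndarray:
        return (self.df["status"] == "case").to_numpy()

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return len(self.df) - self.n_cases

    def design_covariates(self, covariates: tuple[str, ...]) -> np.ndarray:
        cols = []
        for name in covariates:
            if name == "sex":
                cols.append((self.df["sex"] == "male").to_numpy(float))
            elif name == "age":
                cols.append(self.df["age"].to_numpy(float))
            else:
                cols.append(self.df[name].to_numpy(float))
        return np.column_stack(cols) if cols else np.empty((len(self.df), 0))


@dataclass
class AssociationResult:
    """Per-variant additive-model association summary.

    ``beta`` is the log odds ratio per effect-allele dosage unit; the Wald
    95% CI is ``exp(beta ± 1.959964·se)`` and ``p`` the two-sided normal
    P-value. ``direction`` is the sign of ``beta``.
    """

    variant_id: str
    beta: float
    se: float
    p: float
    n_used: int
    maf_cases: float
    maf_controls: float
    effect_allele: str = "A"
    other_allele: str = "G"
    converged: bool = True
    note: str = ""

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z_95 * self.se)

    @property
    def direction(self) -> int:
        return int(np.sign(self.beta))


@dataclass(frozen=True)
class ReplicationVerdict:
    variant_id: str
    passed: bool
    reason: str


def _effect_allele_freq(dosages: np.ndarray) -> float:
    d = dosages[np.isfinite(dosages)]
    return float(d.sum() / (2.0 * d.size)) if d.size else float("nan")


def fit_additive_logistic(
    dosages: np.ndarray,
    samples: SampleTable,
    covariates: tuple[str, ...] = ("sex", "age"),
    variant_id: str = "variant",
    effect_allele: str = "A",
    other_allele: str = "G",
) -> AssociationResult:
    """Fit ``logit P(case) = b0 + beta*dosage + covariates`` by Newton/IRLS.

    Maximum likelihood to gradient tolerance 1e-8 (max 50 iterations); the
    Wald SE comes from the inverse observed information. Samples with
    missing dosage or covariates are excluded. Complete separation yields a
    flagged non-converged result rather than a silent estimate; a
    rank-deficient design raises.
    """
    d = np.asarray(dosages, dtype=float)
    if d.shape[0] != len(samples.df):
        raise ValueError("dosages not aligned with sample table")
    y = samples.is_case.astype(float)
    cov = samples.design_covariates(covariates)
    mask = np.isfinite(d) & np.all(np.isfinite(cov), axis=1)
    d, y, cov = d[mask], y[mask], cov[mask]
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("need at least one case and one control after exclusions")

    X = np.column_stack([np.ones_like(d), d, cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    maf_ca = _effect_allele_freq(d[y == 1])
    maf_co = _effect_allele_freq(d[y == 0])
    maf_ca = min(maf_ca, 1 - maf_ca)
    maf_co = min(maf_co, 1 - maf_co)

    converged, note = True, ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(method="newton", maxiter=50, tol=1e-8, disp=0)
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        if not fit.mle_retvals.get("converged", True) or abs(beta) > 20 or not np.isfinite(se):
            converged, note = False, "non-converged (possible separation)"
            beta = float(np.clip(beta, -20, 20))
            se = se if np.isfinite(se) else float("inf")
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        converged, note = False, "complete separation: infinite estimate"
        beta, se = float(np.sign(np.corrcoef(d, y)[0, 1] or 1) * 20), float("inf")

    if converged:
        p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
        p = max(p, np.nextafter(0, 1))
    else:
        p = float("nan")
    return AssociationResult(
        variant_id=variant_id,
        beta=beta,
        se=se,
        p=p,
        n_used=int(mask.sum()),
        maf_cases=maf_ca,
        maf_controls=maf_co,
        effect_allele=effect_allele,
        other_allele=other_allele,
        converged=converged,
        note=note,
    )


def discovery_screen(
    results: list[AssociationResult], p_threshold: float = 0.001
) -> set[str]:
    """Variant IDs retained at the discovery stage: P strictly below threshold."""
    if not results:
        raise ValueError("no association results")
    return {r.variant_id for r in results if r.converged and r.p < p_threshold}


def harmonize_to(
    result: AssociationResult, effect_allele: str, other_allele: str
) -> AssociationResult:
    """Re-express a result on the given effect allele.

    If the coded alleles are swapped relative to the target, the log OR is
    negated and case/control allele frequencies complemented (MAFs are
    already folded to [0, 0.5] so they are unchanged). Raises if the allele
    pairs cannot be reconciled.
    """
    if (result.effect_allele, result.other_allele) == (effect_allele, other_allele):
        return result
    if (result.effect_allele, result.other_allele) == (other_allele, effect_allele):
        return replace(
            result,
            beta=-result.beta,
            effect_allele=effect_allele,
            other_allele=other_allele,
        )
    raise ValueError(
        f"cannot harmonize alleles {result.effect_allele}/{result.other_allele} "
        f"to {effect_allele}/{other_allele}"
    )


def replication_check(
    discovery: AssociationResult,
    replication: AssociationResult,
    alpha: float = 0.05,
) -> ReplicationVerdict:
    """Replication passes iff P < alpha with the same direction of effect.

    The replication result is harmonized to the discovery effect allele
    before signs are compared.
    """
    if discovery.variant_id != replication.variant_id:
        raise ValueError("results refer to different variants")
    rep = harmonize_to(replication, discovery.effect_allele, discovery.other_allele)
    if not rep.converged:
        return ReplicationVerdict(rep.variant_id, False, "replication fit did not converge")
    if not rep.p < alpha:
        return ReplicationVerdict(rep.variant_id, False, f"p={rep.p:.3g} >= {alpha:g}")
    if rep.direction != discovery.direction:
        return ReplicationVerdict(rep.variant_id, False, "opposite direction of association")
    return ReplicationVerdict(rep.variant_id, True, "significant, same direction")
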