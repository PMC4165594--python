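"""Causal-effect estimators: the ratio (Wald) IV with a delta-method SE, the
summary-data inverse-variance weighted (IVW) estimator, and the
instrument-strength gate.

The ratio estimator divides the second-stage log OR (disease on GRS) by the
first-stage slope (trait on GRS), giving the disease log OR per 1 unit of the
lipid trait.  Its SE comes from the first-order delta method with both stages'
variances and zero covariance — the first stage is fit in a distinct
(sub)sample.  The IVW estimator combines per-SNP Wald ratios using summary
statistics only and is used when the first-stage R² falls below the gate
(default 1.5%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError, WeakInstrumentError
from .regressions import StageEstimate

#: default instrument-strength gate on the first-stage R² (inclusive)
R2_GATE = 0.015


@dataclass
class IVEstimate:
    """Causal disease log OR per 1 unit of the lipid trait."""

    log_or_per_unit: float
    se: float
    method: str  # "ratio" | "ivw"
    first_stage_r2: float | None = None
    gate_passed: bool | None = None
    n_snps: int | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or_per_unit))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_or_per_unit - 1.96 * self.se)),
            float(np.exp(self.log_or_per_unit + 1.96 * self.se)),
        )

    @property
    def p_value(self) -> float:
        z = self.log_or_per_unit / self.se
        return float(2 * stats.norm.sf(abs(z)))


def select_method(stage1: StageEstimate, threshold: float = R2_GATE) -> str:
    """Headline method: individual-level ratio when the first-stage R² is at or
    above the gate, summary-data IVW otherwise."""
    if stage1.r_squared is None:
        raise ValidationError("first-stage estimate carries no R²")
    return "ratio" if stage1.r_squared >= threshold else "ivw"


def ratio_iv(
    stage2: StageEstimate,
    stage1: StageEstimate,
    threshold: float = R2_GATE,
    allow_weak: bool = False,
) -> IVEstimate:
    """Wald ratio: log OR per trait unit = β₂/β₁ with delta-method SE
    sqrt(se₂²/β₁² + β₂²·se₁²/β₁⁴).

    ``gate_passed`` records whether the first-stage R² meets the gate; a weak
    instrument below the gate raises unless ``allow_weak`` is set.  A
    first-stage coefficient within 1e-8 of zero always raises.
    """
    b1, se1 = stage1.coefficient, stage1.se
    b2, se2 = stage2.coefficient, stage2.se
    if abs(b1) < 1e-8:
        raise WeakInstrumentError("first-stage coefficient is (numerically) zero")
    r2 = stage1.r_squared
    gate = bool(r2 is not None and r2 >= threshold)
    if not gate and not allow_weak:
        raise WeakInstrumentError(
            f"first-stage R² {r2} below the {threshold:.3%} gate; "
            "pass allow_weak=True to force a ratio estimate"
        )
    log_or = b2 / b1
    se = np.sqrt(se2**2 / b1**2 + b2**2 * se1**2 / b1**4)
    return IVEstimate(
        log_or_per_unit=float(log_or),
        se=float(se),
        method="ratio",
        first_stage_r2=r2,
        gate_passed=gate,
    )


def ivw_summary(
    snp_disease: list[StageEstimate] | pd.DataFrame,
    snp_trait: pd.DataFrame,
) -> tuple[IVEstimate, pd.DataFrame]:
    """Summary-data IVW estimate from per-SNP disease log ORs and per-SNP trait
    effects.

    ``snp_trait`` rows need ``snp_id`` and a signed ``beta`` (risk-allele
    effect on the trait: negative for HDL under the risk-direction convention);
    if ``risk_allele`` columns are present on both sides they are checked for
    orientation mismatches.  Weights are 1/se₂ⱼ² (the trait-side SE is ignored,
    first-order IVW):

        log OR per unit = Σ β₁ⱼβ₂ⱼ/se₂ⱼ² / Σ β₁ⱼ²/se₂ⱼ² ,  se = 1/√(Σ β₁ⱼ²/se₂ⱼ²).

    Returns the pooled estimate plus a per-SNP diagnostics frame with each
    SNP's Wald ratio β₂ⱼ/β₁ⱼ and its SE se₂ⱼ/|β₁ⱼ|.
    """
    if isinstance(snp_disease, list):
        dis = pd.DataFrame(
            {
                "snp_id": [e.label for e in snp_disease],
                "log_or": [e.coefficient for e in snp_disease],
                "se": [e.se for e in snp_disease],
                "ok": [e.ok for e in snp_disease],
            }
        )
    else:
        dis = snp_disease.copy()
        if "ok" not in dis.columns:
            dis["ok"] = True
    dis = dis[dis["ok"] & np.isfinite(dis["log_or"]) & (dis["se"] > 0)]
    trait = snp_trait[snp_trait["beta"] != 0]
    merged = dis.merge(trait, on="snp_id", suffixes=("_disease", "_trait"))
    if merged.empty:
        raise ValidationError("no overlapping SNPs between disease and trait estimates")
    if "risk_allele_disease" in merged.columns:
        bad = merged["risk_allele_disease"] != merged["risk_allele_trait"]
        if bad.any():
            raise ValidationError(
                f"risk-allele orientation mismatch: {merged.loc[bad, 'snp_id'].tolist()}"
            )

    b1 = merged["beta"].to_numpy(dtype=float)
    b2 = merged["log_or"].to_numpy(dtype=float)
    se2 = merged["se"].to_numpy(dtype=float)
    w = b1**2 / se2**2
    log_or = float(np.sum(b1 * b2 / se2**2) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    diagnostics = pd.DataFrame(
        {
            "snp_id": merged["snp_id"],
            "ratio": b2 / b1,
            "ratio_se": se2 / np.abs(b1),
        }
    )
    est = IVEstimate(
        log_or_per_unit=log_or, se=se, method="ivw", n_snps=int(len(merged))
    )
    return est, diagnostics
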