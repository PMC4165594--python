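"""Inverse-variance meta-analysis of per-cohort log estimates.

Fixed-effects pooling with Cochran's Q and I² heterogeneity, a
DerSimonian–Laird random-effects check, and reconstruction of log-scale SEs
from printed odds ratios with 95% confidence intervals (needed to pool
estimates quoted only as OR and CI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass
class MetaResult:
    pooled_log_estimate: float
    se: float
    p_value: float
    q_statistic: float
    i_squared: float  # percent, truncated at 0
    model: str  # "fixed" | "random"
    k: int
    tau_squared: float = 0.0

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.pooled_log_estimate))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.pooled_log_estimate - 1.96 * self.se)),
            float(np.exp(self.pooled_log_estimate + 1.96 * self.se)),
        )


def _validate(estimates) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(estimates, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValidationError("estimates must be a non-empty list of (log x, se)")
    x, se = arr[:, 0], arr[:, 1]
    if (se <= 0).any() or not np.isfinite(arr).all():
        raise ValidationError("all SEs must be positive and finite")
    return x, se


def _heterogeneity(x, se, pooled):
    w = 1.0 / se**2
    q = float(np.sum(w * (x - pooled) ** 2))
    k = len(x)
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return q, i2


def fixed_effects(estimates) -> MetaResult:
    """Inverse-variance fixed-effects pooling of (log estimate, se) pairs."""
    x, se = _validate(estimates)
    w = 1.0 / se**2
    pooled = float(np.sum(w * x) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    q, i2 = _heterogeneity(x, se, pooled)
    p = float(2 * stats.norm.sf(abs(pooled / pooled_se)))
    return MetaResult(pooled, pooled_se, p, q, i2, "fixed", len(x))


def random_effects(estimates) -> MetaResult:
    """DerSimonian–Laird random effects: τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)),
    then inverse-variance pooling with weights 1/(se² + τ²)."""
    x, se = _validate(estimates)
    k = len(x)
    if k < 2:
        raise ValidationError("random effects needs at least 2 studies")
    w = 1.0 / se**2
    fixed = float(np.sum(w * x) / np.sum(w))
    q, _ = _heterogeneity(x, se, fixed)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * x) / np.sum(w_re))
    pooled_se = float(1.0 / np.sqrt(np.sum(w_re)))
    _, i2 = _heterogeneity(x, se, fixed)
    p = float(2 * stats.norm.sf(abs(pooled / pooled_se)))
    return MetaResult(pooled, pooled_se, p, q, i2, "random", k, tau_squared=tau2)


def se_from_ci(odds_ratio: float, lower: float, upper: float) -> float:
    """Log-scale SE from a printed OR with a symmetric 95% CI:
    se = (ln U − ln L) / (2 × 1.96).

    Warns when the printed point estimate is off the CI midpoint by more than
    0.02 on the log scale (rounded or asymmetric interval).
    """
    if not (0 < lower <= odds_ratio <= upper):
        raise ValidationError(
            f"CI ordering violated: {lower} <= {odds_ratio} <= {upper}"
        )
    se = (np.log(upper) - np.log(lower)) / (2 * 1.96)
    midpoint = 0.5 * (np.log(upper) + np.log(lower))
    if abs(np.log(odds_ratio) - midpoint) > 0.02:
        warnings.warn(
            f"OR {odds_ratio} is not at the midpoint of ({lower}, {upper}) on the "
            "log scale; the printed interval is rounded or asymmetric",
            stacklevel=2,
        )
    return float(se)


def pool_printed_ors(rows, model: str = "fixed") -> MetaResult:
    """Pool rows of (OR, ci_lower, ci_upper) printed values.

    SEs are reconstructed with :func:`se_from_ci`; a zero reconstructed SE
    (degenerate interval) is rejected downstream by the pooling validator.
    """
    estimates = [
        (np.log(or_), se_from_ci(or_, lo, hi)) for or_, lo, hi in rows
    ]
    fn = fixed_effects if model == "fixed" else random_effects
    return fn(estimates)
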