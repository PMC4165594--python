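"""First-stage, second-stage and per-SNP association fits.

First stage: OLS of the transformed lipid trait on the standardized GRS; its R²
and F(1, n−2) measure instrument strength.  Second stage: logistic regression
of case status on the GRS plus covariates (ancestry PCs, optionally batch,
age, sex and APOE ε4 count).  Per-SNP fits repeat the second stage with one
risk-allele dosage at a time for the summary-data estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import ConvergenceError, ValidationError

#: labels counted as controls in the disease model
CONTROL_LABELS = ("control", "population_control")


@dataclass
class StageEstimate:
    """One regression result.

    ``coefficient`` is the slope on the predictor of interest: trait units per
    GRS SD for the first stage, log OR per GRS SD (or per risk allele) for the
    second stage / per-SNP fits.
    """

    coefficient: float
    se: float
    n: int
    p_value: float
    r_squared: float | None = None
    f_statistic: float | None = None
    f_df: tuple[int, int] | None = None
    covariates_used: tuple[str, ...] = ()
    label: str | None = None
    ok: bool = True
    reason: str = ""

    @property
    def ci(self) -> tuple[float, float]:
        return (self.coefficient - 1.96 * self.se, self.coefficient + 1.96 * self.se)


def encode_status(
    status, include_population_controls: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Map status labels to (binary 0/1 outcome, inclusion mask).

    MCI individuals are never part of the disease model; population controls
    are coded 0 when included, dropped otherwise.  Numeric 0/1 input is passed
    through unchanged.
    """
    s = np.asarray(status)
    if s.dtype.kind in "biuf":
        y = s.astype(float)
        if not np.isin(y[~np.isnan(y)], [0.0, 1.0]).all():
            raise ValidationError("numeric status must be 0/1")
        return y, ~np.isnan(y)
    y = np.full(len(s), np.nan)
    y[s == "case"] = 1.0
    y[s == "control"] = 0.0
    if include_population_controls:
        y[s == "population_control"] = 0.0
    return y, ~np.isnan(y)


def first_stage(trait_values, grs) -> StageEstimate:
    """OLS slope of the transformed trait on the standardized GRS, with R² and
    F(1, n−2) as instrument-strength statistics.  Pairs with a missing value
    on either side are dropped."""
    y = np.asarray(trait_values, dtype=float)
    x = np.asarray(grs, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 30:
        raise ValidationError(f"first stage needs n >= 30, got {n}")
    if np.ptp(x) == 0:
        raise ValidationError("zero-variance GRS in the first stage")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(res.rsquared)
    return StageEstimate(
        coefficient=float(res.params[1]),
        se=float(res.bse[1]),
        n=n,
        p_value=float(res.pvalues[1]),
        r_squared=r2,
        f_statistic=float(res.fvalue),
        f_df=(1, n - 2),
    )


def _check_full_rank(X: pd.DataFrame) -> None:
    """Raise naming the first column that is linearly dependent on the ones
    before it (including the intercept)."""
    arr = X.to_numpy(dtype=float)
    for j in range(arr.shape[1]):
        sub = arr[:, : j + 1]
        if np.linalg.matrix_rank(sub) < j + 1:
            raise ValidationError(f"singular covariate matrix: column {X.columns[j]!r}")


def second_stage(
    status,
    grs,
    covariates: pd.DataFrame | None = None,
    include_population_controls: bool = True,
) -> StageEstimate:
    """Logistic regression of disease status on the GRS plus covariates;
    returns the log OR per GRS SD with its information-matrix SE."""
    y, keep = encode_status(status, include_population_controls)
    x = np.asarray(grs, dtype=float)
    keep = keep & ~np.isnan(x)
    cov_names: tuple[str, ...] = ()
    X = pd.DataFrame({"const": 1.0, "grs": x})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        cov_names = tuple(cov.columns)
        keep = keep & ~cov.isna().any(axis=1).to_numpy()
        X = pd.concat([X, cov], axis=1)
    X, y = X.loc[keep].reset_index(drop=True), y[keep]
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("both cases and controls are required")
    _check_full_rank(X)
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # non-convergence is detected below and raised as ConvergenceError
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=False, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic fit did not converge (separation?)")
    if not np.isfinite(res.bse["grs"]) or res.bse["grs"] > 1e4:
        raise ConvergenceError("unstable logistic SE (quasi-separation?)")
    return StageEstimate(
        coefficient=float(res.params["grs"]),
        se=float(res.bse["grs"]),
        n=int(len(y)),
        p_value=float(res.pvalues["grs"]),
        covariates_used=cov_names,
    )


def per_snp_associations(
    status,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    include_population_controls: bool = True,
) -> list[StageEstimate]:
    """One logistic fit per SNP (risk-allele dosage as the predictor).

    SNPs whose fit fails — monomorphic dosage, separation, non-convergence —
    are returned flagged (``ok=False`` with a reason and NaN estimate), never
    silently dropped.
    """
    out: list[StageEstimate] = []
    for snp in dosages.columns:
        dose = dosages[snp].to_numpy(dtype=float)
        valid = dose[~np.isnan(dose)]
        if len(valid) == 0 or np.ptp(valid) == 0:
            out.append(StageEstimate(
                coefficient=np.nan, se=np.nan, n=int(len(valid)),
                p_value=np.nan, label=str(snp), ok=False,
                reason="monomorphic or all-missing SNP",
            ))
            continue
        try:
            est = second_stage(status, dose, covariates,
                               include_population_controls)
        except (ConvergenceError, ValidationError) as exc:
            out.append(StageEstimate(
                coefficient=np.nan, se=np.nan, n=0, p_value=np.nan,
                label=str(snp), ok=False, reason=str(exc),
            ))
            continue
        est.label = str(snp)
        out.append(est)
    return out
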