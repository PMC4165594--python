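"""Lipid outcome preparation: unit conversion, covariate residualization, and
rank-based inverse-normal transformation.

Serum lipids arrive in mmol/l and are converted to mg/dl (×38.67 for the
cholesterol fractions, ×88.57 for triglycerides).  Each lipid is then regressed
on age, age² and sex, and the OLS residuals are mapped to normal scores with
Blom offsets, Φ⁻¹((r − 0.375)/(n + 0.25)).  The transform is fit within the
measured-lipid subset only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError

#: mmol/l → mg/dl conversion factors
CONVERSION = {"HDL": 38.67, "LDL": 38.67, "TC": 38.67, "TG": 88.57}

LIPIDS = tuple(CONVERSION)


@dataclass
class LipidPanel:
    """Per-individual lipid values plus the covariates used for residualization.

    ``values`` has one column per lipid (subset of HDL/LDL/TC/TG); NaN marks an
    unmeasured individual.  ``transformed`` flags panels whose values are
    unitless normal scores rather than concentrations.
    """

    values: pd.DataFrame
    age: pd.Series
    sex: pd.Series
    unit: str = "mmol/l"
    transformed: bool = False

    def __post_init__(self) -> None:
        if self.unit not in ("mmol/l", "mg/dl"):
            raise ValidationError(f"unknown lipid unit: {self.unit!r}")
        unknown = set(self.values.columns) - set(LIPIDS)
        if unknown:
            raise ValidationError(f"unknown lipid columns: {sorted(unknown)}")
        if not self.transformed:
            bad = (self.values <= 0).any()
            if bad.any():
                raise ValidationError(
                    f"non-positive lipid values in {list(bad[bad].index)}"
                )


def convert_units(panel: LipidPanel) -> LipidPanel:
    """Convert a mmol/l panel to mg/dl. Converting an mg/dl panel is an error
    (guards against double conversion)."""
    if panel.transformed:
        raise ValidationError("cannot unit-convert a transformed panel")
    if panel.unit != "mmol/l":
        raise ValidationError(f"panel already in {panel.unit}; expected mmol/l")
    factors = pd.Series({c: CONVERSION[c] for c in panel.values.columns})
    return replace(panel, values=panel.values * factors, unit="mg/dl")


def inverse_normal(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets; ties get average
    ranks.  NaNs are propagated and excluded from the ranking."""
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    v = x[ok]
    if len(v) == 0:
        return out
    if np.nanmax(v) == np.nanmin(v):
        raise ValidationError("constant input: inverse-normal transform undefined")
    ranks = stats.rankdata(v, method="average")
    out[ok] = stats.norm.ppf((ranks - 0.375) / (len(v) + 0.25))
    return out


def residualize_inverse_normal(
    values: pd.Series | np.ndarray,
    age: pd.Series | np.ndarray,
    sex: pd.Series | np.ndarray,
) -> np.ndarray:
    """Residualize on age, age² and sex, then inverse-normal transform.

    Individuals with a missing value are excluded from both the fit and the
    ranking and come back as NaN.  Requires n ≥ 10 complete observations and
    non-missing covariates for every measured individual.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(age, dtype=float)
    s = np.asarray(sex, dtype=float)
    ok = ~np.isnan(y)
    if np.isnan(a[ok]).any() or np.isnan(s[ok]).any():
        raise ValidationError("age/sex missing for individuals with measured lipids")
    if ok.sum() < 10:
        raise ValidationError(f"need at least 10 observations, got {int(ok.sum())}")
    if np.nanmax(y[ok]) == np.nanmin(y[ok]):
        raise ValidationError("constant input: transform undefined")
    X = sm.add_constant(np.column_stack([a[ok], a[ok] ** 2, s[ok]]))
    resid = sm.OLS(y[ok], X).fit().resid
    out = np.full_like(y, np.nan)
    out[ok] = inverse_normal(resid)
    return out


def transform_panel(panel: LipidPanel) -> LipidPanel:
    """Convert to mg/dl if needed, then residualize + inverse-normal each lipid."""
    if panel.transformed:
        raise ValidationError("panel already transformed")
    if panel.unit == "mmol/l":
        panel = convert_units(panel)
    out = {}
    for c in panel.values.columns:
        out[c] = residualize_inverse_normal(panel.values[c], panel.age, panel.sex)
    values = pd.DataFrame(out, index=panel.values.index)
    return replace(panel, values=values, unit="mg/dl", transformed=True)
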