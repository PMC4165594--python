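"""Weighted genotype risk scores (GRS) from risk-allele dosages.

A score is the weighted sum of risk-allele dosages divided by the number of
non-missing SNPs for that individual ("score per non-missing SNP").  Scores are
standardized within cohort over included individuals, and individuals missing
5% or more of a score's SNPs are excluded from that score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError

#: risk-direction convention per trait: the risk allele raises LDL/TC/TG (+1)
#: and lowers HDL (−1)
RISK_DIRECTION = {"HDL": -1.0, "LDL": 1.0, "TC": 1.0, "TG": 1.0}


def orient_weights(raw_weights: pd.DataFrame) -> pd.DataFrame:
    """Orient each weights row to its risk allele.

    Input rows carry the signed per-allele effect of ``risk_allele`` on the
    trait.  Rows whose sign is inconsistent with the trait's risk direction
    (positive for LDL/TC/TG, negative for HDL) have their alleles swapped.  On
    output every beta is a positive magnitude, ``risk_allele`` is the allele
    that raises LDL/TC/TG or lowers HDL, and an ``oriented`` marker column is
    set (a positive HDL magnitude is otherwise ambiguous), making the
    operation idempotent.
    """
    w = raw_weights.copy()
    if "oriented" in w.columns and w["oriented"].astype(bool).all():
        return w
    if (w["beta"] == 0).any():
        bad = w.loc[w["beta"] == 0, "snp_id"].tolist()
        raise ValidationError(f"zero beta, risk direction undefined: {bad}")
    dup = w.duplicated(subset=["snp_id", "trait"])
    if dup.any():
        raise ValidationError(
            f"duplicate (snp, trait) rows: {w.loc[dup, 'snp_id'].tolist()}"
        )
    unknown = set(w["trait"]) - set(RISK_DIRECTION)
    if unknown:
        raise ValidationError(f"unknown traits: {sorted(unknown)}")
    direction = w["trait"].map(RISK_DIRECTION)
    flip = np.sign(w["beta"]) != direction
    ra = w["risk_allele"].where(~flip, w["other_allele"])
    oa = w["other_allele"].where(~flip, w["risk_allele"])
    w["risk_allele"], w["other_allele"] = ra, oa
    w["beta"] = w["beta"].abs()
    w["oriented"] = True
    return w


def select_weights(
    weights: pd.DataFrame, trait: str, snp_set: str = "full"
) -> pd.DataFrame:
    """Rows of one trait's score: the full set or the trait-specific subset,
    dropping rows flagged excluded (e.g. the APOE-region SNP)."""
    if snp_set not in ("full", "specific"):
        raise ValidationError(f"snp_set must be 'full' or 'specific': {snp_set!r}")
    sub = weights[(weights["trait"] == trait)]
    if "excluded" in sub.columns:
        sub = sub[~sub["excluded"].astype(bool)]
    if snp_set == "specific":
        sub = sub[sub["trait_specific"].astype(bool)]
    if sub.empty:
        raise ValidationError(f"no weights for trait {trait!r} set {snp_set!r}")
    return sub


def compute_grs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    trait: str | None = None,
    snp_set: str | None = None,
    max_missing: float = 0.05,
) -> pd.DataFrame:
    """Compute one weighted score for every individual.

    ``weights`` is either a pre-selected set of rows (``trait``/``snp_set``
    omitted) or the complete table plus a trait and set selector.  Dosage
    columns are risk-allele dosages in [0, 2]; fractional (imputed) values are
    accepted.  Returns a frame indexed like ``dosages`` with columns ``raw``,
    ``standardized``, ``n_missing`` and ``excluded``; individuals with a
    missing fraction ≥ ``max_missing`` are excluded and get no standardized
    score.
    """
    if trait is not None:
        weights = select_weights(weights, trait, snp_set or "full")
    snps = weights["snp_id"].to_numpy()
    betas = weights["beta"].to_numpy(dtype=float)
    if len(snps) != len(set(snps)):
        raise ValidationError("duplicate SNPs in the selected weights")

    present = [s in dosages.columns for s in snps]
    if not all(present):
        absent = [s for s, ok in zip(snps, present) if not ok]
        warnings.warn(
            f"{len(absent)} weight SNPs absent from the dosage matrix, "
            f"treated as missing for all individuals: {absent[:5]}...",
            stacklevel=2,
        )
    mat = np.full((len(dosages), len(snps)), np.nan)
    for j, (s, ok) in enumerate(zip(snps, present)):
        if ok:
            mat[:, j] = dosages[s].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(mat) < 0 or np.nanmax(mat) > 2:
            raise ValidationError("dosages must lie in [0, 2]")

    missing = np.isnan(mat)
    n_nonmiss = (~missing).sum(axis=1)
    weighted = np.where(missing, 0.0, mat) @ betas
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(n_nonmiss > 0, weighted / np.maximum(n_nonmiss, 1), np.nan)
    n_missing = missing.sum(axis=1)
    excluded = (n_missing / len(snps)) >= max_missing

    std = np.full(len(raw), np.nan)
    inc = ~excluded
    if inc.any():
        mu = raw[inc].mean()
        sd = raw[inc].std(ddof=0)
        if sd == 0:
            # constant score (e.g. all-zero weights): no standardized version
            warnings.warn("zero-variance score; standardized scores set to NaN",
                          stacklevel=2)
        else:
            std[inc] = (raw[inc] - mu) / sd

    return pd.DataFrame(
        {
            "raw": raw,
            "standardized": std,
            "n_missing": n_missing.astype(int),
            "excluded": excluded,
        },
        index=dosages.index,
    )
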