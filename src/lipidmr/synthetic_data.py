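"""Multi-cohort case-control simulator with a known lipid→disease causal structure.

The generator emulates the statistical skeleton of a lipid Mendelian-randomization
study: independent autosomal SNPs with additive per-allele effects on four lipid
traits (HDL-c, LDL-c, TC, TG), a shared normal confounder acting on both trait and
disease, logistic disease risk driven by a configurable causal effect of the trait
(plus optional direct, pleiotropic SNP effects), and case-control ascertainment by
rejection sampling from a large base population.  Three cohorts are produced by
default — a large case-control panel with population controls, a mid-sized clinical
cohort carrying the measured-lipid subset (including MCI individuals), and a small
replication cohort.

Every simulated dataset is accompanied by a :class:`TruthRecord` holding the
generating parameters and the realized first-stage R², so downstream estimators can
be tested for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SamplingError

TRAITS = ("HDL", "LDL", "TC", "TG")

#: trait direction convention: the risk allele raises LDL/TC/TG and lowers HDL
TRAIT_DIRECTION = {"HDL": -1.0, "LDL": 1.0, "TC": 1.0, "TG": 1.0}

#: serum scale/location used to turn the unit-variance latent trait into mmol/l
_SERUM_BASE = {"HDL": 1.60, "LDL": 3.20, "TC": 5.50, "TG": 1.50}
_SERUM_SD = {"HDL": 0.30, "LDL": 0.60, "TC": 0.80, "TG": 0.35}

_STATUS_CASE = "case"
_STATUS_CONTROL = "control"
_STATUS_POP = "population_control"
_STATUS_MCI = "MCI"

# named RNG substreams so per-step reruns are stable
_STREAM_WEIGHTS = 0
_STREAM_COHORT_BASE = 100


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _as_trait_map(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(TRAITS) - set(value)
        if missing:
            raise ConfigurationError(f"{name} missing traits: {sorted(missing)}")
        return {t: float(value[t]) for t in TRAITS}
    return {t: float(value) for t in TRAITS}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the target study structure: SNP-set sizes 69/55/40/70 (full)
    and 45/9/16/18 (trait specific), three cohorts of 9,398 / 663 / 517
    individuals, a measured-lipid subset of ~550 (83% of the clinical cohort)
    plus 127 MCI individuals, and full-score instrument strengths of roughly
    1.8%–4.3% of trait variance.
    """

    n_snps_full: Mapping[str, int] = field(
        default_factory=lambda: {"HDL": 69, "LDL": 55, "TC": 70, "TG": 40}
    )
    n_snps_specific: Mapping[str, int] = field(
        default_factory=lambda: {"HDL": 45, "LDL": 9, "TC": 18, "TG": 16}
    )
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: fraction of trait variance explained by the full-score SNP effects
    trait_r2_target: Mapping[str, float] | float = field(
        default_factory=lambda: {"HDL": 0.042, "LDL": 0.018, "TC": 0.036, "TG": 0.043}
    )
    confounder_effect_trait: float = 0.3
    confounder_effect_disease: float = 0.3
    #: log OR of disease per 1 unit of (latent, unit-variance) trait
    causal_log_or_per_unit: Mapping[str, float] | float = 0.0
    #: direct per-SNP effect on disease liability (scalar broadcast to all SNPs)
    pleiotropy_log_or: float = 0.0
    #: (n_cases, n_screened_controls, n_population_controls) per cohort
    cohort_sizes: Sequence[tuple[int, int, int]] = (
        (3234, 1175, 4989),
        (350, 313, 0),
        (330, 187, 0),
    )
    cohort_names: Sequence[str] = ("COHORT1", "COHORT2", "COHORT3")
    #: index of the cohort that carries measured serum lipids
    lipid_cohort: int = 1
    lipid_subset_fraction: float = 0.83
    n_mci: int = 127
    missing_rate: float = 0.01
    #: marginal disease probability in the base population (sampling efficiency)
    base_prevalence: float = 0.30
    max_oversample: int = 80
    seed: int = 0

    def validate(self) -> None:
        full = {t: int(self.n_snps_full.get(t, 0)) for t in TRAITS}
        spec = {t: int(self.n_snps_specific.get(t, 0)) for t in TRAITS}
        for t in TRAITS:
            if spec[t] > full[t]:
                raise ConfigurationError(
                    f"trait-specific count exceeds full count for {t}: "
                    f"{spec[t]} > {full[t]}"
                )
            if full[t] < 1:
                raise ConfigurationError(f"need at least one SNP for {t}")
        lo, hi = self.maf_range
        if not (0.01 <= lo < hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0.01, 0.5]: {self.maf_range}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not 0.0 < self.base_prevalence < 1.0:
            raise ConfigurationError("base_prevalence must be in (0, 1)")
        if not 0.0 < self.lipid_subset_fraction <= 1.0:
            raise ConfigurationError("lipid_subset_fraction must be in (0, 1]")
        for sizes in self.cohort_sizes:
            n_cases, n_ctrl, n_pop = sizes
            if n_cases <= 0 or n_ctrl <= 0 or n_pop < 0:
                raise ConfigurationError(f"cohort sizes must be positive: {sizes}")
        if not 0 <= self.lipid_cohort < len(self.cohort_sizes):
            raise ConfigurationError("lipid_cohort index out of range")
        r2 = _as_trait_map(self.trait_r2_target, "trait_r2_target")
        c2 = self.confounder_effect_trait ** 2
        for t, v in r2.items():
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"trait_r2_target[{t}] out of [0, 1): {v}")
            if v + c2 >= 1.0:
                raise ConfigurationError(
                    f"trait_r2_target[{t}] + confounder_effect_trait^2 must be < 1"
                )

    @property
    def r2_by_trait(self) -> dict[str, float]:
        return _as_trait_map(self.trait_r2_target, "trait_r2_target")

    @property
    def causal_by_trait(self) -> dict[str, float]:
        return _as_trait_map(self.causal_log_or_per_unit, "causal_log_or_per_unit")


@dataclass
class TruthRecord:
    """Generating parameters stored alongside each simulated dataset."""

    causal_log_or_per_unit: dict[str, float]
    #: signed per-allele effect of each SNP on each trait (trait SD units);
    #: index snp_id, one column per trait, 0 where the SNP does not act
    snp_trait_effects: pd.DataFrame
    #: direct (pleiotropic) per-SNP log OR on disease
    snp_disease_effects: pd.Series
    #: variance fraction of each trait explained by the true-weight score,
    #: measured on unconditional base-population draws
    realized_r2: dict[str, float]


@dataclass
class CohortData:
    """One cohort: risk-allele dosages plus the phenotype/covariate table."""

    name: str
    #: individuals × SNPs, risk-allele dosage in [0, 2], NaN = missing
    dosages: pd.DataFrame
    #: status/age/sex/PCs/batch/apoe4 and serum lipids (mmol/l, NaN where unmeasured)
    phenotypes: pd.DataFrame
    lipid_unit: str = "mmol/l"


# ---------------------------------------------------------------------------
# weights table
# ---------------------------------------------------------------------------

def simulate_weights(config: SimulationConfig) -> pd.DataFrame:
    """Draw an external-GWAS-style weights table with the configured set sizes.

    Trait-specific SNPs are associated with exactly one trait; the remaining
    (shared) SNPs are each associated with at least two traits so that the full
    sets overlap, mirroring the overlap structure of published lipid loci.
    Effect sizes are scaled per trait so the additive score explains
    ``trait_r2_target`` of the trait variance under Hardy-Weinberg equilibrium.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_WEIGHTS)
    full = {t: int(config.n_snps_full[t]) for t in TRAITS}
    spec = {t: int(config.n_snps_specific[t]) for t in TRAITS}

    # membership: list of (snp_index, traits, specific_flag)
    memberships: list[tuple[list[str], bool]] = []
    for t in TRAITS:
        memberships.extend(([t], True) for _ in range(spec[t]))

    quota = {t: full[t] - spec[t] for t in TRAITS}
    # greedy: each shared SNP covers the two largest remaining quotas, plus any
    # other open trait with probability 0.3.  When only one trait still has
    # quota, the remainder become single-trait SNPs that are nevertheless not
    # flagged trait-specific (the specific ⇒ single-trait implication is
    # one-directional).
    while any(q > 0 for q in quota.values()):
        open_traits = sorted((t for t in TRAITS if quota[t] > 0),
                             key=lambda t: -quota[t])
        if len(open_traits) == 1:
            t = open_traits[0]
            memberships.extend(([t], False) for _ in range(quota[t]))
            quota[t] = 0
            break
        chosen = list(open_traits[:2])
        for t in open_traits[2:]:
            if rng.random() < 0.3:
                chosen.append(t)
        for t in chosen:
            quota[t] -= 1
        memberships.append((chosen, False))

    n_snps = len(memberships)
    snp_ids = [f"rs{100000 + i}" for i in range(n_snps)]
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=n_snps)
    alleles = np.array(list("ACGT"))
    pair_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(n_snps)])
    risk_alleles = alleles[pair_idx[:, 0]]
    other_alleles = alleles[pair_idx[:, 1]]

    rows = []
    for i, (traits, is_specific) in enumerate(memberships):
        for t in traits:
            rows.append({
                "snp_id": snp_ids[i],
                "trait": t,
                "risk_allele": risk_alleles[i],
                "other_allele": other_alleles[i],
                "beta": abs(rng.normal(0.0, 1.0)) + 0.05,  # raw magnitude, rescaled below
                "se_beta": np.nan,
                "trait_specific": is_specific,
                "risk_allele_freq": mafs[i],
                "oriented": True,
                "excluded": False,
                "reason": "",
            })
    table = pd.DataFrame(rows)

    # rescale per trait so Var(sum beta * dosage) over the full set = r2 target
    r2 = config.r2_by_trait
    for t in TRAITS:
        mask = table["trait"] == t
        f = table.loc[mask, "risk_allele_freq"].to_numpy()
        m = table.loc[mask, "beta"].to_numpy()
        var_raw = np.sum(m ** 2 * 2.0 * f * (1.0 - f))
        scale = np.sqrt(r2[t] / var_raw) if var_raw > 0 and r2[t] > 0 else 0.0
        table.loc[mask, "beta"] = m * scale
    # GWAS-significant loci: |beta|/se between ~6 and ~25
    z = rng.uniform(6.0, 25.0, size=len(table))
    with np.errstate(invalid="ignore"):
        table["se_beta"] = np.where(table["beta"] > 0, table["beta"] / z, 0.01)
    return table


def signed_trait_effects(weights: pd.DataFrame, trait: str) -> pd.Series:
    """Per-allele effect of the risk allele on the trait, with the sign convention
    that the risk allele lowers HDL and raises LDL/TC/TG."""
    sub = weights[weights["trait"] == trait]
    return pd.Series(
        sub["beta"].to_numpy() * TRAIT_DIRECTION[trait],
        index=sub["snp_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _effect_matrix(weights: pd.DataFrame) -> pd.DataFrame:
    """snp × trait signed effect matrix (0 where the SNP does not act)."""
    snps = weights["snp_id"].drop_duplicates().to_numpy()
    eff = pd.DataFrame(0.0, index=snps, columns=list(TRAITS))
    for t in TRAITS:
        s = signed_trait_effects(weights, t)
        eff.loc[s.index, t] = s.to_numpy()
    return eff


def _draw_block(rng, n, freqs, eff, config, pleio):
    """Draw n unconditional individuals; returns (dosages, latent, status01, extras)."""
    p = len(freqs)
    dos = rng.binomial(2, freqs, size=(n, p)).astype(float)
    u = rng.normal(size=n)
    genetic = dos @ eff.to_numpy()                     # n × 4, trait order TRAITS
    genetic_mean = 2.0 * freqs @ eff.to_numpy()
    r2 = np.array([config.r2_by_trait[t] for t in TRAITS])
    c_t = config.confounder_effect_trait
    sigma = np.sqrt(np.clip(1.0 - r2 - c_t ** 2, 0.0, None))
    latent = (genetic - genetic_mean) + c_t * u[:, None] \
        + rng.normal(size=(n, len(TRAITS))) * sigma
    causal = np.array([config.causal_by_trait[t] for t in TRAITS])
    eta = (
        np.log(config.base_prevalence / (1.0 - config.base_prevalence))
        + latent @ causal
        + config.confounder_effect_disease * u
        + (dos - 2.0 * freqs) @ pleio
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    status = rng.random(n) < prob
    age = np.clip(rng.normal(75.0, 7.0, size=n), 60.0, 95.0)
    sex = rng.binomial(1, 0.55, size=n).astype(int)
    pcs = rng.normal(size=(n, 4))
    batch = rng.binomial(1, 0.5, size=n).astype(int)
    apoe4 = rng.binomial(2, 0.2, size=n).astype(int)
    return dos, latent, status, (age, sex, pcs, batch, apoe4)


def _serum_lipids(latent, age, sex, rng):
    """Map unit-variance latent traits to serum mmol/l with age/sex structure.

    TG is generated on a log scale (right-skewed, strictly positive); the other
    lipids are affine in the latent value with a small positivity floor.
    """
    out = {}
    for k, t in enumerate(TRAITS):
        if t == "TG":
            vals = _SERUM_BASE[t] * np.exp(
                0.25 * latent[:, k] + 0.004 * (age - 75.0) - 0.02 * sex
            )
        else:
            vals = (
                _SERUM_BASE[t]
                + _SERUM_SD[t] * latent[:, k]
                + 0.006 * (age - 75.0)
                - 0.04 * sex
            )
        out[t] = np.maximum(vals, 0.05)
    return out


def simulate_cohorts(
    config: SimulationConfig, weights: pd.DataFrame
) -> tuple[list[CohortData], TruthRecord]:
    """Simulate all cohorts by case-control rejection sampling.

    Cases and screened controls are accumulated from unconditional draws of the
    base population until the requested counts are met (bounded by
    ``max_oversample`` times the target); population controls and MCI
    individuals are sampled unconditionally.  Serum lipids (mmol/l) are recorded
    only for the designated subset of the lipid cohort.
    """
    config.validate()
    eff = _effect_matrix(weights)
    snps = eff.index.to_numpy()
    loci = weights.drop_duplicates("snp_id").set_index("snp_id")
    freqs = loci.loc[snps, "risk_allele_freq"].to_numpy()
    pleio = np.full(len(snps), float(config.pleiotropy_log_or))

    cohorts: list[CohortData] = []
    r2_pool: list[np.ndarray] = []
    r2_latent: list[np.ndarray] = []

    for ci, (n_cases, n_ctrl, n_pop) in enumerate(config.cohort_sizes):
        rng = _rng(config.seed, _STREAM_COHORT_BASE + ci)
        need_cases, need_ctrl = n_cases, n_ctrl
        got_dos, got_lat, got_status = [], [], []
        got_extra = []
        drawn = 0
        budget = config.max_oversample * (n_cases + n_ctrl)
        prev = config.base_prevalence
        while need_cases > 0 or need_ctrl > 0:
            block = int(min(
                max(need_cases / max(prev, 1e-3), need_ctrl / max(1 - prev, 1e-3), 256) * 1.4,
                budget - drawn,
            ))
            if block <= 0:
                raise SamplingError(
                    f"cohort {ci}: could not reach {n_cases} cases / {n_ctrl} controls "
                    f"within {budget} base draws (base_prevalence={prev})"
                )
            dos, lat, status, extras = _draw_block(rng, block, freqs, eff, config, pleio)
            drawn += block
            if ci == 0 and len(r2_pool) * block < 60000:
                r2_pool.append(dos @ eff.to_numpy())
                r2_latent.append(lat)
            case_idx = np.flatnonzero(status)[:need_cases]
            ctrl_idx = np.flatnonzero(~status)[:need_ctrl]
            keep = np.concatenate([case_idx, ctrl_idx])
            got_dos.append(dos[keep])
            got_lat.append(lat[keep])
            got_status.extend([_STATUS_CASE] * len(case_idx))
            got_status.extend([_STATUS_CONTROL] * len(ctrl_idx))
            got_extra.append(tuple(
                e[keep] if e.ndim == 1 else e[keep, :] for e in extras
            ))
            need_cases -= len(case_idx)
            need_ctrl -= len(ctrl_idx)

        # unconditional tail: population controls, then MCI for the lipid cohort
        n_uncond = n_pop + (config.n_mci if ci == config.lipid_cohort else 0)
        if n_uncond > 0:
            dos, lat, status, extras = _draw_block(
                rng, n_uncond, freqs, eff, config, pleio
            )
            got_dos.append(dos)
            got_lat.append(lat)
            got_status.extend([_STATUS_POP] * n_pop)
            if ci == config.lipid_cohort:
                got_status.extend([_STATUS_MCI] * config.n_mci)
            got_extra.append(tuple(
                e if e.ndim == 1 else e[:, :] for e in extras
            ))

        dos = np.vstack(got_dos)
        lat = np.vstack(got_lat)
        age = np.concatenate([e[0] for e in got_extra])
        sex = np.concatenate([e[1] for e in got_extra])
        pcs = np.vstack([e[2] for e in got_extra])
        batch = np.concatenate([e[3] for e in got_extra])
        apoe4 = np.concatenate([e[4] for e in got_extra])
        status = np.array(got_status)
        n = len(status)
        iids = [f"{config.cohort_names[ci]}_{i:06d}" for i in range(n)]

        # measured serum lipids: only in the designated cohort/subset
        lipids = {t: np.full(n, np.nan) for t in TRAITS}
        if ci == config.lipid_cohort:
            cc = np.flatnonzero((status == _STATUS_CASE) | (status == _STATUS_CONTROL))
            k = int(round(config.lipid_subset_fraction * len(cc)))
            measured = np.concatenate([
                rng.permutation(cc)[:k],
                np.flatnonzero(status == _STATUS_MCI),
            ])
            serum = _serum_lipids(lat[measured], age[measured], sex[measured], rng)
            for t in TRAITS:
                lipids[t][measured] = serum[t]

        if config.missing_rate > 0:
            mask = rng.random(dos.shape) < config.missing_rate
            dos = np.where(mask, np.nan, dos)

        dosages = pd.DataFrame(dos, index=pd.Index(iids, name="IID"), columns=snps)
        pheno = pd.DataFrame(
            {
                "status": status,
                "age": age,
                "sex": sex,
                "PC1": pcs[:, 0],
                "PC2": pcs[:, 1],
                "PC3": pcs[:, 2],
                "PC4": pcs[:, 3],
                "batch": batch,
                "apoe4": apoe4,
                **{t: lipids[t] for t in TRAITS},
            },
            index=pd.Index(iids, name="IID"),
        )
        cohorts.append(CohortData(config.cohort_names[ci], dosages, pheno))

    scores = np.vstack(r2_pool)
    latents = np.vstack(r2_latent)
    realized = {}
    for k, t in enumerate(TRAITS):
        s, y = scores[:, k], latents[:, k]
        if s.std() == 0:
            realized[t] = 0.0
        else:
            realized[t] = float(np.corrcoef(s, y)[0, 1] ** 2)

    truth = TruthRecord(
        causal_log_or_per_unit=config.causal_by_trait,
        snp_trait_effects=eff,
        snp_disease_effects=pd.Series(pleio, index=snps),
        realized_r2=realized,
    )
    return cohorts, truth


# ---------------------------------------------------------------------------
# plain-text IO (PLINK-.raw-style dosages, TSV phenotypes, CSV weights)
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortData, outdir: str | Path, weights: pd.DataFrame) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loci = weights.drop_duplicates("snp_id").set_index("snp_id")
    cols = {
        snp: f"{snp}_{loci.loc[snp, 'risk_allele']}" for snp in cohort.dosages.columns
    }
    raw = cohort.dosages.rename(columns=cols).reset_index()
    raw.insert(0, "FID", raw["IID"])
    raw.to_csv(outdir / "dosages.raw", sep="\t", index=False, na_rep="NA",
               float_format="%.6g")
    cohort.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", na_rep="NA",
                             float_format="%.10g")


def read_cohort(indir: str | Path, name: str | None = None) -> CohortData:
    indir = Path(indir)
    raw = pd.read_csv(indir / "dosages.raw", sep="\t", na_values="NA")
    raw = raw.set_index("IID").drop(columns=["FID"])
    raw.columns = [c.rsplit("_", 1)[0] for c in raw.columns]
    pheno = pd.read_csv(indir / "phenotypes.tsv", sep="\t", na_values="NA",
                        index_col="IID")
    return CohortData(name or indir.name, raw, pheno)


def write_weights(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, index=False, float_format="%.10g")


def read_weights(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    """Sidecar key=value file; per-SNP vectors stored as inline JSON."""
    lines = []
    for t, v in truth.causal_log_or_per_unit.items():
        lines.append(f"causal_log_or_per_unit.{t}={v!r}")
    for t, v in truth.realized_r2.items():
        lines.append(f"realized_r2.{t}={v!r}")
    lines.append("snp_trait_effects=" + json.dumps(
        {c: truth.snp_trait_effects[c].round(10).to_dict() for c in truth.snp_trait_effects},
        sort_keys=True))
    lines.append("snp_disease_effects=" + json.dumps(
        truth.snp_disease_effects.round(10).to_dict(), sort_keys=True))
    Path(path).write_text("\n".join(lines) + "\n")
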