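"""End-to-end orchestration: simulate or ingest cohorts, prepare lipid
phenotypes, build scores, fit both stages, estimate causal effects, pool across
cohorts, and write a reproducible report bundle.

The analysis sequence follows the study design: the first-stage (trait ~ GRS)
equation is fit once per trait×set in the measured-lipid subset of the
designated cohort (MCI individuals included); second-stage (disease ~ GRS)
logistic fits run per cohort with ancestry PCs (plus a batch indicator for the
lipid cohort); the individual-level ratio IV is the headline method when the
first-stage R² meets the gate, the summary-data IVW otherwise; per-cohort
estimates are pooled by inverse-variance fixed-effects meta-analysis (random
effects as a check).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import grs, iv, meta, phenotypes, regressions, synthetic_data
from .errors import ConfigurationError, WeakInstrumentError
from .synthetic_data import TRAITS, SimulationConfig

log = logging.getLogger("lipidmr")

PC_COLUMNS = ("PC1", "PC2", "PC3", "PC4")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulation`` is set (synthetic run, seed mandatory) or
    ``cohort_dirs`` + ``weights_path`` point at ingested data.
    """

    outdir: str = "lipidmr_out"
    simulation: SimulationConfig | None = None
    cohort_dirs: Sequence[str] | None = None
    weights_path: str | None = None
    #: index of the cohort carrying measured lipids (ingested runs)
    lipid_cohort: int = 1
    traits: Sequence[str] = TRAITS
    sets: Sequence[str] = ("full", "specific")
    gate_threshold: float = iv.R2_GATE
    meta_models: Sequence[str] = ("fixed", "random")
    include_population_controls: bool = True
    adjust_age_sex_apoe: bool = False
    run_ivw: bool = True
    max_missing: float = 0.05
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**{
                k: (tuple(map(tuple, v)) if k == "cohort_sizes" else v)
                for k, v in sim.items()
            })
        return cfg

    def validate(self) -> None:
        if self.simulation is None:
            if not self.cohort_dirs or not self.weights_path:
                raise ConfigurationError(
                    "need either a simulation block or cohort_dirs + weights_path"
                )
            for d in list(self.cohort_dirs) + [self.weights_path]:
                if not Path(d).exists():
                    raise ConfigurationError(f"input path does not exist: {d}")
        elif self.seed is not None:
            self.simulation.seed = self.seed
        bad = set(self.traits) - set(TRAITS)
        if bad:
            raise ConfigurationError(f"unknown traits: {sorted(bad)}")


def _covariates(cohort, is_lipid_cohort: bool, adjust: bool) -> pd.DataFrame:
    cols = list(PC_COLUMNS)
    if is_lipid_cohort and cohort.phenotypes["batch"].nunique() > 1:
        cols.append("batch")
    if adjust:
        cols += ["age", "sex", "apoe4"]
    return cohort.phenotypes[cols].reset_index(drop=True)


def _echo_config(config: RunConfig, outdir: Path) -> None:
    d = dataclasses.asdict(config)
    if d.get("simulation"):
        for k, v in list(d["simulation"].items()):
            if isinstance(v, tuple):
                d["simulation"][k] = [list(x) if isinstance(x, tuple) else x for x in v]
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    (outdir / "config.yaml").write_text(yaml.safe_dump(d, sort_keys=True))


def run(config: RunConfig):
    """Execute the full analysis; returns the summary dict and writes
    ``stages.tsv``, ``iv.tsv``, ``meta.tsv``, ``summary.json``, ``config.yaml``
    and ``run.log`` into the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        summary = _run_inner(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()
    return summary


def _run_inner(config: RunConfig, outdir: Path):
    if config.simulation is not None:
        sim = config.simulation
        weights = synthetic_data.simulate_weights(sim)
        cohorts, truth = synthetic_data.simulate_cohorts(sim, weights)
        lipid_idx = sim.lipid_cohort
        synthetic_data.write_truth(truth, outdir / "truth.txt")
    else:
        weights = synthetic_data.read_weights(config.weights_path)
        cohorts = [synthetic_data.read_cohort(d) for d in config.cohort_dirs]
        lipid_idx = config.lipid_cohort
    weights = grs.orient_weights(weights)
    _echo_config(config, outdir)

    # pre-flight: every weight SNP must be in every dosage matrix
    for c in cohorts:
        absent = sorted(set(weights["snp_id"]) - set(c.dosages.columns))
        if absent:
            raise ConfigurationError(
                f"cohort {c.name}: weight SNPs absent from dosages: {absent[:10]}"
            )

    # lipid phenotype preparation (within the measured subset only)
    lipid_cohort = cohorts[lipid_idx]
    panel = phenotypes.LipidPanel(
        values=lipid_cohort.phenotypes[list(config.traits)],
        age=lipid_cohort.phenotypes["age"],
        sex=lipid_cohort.phenotypes["sex"],
        unit=lipid_cohort.lipid_unit,
    )
    transformed = phenotypes.transform_panel(panel).values
    n_measured = int(transformed.notna().any(axis=1).sum())
    log.info("lipid cohort %s: %d individuals with measured lipids",
             lipid_cohort.name, n_measured)

    stage_rows, iv_rows, meta_rows = [], [], []
    snp_fit_cache: dict[tuple[str, str], regressions.StageEstimate] = {}
    summary: dict = {"traits": {}, "n_measured_lipids": n_measured}

    for trait in config.traits:
        summary["traits"][trait] = {}
        for sset in config.sets:
            wsub = grs.select_weights(weights, trait, sset)
            scores = {}
            for c in cohorts:
                sc = grs.compute_grs(c.dosages, wsub, max_missing=config.max_missing)
                scores[c.name] = sc
                log.info(
                    "%s %s/%s: %d individuals excluded for >=%.0f%% missing SNPs",
                    c.name, trait, sset, int(sc["excluded"].sum()),
                    100 * config.max_missing,
                )

            # first stage: measured-lipid subset of the lipid cohort, MCI included
            sc = scores[lipid_cohort.name]
            stage1 = regressions.first_stage(
                transformed[trait].to_numpy(), sc["standardized"].to_numpy()
            )
            stage_rows.append(_stage_row(lipid_cohort.name, trait, sset,
                                         "first", stage1))
            method = iv.select_method(stage1, config.gate_threshold)

            ratio_ests, ivw_ests, grs_logors = [], [], []
            for ci, c in enumerate(cohorts):
                cov = _covariates(c, ci == lipid_idx, config.adjust_age_sex_apoe)
                sc = scores[c.name]
                stage2 = regressions.second_stage(
                    c.phenotypes["status"].to_numpy(), sc["standardized"].to_numpy(),
                    cov, config.include_population_controls,
                )
                stage_rows.append(_stage_row(c.name, trait, sset, "second", stage2))
                grs_logors.append((stage2.coefficient, stage2.se))

                try:
                    est = iv.ratio_iv(stage2, stage1, config.gate_threshold,
                                      allow_weak=True)
                except WeakInstrumentError:
                    est = None
                if est is not None:
                    ratio_ests.append(est)
                    iv_rows.append(_iv_row(c.name, trait, sset, est))

                if config.run_ivw:
                    snp_ests = _per_snp_cached(
                        snp_fit_cache, c, wsub["snp_id"].tolist(), cov, config
                    )
                    n_failed = sum(not e.ok for e in snp_ests)
                    if n_failed:
                        log.info("%s %s/%s: %d SNP fits flagged",
                                 c.name, trait, sset, n_failed)
                    trait_side = wsub.assign(
                        beta=wsub["beta"] * grs.RISK_DIRECTION[trait]
                    )[["snp_id", "beta", "se_beta"]]
                    est_ivw, _ = iv.ivw_summary(snp_ests, trait_side)
                    est_ivw.first_stage_r2 = stage1.r_squared
                    ivw_ests.append(est_ivw)
                    iv_rows.append(_iv_row(c.name, trait, sset, est_ivw))

            pooled: dict = {}
            for label, ests in (("grs_log_or", grs_logors),
                                ("iv_ratio", [(e.log_or_per_unit, e.se)
                                              for e in ratio_ests]),
                                ("iv_ivw", [(e.log_or_per_unit, e.se)
                                            for e in ivw_ests])):
                if not ests:
                    continue
                for model in config.meta_models:
                    if model == "random" and len(ests) < 2:
                        continue
                    mr = (meta.fixed_effects(ests) if model == "fixed"
                          else meta.random_effects(ests))
                    meta_rows.append(_meta_row(trait, sset, label, mr))
                    if model == "fixed":
                        pooled[label] = {
                            "or": round(mr.odds_ratio, 4),
                            "ci": [round(v, 4) for v in mr.ci],
                            "p": float(mr.p_value),
                            "i_squared": round(mr.i_squared, 2),
                        }
            summary["traits"][trait][sset] = {
                "first_stage_r2": stage1.r_squared,
                "headline_method": method,
                "meta": pooled,
            }

    _write_tables(outdir, stage_rows, iv_rows, meta_rows, summary)
    return summary


def _per_snp_cached(cache, cohort, snps, cov, config):
    todo = [s for s in snps if (cohort.name, s) not in cache]
    if todo:
        ests = regressions.per_snp_associations(
            cohort.phenotypes["status"].to_numpy(), cohort.dosages[todo],
            cov, config.include_population_controls,
        )
        for s, e in zip(todo, ests):
            cache[(cohort.name, s)] = e
    return [cache[(cohort.name, s)] for s in snps]


def _stage_row(cohort, trait, sset, stage, est):
    return {
        "cohort": cohort, "trait": trait, "set": sset, "stage": stage,
        "coefficient": est.coefficient, "se": est.se, "n": est.n,
        "r_squared": est.r_squared if est.r_squared is not None else "",
        "f_statistic": est.f_statistic if est.f_statistic is not None else "",
        "p_value": est.p_value,
    }


def _iv_row(cohort, trait, sset, est):
    lo, hi = est.ci
    return {
        "cohort": cohort, "trait": trait, "set": sset, "method": est.method,
        "log_or_per_unit": est.log_or_per_unit, "se": est.se,
        "or": f"{est.odds_ratio:.3f}", "ci_lower": f"{lo:.2f}",
        "ci_upper": f"{hi:.2f}",
        "first_stage_r2": est.first_stage_r2 if est.first_stage_r2 is not None else "",
        "gate_passed": est.gate_passed if est.gate_passed is not None else "",
        "n_snps": est.n_snps if est.n_snps is not None else "",
    }


def _meta_row(trait, sset, quantity, mr):
    lo, hi = mr.ci
    return {
        "trait": trait, "set": sset, "quantity": quantity, "model": mr.model,
        "k": mr.k, "pooled_log_estimate": mr.pooled_log_estimate, "se": mr.se,
        "or": f"{mr.odds_ratio:.3f}", "ci_lower": f"{lo:.2f}",
        "ci_upper": f"{hi:.2f}", "p_value": mr.p_value,
        "q_statistic": mr.q_statistic, "i_squared": round(mr.i_squared, 1),
        "tau_squared": mr.tau_squared,
    }


def _write_tables(outdir, stage_rows, iv_rows, meta_rows, summary):
    kw = dict(sep="\t", index=False, float_format="%.8g")
    pd.DataFrame(stage_rows).to_csv(outdir / "stages.tsv", **kw)
    pd.DataFrame(iv_rows).to_csv(outdir / "iv.tsv", **kw)
    pd.DataFrame(meta_rows).to_csv(outdir / "meta.tsv", **kw)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
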