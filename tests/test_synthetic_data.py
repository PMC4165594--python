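"""Generator contracts: set sizes, overlap structure, determinism, and the
moments of the generated genotypes and traits."""

import numpy as np
import pandas as pd
import pytest

import lipidmr as L
from lipidmr.synthetic_data import TRAITS


def test_weights_set_sizes_match_config(small_config, small_weights):
    full = small_weights.groupby("trait").size().to_dict()
    spec = small_weights.groupby("trait")["trait_specific"].sum().to_dict()
    assert full == {t: small_config.n_snps_full[t] for t in full}
    assert spec == {t: small_config.n_snps_specific[t] for t in spec}


def test_default_set_sizes_are_study_structure():
    w = L.simulate_weights(L.SimulationConfig(seed=1))
    sizes = w.groupby("trait").size()
    spec = w.groupby("trait")["trait_specific"].sum()
    assert sizes.to_dict() == {"HDL": 69, "LDL": 55, "TC": 70, "TG": 40}
    assert spec.to_dict() == {"HDL": 45, "LDL": 9, "TC": 18, "TG": 16}


def test_specific_snps_are_disjoint_and_full_sets_overlap(small_weights):
    spec = small_weights[small_weights["trait_specific"]]
    # a trait-specific SNP appears for exactly one trait
    assert spec.groupby("snp_id")["trait"].nunique().max() == 1
    shared = small_weights[~small_weights["trait_specific"]]
    assert shared.groupby("snp_id")["trait"].nunique().max() >= 2


def test_weights_rows_complete(small_weights):
    assert (small_weights["beta"] >= 0).all()
    assert (small_weights["se_beta"] > 0).all()
    assert (small_weights["risk_allele"] != small_weights["other_allele"]).all()
    assert small_weights["risk_allele_freq"].between(0.01, 0.5).all()


def test_trait_specific_exceeding_full_is_config_error():
    cfg = L.SimulationConfig(n_snps_specific={"HDL": 80, "LDL": 9, "TC": 18, "TG": 16})
    with pytest.raises(L.ConfigurationError):
        L.simulate_weights(cfg)


def test_zero_r2_gives_zero_weights_and_constant_scores(small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, trait_r2_target=0.0, missing_rate=0.0)
    w = L.simulate_weights(cfg)
    assert (w["beta"] == 0).all()
    cohorts, _ = L.simulate_cohorts(cfg, w)
    raw = L.compute_grs(cohorts[0].dosages, w, "TC", "full", max_missing=1.1)["raw"]
    assert np.allclose(raw, 0.0)


def test_seed_determinism_and_sensitivity(small_config):
    import dataclasses

    w1 = L.simulate_weights(small_config)
    w2 = L.simulate_weights(small_config)
    pd.testing.assert_frame_equal(w1, w2)
    w3 = L.simulate_weights(dataclasses.replace(small_config, seed=small_config.seed + 1))
    assert not w1["beta"].equals(w3["beta"])

    c1, t1 = L.simulate_cohorts(small_config, w1)
    c2, t2 = L.simulate_cohorts(small_config, w1)
    pd.testing.assert_frame_equal(c1[0].dosages, c2[0].dosages)
    pd.testing.assert_frame_equal(c1[1].phenotypes, c2[1].phenotypes)
    assert t1.realized_r2 == t2.realized_r2


def test_cohort_counts_and_status_labels(small_config, small_cohorts):
    cohorts, _ = small_cohorts
    for c, (n_cases, n_ctrl, n_pop) in zip(cohorts, small_config.cohort_sizes):
        counts = c.phenotypes["status"].value_counts().to_dict()
        assert counts.get("case") == n_cases
        assert counts.get("control") == n_ctrl
        assert counts.get("population_control", 0) == n_pop
    # MCI only in the lipid cohort
    assert (cohorts[0].phenotypes["status"] != "MCI").all()
    assert (cohorts[1].phenotypes["status"] == "MCI").sum() == small_config.n_mci


def test_lipids_measured_only_in_designated_subset(small_config, small_cohorts):
    cohorts, _ = small_cohorts
    assert cohorts[0].phenotypes[list(TRAITS)].isna().all().all()
    pheno = cohorts[1].phenotypes
    measured = pheno["TC"].notna()
    n_cc = (pheno["status"].isin(["case", "control"])).sum()
    expected = round(small_config.lipid_subset_fraction * n_cc) + small_config.n_mci
    assert measured.sum() == expected
    # all MCI individuals carry lipids; all lipids positive
    assert pheno.loc[pheno["status"] == "MCI", "TC"].notna().all()
    assert (pheno.loc[measured, list(TRAITS)] > 0).all().all()


def test_missingness_rate_close_to_config(small_config, small_cohorts):
    cohorts, _ = small_cohorts
    frac = float(cohorts[0].dosages.isna().to_numpy().mean())
    assert frac == pytest.approx(small_config.missing_rate, abs=0.005)


def test_unachievable_case_counts_raise_sampling_error():
    cfg = L.SimulationConfig(
        n_snps_full={"HDL": 2, "LDL": 2, "TC": 2, "TG": 2},
        n_snps_specific={"HDL": 1, "LDL": 1, "TC": 1, "TG": 1},
        cohort_sizes=[(5000, 10, 0)],
        cohort_names=("A",),
        lipid_cohort=0,
        base_prevalence=0.02,
        max_oversample=3,
        seed=1,
    )
    w = L.simulate_weights(cfg)
    with pytest.raises(L.SamplingError):
        L.simulate_cohorts(cfg, w)


def test_dosage_means_and_realized_r2_at_large_n():
    """At n=50,000 the dosage mean per SNP is 2f (binomial) and the realized
    first-stage R² sits at the configured target."""
    cfg = L.SimulationConfig(
        n_snps_full={"HDL": 4, "LDL": 4, "TC": 12, "TG": 4},
        n_snps_specific={"HDL": 2, "LDL": 2, "TC": 4, "TG": 2},
        trait_r2_target=0.04,
        cohort_sizes=[(5000, 45000, 0)],
        cohort_names=("BIG",),
        lipid_cohort=0,
        base_prevalence=0.12,
        missing_rate=0.0,
        seed=42,
    )
    w = L.simulate_weights(cfg)
    cohorts, truth = L.simulate_cohorts(cfg, w)
    assert truth.realized_r2["TC"] == pytest.approx(0.04, abs=0.01)

    # dosages of unconditionally sampled individuals follow binomial(2, f);
    # use the controls (prevalence is low, selection negligible)
    dos = cohorts[0].dosages
    loci = w.drop_duplicates("snp_id").set_index("snp_id")
    n = len(dos)
    for snp in dos.columns[:8]:
        f = loci.loc[snp, "risk_allele_freq"]
        se = np.sqrt(2 * f * (1 - f) / n)
        assert abs(dos[snp].mean() - 2 * f) < 4 * se


def test_null_model_per_snp_log_ors_centred_on_zero():
    """With no causal effect and no pleiotropy, per-SNP disease log ORs are
    centred on zero and ~5% reach p<0.05 (checked over 500+ SNPs)."""
    cfg = L.SimulationConfig(
        n_snps_full={"HDL": 260, "LDL": 250, "TC": 2, "TG": 2},
        n_snps_specific={"HDL": 255, "LDL": 245, "TC": 1, "TG": 1},
        trait_r2_target=0.02,
        cohort_sizes=[(600, 600, 0)],
        cohort_names=("A",),
        lipid_cohort=0,
        missing_rate=0.0,
        seed=5,
    )
    w = L.simulate_weights(cfg)
    cohorts, _ = L.simulate_cohorts(cfg, w)
    ests = L.per_snp_associations(
        cohorts[0].phenotypes["status"].to_numpy(), cohorts[0].dosages
    )
    ok = [e for e in ests if e.ok]
    assert len(ok) >= 500
    log_ors = np.array([e.coefficient for e in ok])
    ses = np.array([e.se for e in ok])
    # mean z-score within 4/sqrt(k) of zero
    z = log_ors / ses
    assert abs(z.mean()) < 4 / np.sqrt(len(ok))
    sig = np.mean([e.p_value < 0.05 for e in ok])
    # binomial 95% band around 0.05 for k SNPs
    assert abs(sig - 0.05) < 2.5 * np.sqrt(0.05 * 0.95 / len(ok))


def test_roundtrip_io(tmp_path, small_config, small_weights, small_cohorts):
    cohorts, truth = small_cohorts
    L.synthetic_data.write_cohort(cohorts[1], tmp_path / "B", small_weights)
    back = L.synthetic_data.read_cohort(tmp_path / "B")
    assert list(back.dosages.columns) == list(cohorts[1].dosages.columns)
    np.testing.assert_allclose(
        back.dosages.to_numpy(), cohorts[1].dosages.to_numpy(), atol=1e-6
    )
    assert back.phenotypes["status"].equals(cohorts[1].phenotypes["status"])

    L.synthetic_data.write_weights(small_weights, tmp_path / "w.csv")
    w = L.synthetic_data.read_weights(tmp_path / "w.csv")
    assert w["snp_id"].equals(small_weights["snp_id"])
    np.testing.assert_allclose(w["beta"], small_weights["beta"], rtol=1e-9)

    L.synthetic_data.write_truth(truth, tmp_path / "truth.txt")
    text = (tmp_path / "truth.txt").read_text()
    assert "realized_r2.TC=" in text
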