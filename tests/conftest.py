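import pytest

import lipidmr as L


@pytest.fixture(scope="session")
def small_config():
    """Compact two-cohort study used across module tests."""
    return L.SimulationConfig(
        n_snps_full={"HDL": 8, "LDL": 6, "TC": 8, "TG": 5},
        n_snps_specific={"HDL": 4, "LDL": 2, "TC": 2, "TG": 2},
        trait_r2_target=0.04,
        cohort_sizes=[(400, 300, 200), (300, 250, 0)],
        cohort_names=("A", "B"),
        lipid_cohort=1,
        lipid_subset_fraction=0.9,
        n_mci=60,
        missing_rate=0.01,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_weights(small_config):
    return L.simulate_weights(small_config)


@pytest.fixture(scope="session")
def small_cohorts(small_config, small_weights):
    return L.simulate_cohorts(small_config, small_weights)


def single_cohort_config(seed, causal=0.0, trait="TC", **overrides):
    """One-cohort design with a strong TC instrument, for IV replicate suites."""
    causal_map = {t: 0.0 for t in L.synthetic_data.TRAITS}
    causal_map[trait] = causal
    kw = dict(
        n_snps_full={"HDL": 4, "LDL": 4, "TC": 20, "TG": 4},
        n_snps_specific={"HDL": 2, "LDL": 2, "TC": 6, "TG": 2},
        trait_r2_target=0.04,
        causal_log_or_per_unit=causal_map,
        cohort_sizes=[(1000, 1000, 0)],
        cohort_names=("A",),
        lipid_cohort=0,
        lipid_subset_fraction=0.5,
        n_mci=2500,
        missing_rate=0.01,
        seed=seed,
    )
    kw.update(overrides)
    return L.SimulationConfig(**kw)


def ratio_iv_replicate(seed, causal=0.0, trait="TC", **overrides):
    """Simulate one cohort and run the full ratio-IV path for one trait."""
    cfg = single_cohort_config(seed, causal, trait, **overrides)
    w = L.simulate_weights(cfg)
    cohorts, _ = L.simulate_cohorts(cfg, w)
    c = cohorts[0]
    panel = L.LipidPanel(
        values=c.phenotypes[[trait]], age=c.phenotypes["age"], sex=c.phenotypes["sex"]
    )
    transformed = L.phenotypes.transform_panel(panel).values[trait]
    scores = L.compute_grs(c.dosages, w, trait, "full")
    stage1 = L.first_stage(transformed.to_numpy(), scores["standardized"].to_numpy())
    stage2 = L.second_stage(
        c.phenotypes["status"].to_numpy(), scores["standardized"].to_numpy()
    )
    return L.ratio_iv(stage2, stage1, allow_weak=True)
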