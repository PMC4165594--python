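"""Risk-allele orientation and weighted-score construction."""

import numpy as np
import pandas as pd
import pytest

import lipidmr as L


def _weights(rows):
    return pd.DataFrame(
        rows,
        columns=["snp_id", "trait", "risk_allele", "other_allele", "beta",
                 "se_beta", "trait_specific"],
    )


class TestOrientWeights:
    def test_negative_raising_trait_beta_flips_alleles(self):
        w = _weights([("rs1", "LDL", "A", "G", -0.1, 0.01, True)])
        out = L.orient_weights(w)
        assert out.loc[0, "risk_allele"] == "G"
        assert out.loc[0, "other_allele"] == "A"
        assert out.loc[0, "beta"] == pytest.approx(0.1)

    def test_hdl_raising_allele_flipped_to_lowering(self):
        w = _weights([("rs2", "HDL", "C", "T", +0.2, 0.01, False)])
        out = L.orient_weights(w)
        assert out.loc[0, "risk_allele"] == "T"
        assert out.loc[0, "beta"] == pytest.approx(0.2)

    def test_oriented_table_is_fixed_point(self):
        w = _weights([
            ("rs1", "LDL", "A", "G", 0.1, 0.01, True),
            ("rs2", "HDL", "C", "T", -0.2, 0.01, False),
        ])
        once = L.orient_weights(w)
        twice = L.orient_weights(once)
        pd.testing.assert_frame_equal(once, twice)
        assert (once["beta"] > 0).all()

    def test_zero_beta_rejected(self):
        w = _weights([("rs1", "TC", "A", "G", 0.0, 0.01, True)])
        with pytest.raises(L.ValidationError):
            L.orient_weights(w)

    def test_duplicate_snp_trait_rejected(self):
        w = _weights([
            ("rs1", "TC", "A", "G", 0.1, 0.01, True),
            ("rs1", "TC", "C", "T", 0.2, 0.01, True),
        ])
        with pytest.raises(L.ValidationError):
            L.orient_weights(w)


def test_select_weights_drops_flagged_exclusions():
    w = pd.DataFrame({
        "snp_id": ["rs1", "rs2"], "trait": ["TC", "TC"],
        "risk_allele": ["A", "C"], "other_allele": ["G", "T"],
        "beta": [0.1, 0.2], "se_beta": [0.01, 0.01],
        "trait_specific": [True, False],
        "excluded": [False, True], "reason": ["", "APOE-region"],
    })
    sub = L.select_weights(w, "TC", "full")
    assert sub["snp_id"].tolist() == ["rs1"]


class TestComputeGRS:
    def test_single_snp_score(self):
        w = _weights([("rs1", "TC", "A", "G", 0.5, 0.01, False)])
        dos = pd.DataFrame({"rs1": [2.0]}, index=["i1"])
        out = L.compute_grs(dos, w)
        assert out.loc["i1", "raw"] == pytest.approx(1.0)

    def test_missing_snp_shrinks_denominator(self):
        # score per NON-MISSING SNP: (0.5*2)/1, not /2
        w = _weights([
            ("rs1", "TC", "A", "G", 0.5, 0.01, False),
            ("rs2", "TC", "C", "T", 0.5, 0.01, False),
        ])
        dos = pd.DataFrame({"rs1": [2.0], "rs2": [np.nan]}, index=["i1"])
        out = L.compute_grs(dos, w, max_missing=0.6)
        assert out.loc["i1", "raw"] == pytest.approx(1.0)

    def test_five_percent_missing_exclusion_is_inclusive(self):
        w = _weights([
            (f"rs{j}", "TC", "A", "G", 0.1, 0.01, False) for j in range(20)
        ])
        rng = np.random.default_rng(0)
        dos = pd.DataFrame(
            rng.integers(0, 3, size=(30, 20)).astype(float),
            columns=[f"rs{j}" for j in range(20)],
        )
        dos.iloc[0, 0] = np.nan  # 1/20 = 5% -> excluded
        out = L.compute_grs(dos, w)
        assert bool(out["excluded"].iloc[0])
        assert np.isnan(out["standardized"].iloc[0])
        assert not out["excluded"].iloc[1:].any()

    def test_raw_score_matches_loop_oracle_on_complete_data(self):
        rng = np.random.default_rng(1)
        betas = np.array([0.2, 0.5, 0.3])
        w = _weights([
            (f"rs{j}", "TC", "A", "G", betas[j], 0.01, False) for j in range(3)
        ])
        dos = pd.DataFrame(
            rng.integers(0, 3, size=(5, 3)).astype(float),
            columns=[f"rs{j}" for j in range(3)],
        )
        out = L.compute_grs(dos, w)
        for i in range(5):
            acc = sum(betas[j] * dos.iloc[i, j] for j in range(3)) / 3
            assert out["raw"].iloc[i] == pytest.approx(acc, abs=1e-12)

    def test_standardization_is_exact_within_cohort(self, small_cohorts, small_weights):
        cohorts, _ = small_cohorts
        for c in cohorts:
            out = L.compute_grs(c.dosages, small_weights, "HDL", "full")
            std = out.loc[~out["excluded"], "standardized"]
            assert abs(std.mean()) < 1e-10
            assert abs(std.std(ddof=0) - 1) < 1e-10

    def test_column_permutation_invariance(self, small_cohorts, small_weights):
        cohorts, _ = small_cohorts
        dos = cohorts[0].dosages
        shuffled = dos[list(dos.columns[::-1])]
        a = L.compute_grs(dos, small_weights, "TC", "full")
        b = L.compute_grs(shuffled, small_weights, "TC", "full")
        pd.testing.assert_frame_equal(a, b)

    def test_doubling_betas_doubles_raw_not_standardized(self, small_cohorts,
                                                         small_weights):
        cohorts, _ = small_cohorts
        wsub = L.select_weights(small_weights, "TC", "full")
        doubled = wsub.assign(beta=wsub["beta"] * 2)
        a = L.compute_grs(cohorts[0].dosages, wsub)
        b = L.compute_grs(cohorts[0].dosages, doubled)
        inc = ~a["excluded"]
        np.testing.assert_allclose(b.loc[inc, "raw"], 2 * a.loc[inc, "raw"])
        np.testing.assert_allclose(
            b.loc[inc, "standardized"], a.loc[inc, "standardized"], atol=1e-10
        )

    def test_weight_snp_absent_from_matrix_warns(self):
        w = _weights([
            ("rs1", "TC", "A", "G", 0.5, 0.01, False),
            ("rs_gone", "TC", "C", "T", 0.5, 0.01, False),
        ])
        dos = pd.DataFrame({"rs1": [1.0, 2.0, 0.0]})
        with pytest.warns(UserWarning, match="absent"):
            out = L.compute_grs(dos, w, max_missing=0.9)
        # the absent SNP counts as missing for everyone
        assert (out["n_missing"] == 1).all()

    def test_all_missing_individual_excluded(self):
        w = _weights([("rs1", "TC", "A", "G", 0.5, 0.01, False)])
        dos = pd.DataFrame({"rs1": [np.nan, 1.0, 2.0]})
        out = L.compute_grs(dos, w)
        assert bool(out["excluded"].iloc[0])
        assert np.isnan(out["raw"].iloc[0])

    def test_out_of_range_dosage_rejected(self):
        w = _weights([("rs1", "TC", "A", "G", 0.5, 0.01, False)])
        dos = pd.DataFrame({"rs1": [2.4]})
        with pytest.raises(L.ValidationError):
            L.compute_grs(dos, w)

    def test_exclusion_is_per_score(self, small_weights):
        """An individual can fail the missingness rule for one trait's score
        while remaining included for another."""
        rng = np.random.default_rng(2)
        tc = L.select_weights(small_weights, "TC", "full")["snp_id"]
        hdl = L.select_weights(small_weights, "HDL", "full")["snp_id"]
        snps = small_weights["snp_id"].drop_duplicates()
        dos = pd.DataFrame(
            rng.integers(0, 3, size=(20, len(snps))).astype(float),
            columns=list(snps),
        )
        only_tc = [s for s in tc if s not in set(hdl)]
        dos.loc[0, only_tc] = np.nan
        out_tc = L.compute_grs(dos, small_weights, "TC", "full")
        out_hdl = L.compute_grs(dos, small_weights, "HDL", "full")
        assert bool(out_tc["excluded"].iloc[0])
        assert not bool(out_hdl["excluded"].iloc[0])
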