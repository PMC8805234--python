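"""Meta-analysis, the MV-vs-MR difference test, pleiotropy and
heterogeneity diagnostics, stratified MR and parental correlations."""

import numpy as np
import pandas as pd
import pytest

from ntmr import (
    EstimateRecord,
    RatioInput,
    SimConfig,
    cochran_q_snps,
    difference_z,
    effect_size_stratified_mr,
    instrument_validity_screen,
    meta_fixed,
    mr_egger,
    mv_mr_difference_test,
    parental_prs_correlation,
    per_snp_wald,
    ratio_estimate,
    ratio_meta,
    score,
    sex_interaction,
    simulate_cohort,
    tsls,
)
from tests.conftest import dosage_frame, true_weight_table


def rec(beta, se, n=100, method="tsls", outcome="y", stratum="s"):
    return EstimateRecord(method=method, outcome=outcome, stratum=stratum,
                          beta=beta, se=se, n=n)


class TestMetaFixed:
    def test_single_record_passthrough(self):
        m = meta_fixed([rec(0.2, 0.05)])
        assert m.pooled_beta == pytest.approx(0.2, abs=1e-14)
        assert m.pooled_se == pytest.approx(0.05, abs=1e-14)
        assert m.q == pytest.approx(0.0, abs=1e-14)
        assert m.df == 0 and m.p_q == 1.0

    def test_stated_arithmetic(self):
        m = meta_fixed([rec(0.1, 0.1), rec(0.3, 0.1)])
        assert m.pooled_beta == pytest.approx(0.2)
        assert m.pooled_se == pytest.approx(0.1 / np.sqrt(2))
        assert m.q == pytest.approx(2.0)
        assert m.i2 == pytest.approx(50.0)

    def test_identical_records_shrink_se(self):
        k = 4
        m = meta_fixed([rec(0.15, 0.08)] * k)
        assert m.pooled_beta == pytest.approx(0.15)
        assert m.pooled_se == pytest.approx(0.08 / np.sqrt(k))
        assert m.q == pytest.approx(0.0, abs=1e-12)

    def test_order_and_split_invariance(self):
        records = [rec(0.1, 0.05), rec(0.25, 0.1), rec(-0.05, 0.2)]
        m1 = meta_fixed(records)
        m2 = meta_fixed(records[::-1])
        assert m1.pooled_beta == pytest.approx(m2.pooled_beta, abs=1e-14)
        # splitting one record into two half-weight records (se * sqrt(2))
        split = records[:2] + [rec(-0.05, 0.2 * np.sqrt(2))] * 2
        m3 = meta_fixed(split)
        assert m3.pooled_beta == pytest.approx(m1.pooled_beta, abs=1e-14)
        assert m3.pooled_se == pytest.approx(m1.pooled_se, abs=1e-14)

    def test_pooled_se_bounded_by_min_member(self):
        m = meta_fixed([rec(0.1, 0.05), rec(0.2, 0.3)])
        assert m.pooled_se <= 0.05

    def test_random_effects_sensitivity(self):
        # homogeneous input: DL reduces to fixed effects
        mf = meta_fixed([rec(0.1, 0.1), rec(0.12, 0.1)])
        md = meta_fixed([rec(0.1, 0.1), rec(0.12, 0.1)], method="dersimonian_laird")
        assert md.pooled_beta == pytest.approx(mf.pooled_beta, abs=1e-12)

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed([])
        with pytest.raises(ValueError):
            EstimateRecord("tsls", "y", "s", 0.1, 0.0, 10)


class TestRatioMeta:
    def test_single_sample_equals_ratio_estimate(self):
        inp = RatioInput(0.05, 0.01, 0.5, 0.02, 100)
        a = ratio_meta([inp])
        b = ratio_estimate(inp)
        assert a.beta == pytest.approx(b.beta, abs=1e-14)
        assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_identical_samples_common_ratio(self):
        inp = RatioInput(0.06, 0.02, 0.3, 0.03, 100)
        m = ratio_meta([inp, inp, inp])
        assert m.beta == pytest.approx(0.2)

    def test_against_stacked_tsls_oracle(self):
        """Pooling per-sample coefficients matches joint TSLS on stacked
        data with sample fixed effects, within the combined SE."""
        samples = []
        for seed in (61, 62, 63):
            cfg = SimConfig(n_trios=1500, n_snps=50, beta_m={"y": 0.1},
                            gamma_p=0.0, seed=seed)
            cohort, pheno = simulate_cohort(cfg)
            sv = score(dosage_frame(cohort, "nt"), true_weight_table(cohort))
            z = (sv.score - sv.score.mean()) / sv.score.std()
            samples.append((pheno, z))
        inputs = []
        for pheno, z in samples:
            zc = z.to_numpy()
            X = np.column_stack([np.ones(len(z)), zc])
            out = {}
            for col in ("y_y", "maternal_bmi"):
                v = pheno[col].to_numpy()
                b, *_ = np.linalg.lstsq(X, v, rcond=None)
                r = v - X @ b
                s2 = r @ r / (len(v) - 2)
                se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
                out[col] = (b[1], se)
            inputs.append(RatioInput(out["y_y"][0], out["y_y"][1],
                                     out["maternal_bmi"][0], out["maternal_bmi"][1],
                                     len(z)))
        pooled = ratio_meta(inputs)
        # stacked TSLS with sample dummies
        pheno_all = pd.concat([p for p, _ in samples], keys=range(3))
        pheno_all.index = [f"i{j}" for j in range(len(pheno_all))]
        z_all = pd.Series(np.concatenate([z.to_numpy() for _, z in samples]),
                          index=pheno_all.index)
        pheno_all["d1"] = np.repeat([1.0, 0.0, 0.0], 1500)
        pheno_all["d2"] = np.repeat([0.0, 1.0, 0.0], 1500)
        joint = tsls(pheno_all, "y_y", z_all, covariates=["d1", "d2"])
        assert pooled.beta == pytest.approx(joint.beta,
                                            abs=np.hypot(pooled.se, joint.se))


class TestDifferenceTest:
    def test_stated_z_arithmetic(self):
        z, p = difference_z(0.3, 0.05**2, 0.1, 0.1**2, 0.002)
        assert z == pytest.approx(0.2 / np.sqrt(0.0085), rel=1e-12)

    def test_identical_estimates_null(self):
        z, p = difference_z(0.2, 0.01, 0.2, 0.02, 0.001)
        assert z == 0.0 and p == 1.0

    def test_negative_variance_raises(self):
        with pytest.raises(ValueError, match="non-positive variance"):
            difference_z(0.3, 0.001, 0.1, 0.001, 0.01)

    def test_bootstrap_covariance_positive_for_shared_sample(self, base_cohort,
                                                             nt_instrument):
        _, _, pheno = base_cohort
        d = mv_mr_difference_test(pheno, "y_y", nt_instrument,
                                  mr_covariates=["pc1", "pc2"],
                                  n_boot=600, seed=3)
        # MV and MR share families, so replicate estimates co-vary positively
        assert d.cov_boot > 0
        assert 0.0 <= d.p <= 1.0
        # confounded MV vs unbiased MR: difference detected at n=5000
        assert d.beta_mv > d.beta_mr

    def test_n_boot_floor(self, base_cohort, nt_instrument):
        _, _, pheno = base_cohort
        with pytest.raises(ValueError, match="n_boot"):
            mv_mr_difference_test(pheno, "y_y", nt_instrument, n_boot=100)


class TestCochranQ:
    def test_identical_ratios_zero_q(self):
        tab = pd.DataFrame(dict(wald=[0.1, 0.1, 0.1], se=[0.05, 0.1, 0.2]))
        q, df, p = cochran_q_snps(tab)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_stated_arithmetic(self):
        tab = pd.DataFrame(dict(wald=[0.0, 0.2], se=[0.1, 0.1]))
        q, df, p = cochran_q_snps(tab)
        assert q == pytest.approx(2.0)
        assert df == 1

    def test_too_few_snps(self):
        with pytest.raises(ValueError):
            cochran_q_snps(pd.DataFrame(dict(wald=[0.1], se=[0.1])))


class TestEgger:
    def test_exact_linear_fixture(self):
        bx = np.array([0.1, 0.2, 0.3])
        tab = pd.DataFrame(dict(beta_zx=bx, beta_zy=0.01 + 0.1 * bx,
                                se_zy=[0.05] * 3))
        res = mr_egger(tab)
        assert res.intercept == pytest.approx(0.01, abs=1e-12)
        assert res.slope == pytest.approx(0.1, abs=1e-12)

    def test_orientation_forced_positive(self):
        bx = np.array([0.1, -0.2, 0.3])
        tab = pd.DataFrame(dict(beta_zx=bx, beta_zy=0.01 * np.sign(bx) + 0.1 * bx,
                                se_zy=[0.05] * 3))
        res = mr_egger(tab)
        assert res.intercept == pytest.approx(0.01, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match=">= 3"):
            mr_egger(pd.DataFrame(dict(beta_zx=[0.1, 0.2], beta_zy=[0, 0],
                                       se_zy=[0.1, 0.1])))
        with pytest.raises(ValueError, match="not identified"):
            mr_egger(pd.DataFrame(dict(beta_zx=[0.1] * 3, beta_zy=[0, 0.1, 0.2],
                                       se_zy=[0.1] * 3)))


class TestScreen:
    def test_self_and_independent_factors(self, base_cohort, nt_instrument):
        _, _, pheno = base_cohort
        rng = np.random.default_rng(7)
        factors = pd.DataFrame(
            dict(self_factor=nt_instrument,
                 noise=rng.normal(size=len(pheno)),
                 const=np.ones(len(pheno))),
            index=pheno.index,
        )
        out = instrument_validity_screen(nt_instrument, factors).set_index("factor")
        assert out.loc["self_factor", "r"] == pytest.approx(1.0)
        assert out.loc["self_factor", "stars"] == "***"
        assert abs(out.loc["noise", "r"]) < 0.04
        assert out.loc["const", "note"] == "constant column skipped"

    def test_confounder_screen_detects_genetic_link(self):
        """Maternal-genotype pleiotropy onto an observed risk factor is
        detectable as an instrument-factor correlation."""
        cfg = SimConfig(n_trios=4000, n_snps=50, beta_m={"y": 0.1}, seed=71)
        cohort, pheno = simulate_cohort(cfg)
        sv = score(dosage_frame(cohort, "maternal"), true_weight_table(cohort))
        factors = pd.DataFrame(dict(linked=0.3 * sv.score.to_numpy()
                                    + np.random.default_rng(71).normal(size=len(pheno))),
                               index=pheno.index)
        out = instrument_validity_screen(sv.score, factors)
        assert out.loc[0, "p"] < 1e-5


class TestStratifiedMr:
    def test_identical_subscores_identical_estimates(self, base_cohort):
        _, cohort, pheno = base_cohort
        dos = dosage_frame(cohort, "nt").iloc[:, :1]
        dup = dos.copy()
        dup["copy"] = dos.iloc[:, 0]
        w0 = abs(float(cohort.snp_meta["weight"].iloc[0]))
        weights = pd.DataFrame(dict(id=[dos.columns[0], "copy"], chrom=[1, 1],
                                    pos=[1, 2], ea=["A", "A"], oa=["G", "G"],
                                    weight=[w0, w0], flip=[False, False]))
        records, trend = effect_size_stratified_mr(weights, dup, pheno, "y_y",
                                                   n_bins=2)
        assert records[0].beta == pytest.approx(records[1].beta, abs=1e-10)

    def test_homogeneous_effects_no_trend(self, base_cohort):
        _, cohort, pheno = base_cohort
        records, trend = effect_size_stratified_mr(
            true_weight_table(cohort), dosage_frame(cohort, "nt"), pheno, "y_y",
            n_bins=3,
        )
        assert len(records) == 3
        assert trend["p"] > 0.01  # no pleiotropy: slope CI covers 0


class TestSexInteraction:
    def test_constant_sex_errors(self, base_cohort):
        _, _, pheno = base_cohort
        ph = pheno.copy()
        ph["child_sex"] = 1.0
        with pytest.raises(ValueError, match="both sexes"):
            sex_interaction(ph, "y_y")

    def test_simulated_interaction_recovered(self):
        cfg = SimConfig(n_trios=8000, n_snps=50, beta_m={"y": 0.1},
                        sex_beta_diff=0.3, seed=72)
        cohort, pheno = simulate_cohort(cfg)
        b, se, p = sex_interaction(pheno, "y_y")
        assert b == pytest.approx(0.3, abs=3 * se)
        assert p < 0.01

    def test_null_interaction(self, base_cohort):
        _, _, pheno = base_cohort
        b, se, p = sex_interaction(pheno, "y_y")
        assert abs(b) < 3 * se


class TestParentalCorrelation:
    def test_identity(self):
        s = pd.Series(np.random.default_rng(8).normal(size=200))
        out = parental_prs_correlation(s, s, s).set_index("pair")
        assert out.loc["full_vs_paternal", "r"] == pytest.approx(1.0)

    def test_random_mating_null(self, base_cohort):
        _, cohort, _ = base_cohort
        t = cohort.truth
        out = parental_prs_correlation(t["prs_nontransmitted"], t["prs_mat"],
                                       t["prs_pat"])
        assert ((out["ci_low"] <= 0) & (out["ci_high"] >= 0)).all()

    def test_assortative_mating_derived_values(self):
        """Under spousal PRS correlation rho, the full maternal score
        correlates with the paternal score at ~rho while the NT score
        (one random haplotype's half) correlates at ~rho/sqrt(2)."""
        cfg = SimConfig(n_trios=8000, n_snps=100, rho_am=0.3, seed=73)
        cohort, _ = simulate_cohort(cfg)
        t = cohort.truth
        out = parental_prs_correlation(t["prs_nontransmitted"], t["prs_mat"],
                                       t["prs_pat"]).set_index("pair")
        assert out.loc["full_vs_paternal", "r"] == pytest.approx(0.3, abs=0.04)
        assert out.loc["nt_vs_paternal", "r"] == pytest.approx(0.3 / np.sqrt(2),
                                                               abs=0.04)

    def test_no_fathers_errors(self):
        s = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError, match="paternal"):
            parental_prs_correlation(s, s, pd.Series(dtype=float))
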