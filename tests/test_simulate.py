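"""The synthetic-cohort generator: determinism, margins, info scores."""

import dataclasses

import numpy as np
import pytest
from scipy import optimize, special

from gwgi.assoc import maf
from gwgi.simulate import (
    SimScenario,
    SimulationError,
    simulate_collection,
    simulate_expression,
    simulate_study,
)


def scenario(**kw):
    base = dict(
        n_cases_per_study=(300, 200),
        n_controls_per_study=(300, 200),
        n_snps=4,
        baseline_prevalence=0.2,
        seed=5,
    )
    base.update(kw)
    return SimScenario(**base)


class TestDeterminism:
    def test_same_seed_identical_collections(self):
        sc = scenario()
        a = simulate_collection(sc)
        b = simulate_collection(sc)
        for ca, cb in zip(a, b):
            assert ca.samples.equals(cb.samples)
            np.testing.assert_array_equal(ca.dosages, cb.dosages)
            assert ca.variants.equals(cb.variants)

    def test_different_seeds_differ(self):
        a = simulate_study(scenario(seed=1), 0)
        b = simulate_study(scenario(seed=2), 0)
        assert not np.array_equal(a.dosages, b.dosages)


class TestBookkeeping:
    def test_nine_study_counts_match_config(self):
        """Consortium-shaped collection (counts scaled 1/100)."""
        cases = (168,) + (9, 9, 9, 9, 9, 9, 9, 10)
        controls = (131,) + (12, 12, 12, 12, 12, 12, 12, 11)
        sc = scenario(n_cases_per_study=cases, n_controls_per_study=controls)
        col = simulate_collection(sc)
        for st, nca, nco in zip(col, cases, controls):
            assert (st.samples["disease"] == "case").sum() == nca
            assert (st.samples["disease"] == "control").sum() == nco
        # shared variant panel
        for st in col[1:]:
            assert list(st.variants["snp_id"]) == list(col[0].variants["snp_id"])

    def test_single_study_collection_rejected(self):
        with pytest.raises(ValueError, match="2 studies"):
            simulate_collection(
                scenario(n_cases_per_study=(100,), n_controls_per_study=(100,))
            )

    def test_study_index_bounds(self):
        with pytest.raises(ValueError, match="out of range"):
            simulate_study(scenario(), 5)

    def test_unattainable_case_count(self):
        """Covariate effects crush the realized prevalence far below nominal."""
        sc = scenario(
            n_cases_per_study=(200, 200),
            smoking_prev_by_sex=(0.999, 0.999),
            beta_smoke=-30.0,
            baseline_prevalence=0.3,
        )
        with pytest.raises(SimulationError, match="cases"):
            simulate_study(sc, 0)


class TestGenotypesAndInfo:
    def test_exact_genotypes_have_unit_info_and_target_maf(self):
        """Noise-free dosages: info exactly 1, Var(dosage) near 2p(1-p)."""
        sc = scenario(
            n_cases_per_study=(2000, 200),
            n_controls_per_study=(2000, 200),
            maf_range=(0.2, 0.2),
            info_noise_sd=0.0,
            beta_smoke=0.0,
            baseline_prevalence=0.3,
        )
        cohort = simulate_study(sc, 0)
        np.testing.assert_array_equal(
            cohort.variants["info_score"].to_numpy(), np.ones(sc.n_snps)
        )
        n = len(cohort.samples)
        se_binom = np.sqrt(0.2 * 0.8 / (2 * n))
        for j in range(sc.n_snps):
            assert maf(cohort.dosages[:, j]) == pytest.approx(0.2, abs=4 * se_binom)
            assert cohort.dosages[:, j].var() == pytest.approx(
                2 * 0.2 * 0.8, rel=0.15
            )

    def test_info_decreases_with_noise(self):
        means = []
        for sd in (0.0, 0.2, 0.4, 0.8):
            sc = scenario(info_noise_sd=sd, n_snps=30)
            cohort = simulate_study(sc, 0)
            means.append(cohort.variants["info_score"].mean())
        assert all(a > b for a, b in zip(means, means[1:]))
        assert all(0.0 <= m <= 1.0 for m in means)

    def test_pooled_maf_matches_allele_count_average(self):
        """Per-study estimates pool (by allele counts) to the global MAF."""
        sc = scenario(
            n_cases_per_study=(500, 400, 300),
            n_controls_per_study=(500, 400, 300),
            maf_range=(0.3, 0.3),
            info_noise_sd=0.0,
            baseline_prevalence=0.3,
        )
        col = simulate_collection(sc)
        counts = sum(float(c.dosages[:, 0].sum()) for c in col)
        total = sum(2 * len(c.samples) for c in col)
        pooled_oracle = counts / total
        all_d = np.concatenate([c.dosages[:, 0] for c in col])
        assert maf(all_d) == pytest.approx(min(pooled_oracle, 1 - pooled_oracle))
        se = np.sqrt(0.3 * 0.7 / total)
        assert pooled_oracle == pytest.approx(0.3, abs=4 * se)

    def test_sex_differential_maf(self):
        sc = scenario(
            n_cases_per_study=(3000, 200),
            n_controls_per_study=(3000, 200),
            maf_range=(0.25, 0.25),
            maf_sex_delta=0.1,
            info_noise_sd=0.0,
            baseline_prevalence=0.3,
        )
        cohort = simulate_study(sc, 0)
        female = (cohort.samples["sex"] == "female").to_numpy()
        f_f = cohort.dosages[female, 0].mean() / 2
        f_m = cohort.dosages[~female, 0].mean() / 2
        assert f_f - f_m == pytest.approx(0.1, abs=0.03)


class TestCaseMargins:
    def test_male_fraction_among_cases_tuned_to_consortium(self):
        """With beta_sex solved analytically for a 60.4% male case fraction,
        the realized fraction lands within Monte-Carlo error of 0.604."""
        target = 0.604
        prev, b_smoke = 0.1, 1.5
        smoke_m, smoke_f = 0.87, 0.73
        frac_f = 0.40
        b0 = special.logit(prev)

        def p_case_male():
            return smoke_m * special.expit(b0 + b_smoke) + (1 - smoke_m) * special.expit(b0)

        def p_case_female(bs):
            return smoke_f * special.expit(b0 + b_smoke + bs) + (
                1 - smoke_f
            ) * special.expit(b0 + bs)

        def male_case_frac(bs):
            num = (1 - frac_f) * p_case_male()
            return num / (num + frac_f * p_case_female(bs))

        beta_sex = optimize.brentq(lambda b: male_case_frac(b) - target, -2, 2)
        sc = scenario(
            n_cases_per_study=(4000, 200),
            n_controls_per_study=(1000, 200),
            baseline_prevalence=prev,
            beta_sex=beta_sex,
            seed=17,
        )
        fracs = []
        for s in range(8):
            cohort = simulate_study(dataclasses.replace(sc, seed=100 + s), 0)
            cases = cohort.samples[cohort.samples["disease"] == "case"]
            fracs.append((cases["sex"] == "male").mean())
        mc_se = np.sqrt(target * (1 - target) / (8 * 4000))
        assert np.mean(fracs) == pytest.approx(target, abs=2 * mc_se + 1e-9)

    def test_smoking_and_sex_margins_converge(self):
        sc = scenario(
            n_cases_per_study=(5000, 200),
            n_controls_per_study=(5000, 200),
            beta_smoke=0.0,
            beta_sex=0.0,
            baseline_prevalence=0.3,
        )
        cohort = simulate_study(sc, 0)
        s = cohort.samples
        n = len(s)
        for value, expected in [
            ((s["sex"] == "female").mean(), 0.40),
            ((s.loc[s.sex == "male", "smoking"] == "ever").mean(), 0.87),
            ((s.loc[s.sex == "female", "smoking"] == "ever").mean(), 0.73),
        ]:
            se = np.sqrt(expected * (1 - expected) / n)
            assert value == pytest.approx(expected, abs=4 * se)


class TestSimulateExpression:
    def test_noiseless_arithmetic(self):
        codes = np.array([0.0, 1.0, 1.0, 0.0])
        sex = np.array(["male", "female", "male", "female"])
        es = simulate_expression(codes, sex, 0.0, 1.0, 1.0, 0.0, seed=0)
        female_carrier = es.samples[
            (es.samples["sex"] == "female") & (es.samples["genotype_code"] == 1)
        ]
        assert (female_carrier["log2_expr"] == 2.0).all()

    def test_all_missing_codes_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            simulate_expression(
                np.array([np.nan, np.nan]), np.array(["male", "female"]),
                0.1, 0.1, 1.0, 0.1, seed=0,
            )

    def test_low_expression_dropped_and_counted(self):
        codes = np.zeros(50)
        sex = np.repeat("male", 50)
        es = simulate_expression(codes, sex, 0.0, 0.0, -2.0, 0.5, seed=3)
        # base log2 = -2 => rpkm 0.25 at the boundary; noise pushes some below
        assert es.n_dropped_low_expr > 0
        assert len(es.samples) + es.n_dropped_low_expr == 50
        assert (2.0 ** es.samples["log2_expr"] >= 0.25).all()

    def test_deterministic(self):
        codes = np.tile([0.0, 1.0, 2.0], 30)
        sex = np.tile(["male", "female"], 45)
        a = simulate_expression(codes, sex, -0.5, 0.5, 1.0, 0.3, seed=9)
        b = simulate_expression(codes, sex, -0.5, 0.5, 1.0, 0.3, seed=9)
        assert a.samples.equals(b.samples)
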