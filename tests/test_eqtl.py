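"""Dosage coding, expression preparation, group tests, interaction GLM, LD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwgi.assoc import NotEstimable
from gwgi.eqtl import (
    RegionZTable,
    code_dosages,
    dosage_to_genotype,
    expression_interaction,
    group_expression_test,
    ld_r2,
    prepare_expression,
    region_z_comparison,
)
from gwgi.simulate import simulate_expression


class TestDosageCoding:
    @pytest.mark.parametrize(
        "dosage,maf,expected",
        [
            # additive rule (MAF >= 0.1)
            (0.15, 0.2, 0.0),
            (0.2, 0.2, 0.0),
            (0.4, 0.2, 1.0),
            (0.5, 0.2, 1.0),
            (0.6, 0.2, 1.0),
            (0.8, 0.2, 2.0),
            (2.0, 0.2, 2.0),
            (0.3, 0.2, np.nan),
            (0.7, 0.2, np.nan),
            # dominant rule (MAF < 0.1)
            (0.15, 0.04, 0.0),
            (0.4, 0.04, 0.0),
            (0.6, 0.04, 1.0),
            (0.7, 0.04, 1.0),
            (2.0, 0.04, 1.0),
            (0.5, 0.04, np.nan),
        ],
    )
    def test_threshold_rules(self, dosage, maf, expected):
        got = dosage_to_genotype(dosage, maf)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_hard_genotype_dosages(self):
        """Exact 0/2 dosages keep their codes under the additive rule;
        under the dominant rule both 1 and 2 collapse to carrier."""
        np.testing.assert_array_equal(code_dosages([0.0, 2.0], maf=0.3), [0.0, 2.0])
        np.testing.assert_array_equal(
            code_dosages([0.0, 1.0, 2.0], maf=0.05), [0.0, 1.0, 1.0]
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="outside"):
            dosage_to_genotype(2.3, 0.2)
        with pytest.raises(ValueError, match="MAF"):
            dosage_to_genotype(1.0, 0.0)
        with pytest.raises(ValueError):
            code_dosages([0.5, 2.4], 0.2)


def rpkm_frame(values, gene="CXADR", sample_ids=None, sex=None):
    n = len(values)
    frame = pd.DataFrame(
        {
            "sample_id": sample_ids or [f"s{i}" for i in range(n)],
            "gene": gene,
            "rpkm": values,
        }
    )
    if sex is not None:
        frame["sex"] = sex
    return frame


class TestPrepareExpression:
    def test_duplicates_averaged_before_filter(self):
        """A duplicate pair (0.2, 0.4) averages to 0.3 and is retained."""
        frame = rpkm_frame([0.2, 0.4, 4.0], sample_ids=["a", "a", "b"])
        es = prepare_expression(frame, "CXADR")
        assert es.n_duplicates_averaged == 1
        assert es.n_dropped_low_expr == 0
        got = dict(zip(es.samples["sample_id"], es.samples["log2_expr"]))
        assert got["a"] == pytest.approx(np.log2(0.3))
        assert got["b"] == pytest.approx(2.0)

    def test_duplicate_average_on_rpkm_scale(self):
        frame = rpkm_frame([1.0, 3.0], sample_ids=["a", "a"])
        es = prepare_expression(frame, "CXADR")
        assert es.samples["log2_expr"].iloc[0] == pytest.approx(1.0)  # log2(2.0)

    def test_low_expression_dropped_and_counted(self):
        frame = rpkm_frame([0.2, 4.0])
        es = prepare_expression(frame, "CXADR")
        assert es.n_dropped_low_expr == 1
        assert list(es.samples["sample_id"]) == ["s1"]

    def test_absent_gene_and_empty_result(self):
        frame = rpkm_frame([1.0])
        with pytest.raises(ValueError, match="absent"):
            prepare_expression(frame, "OTHER")
        with pytest.raises(ValueError, match="filtered"):
            prepare_expression(rpkm_frame([0.1, 0.2]), "CXADR")

    def test_genotype_and_sex_merged(self):
        frame = rpkm_frame([1.0, 2.0], sex=["male", "female"])
        es = prepare_expression(
            frame, "CXADR", genotype_code=pd.Series({"s0": 0.0, "s1": 1.0})
        )
        assert list(es.samples["genotype_code"]) == [0.0, 1.0]
        assert list(es.samples["sex"]) == ["male", "female"]


class TestGroupExpressionTest:
    def test_matches_textbook_t_formula(self, rng):
        g0 = rng.normal(1.0, 0.6, 10)
        g1 = rng.normal(1.5, 0.6, 10)
        es = simulate_expression(
            np.r_[np.zeros(10), np.ones(10)],
            np.repeat("male", 20), 0, 0, 0, 0.0, seed=0,
        )
        es.samples["log2_expr"] = np.r_[g0, g1]
        out = group_expression_test(es, strata=("combined",))["combined"]
        sp = ((9 * g0.var(ddof=1) + 9 * g1.var(ddof=1)) / 18) ** 0.5
        t = (g1.mean() - g0.mean()) / (sp * np.sqrt(1 / 10 + 1 / 10))
        p = 2 * stats.t.sf(abs(t), df=18)
        assert out["t"] == pytest.approx(t, rel=1e-10)
        assert out["p"] == pytest.approx(p, rel=1e-10)
        assert out["n"] == (10, 10)

    def test_single_carrier_stratum_not_estimable(self):
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "sex": ["female"] * 3 + ["male"] * 3,
                "genotype_code": [0, 0, 1, 0, 1, 1],
                "log2_expr": [1.0, 1.2, 2.0, 0.9, 1.8, 2.1],
            }
        )
        from gwgi.simulate import ExpressionSet

        es = ExpressionSet(samples, "CXADR", 0, 0)
        out = group_expression_test(es)
        assert isinstance(out["female"], NotEstimable)
        assert isinstance(out["male"], dict) or isinstance(out["male"], NotEstimable)

    def test_dominant_groups_are_zero_vs_one(self):
        es = simulate_expression(
            np.r_[np.zeros(20), np.ones(20)],
            np.tile(["male", "female"], 20), 0.5, 0.5, 1.0, 0.1, seed=4,
        )
        out = group_expression_test(es, strata=("combined",))["combined"]
        assert out["means"][1] > out["means"][0]


class TestExpressionInteraction:
    def test_sex_coding_invariance(self):
        es = simulate_expression(
            np.tile([0.0, 1.0, 2.0], 40),
            np.tile(["male", "female"], 60),
            -0.3, 0.3, 1.0, 0.4, seed=6,
        )
        r1 = expression_interaction(es)
        es2 = ExpressionSetWithNumericSex(es)
        r2 = expression_interaction(es2)
        assert r1.beta == pytest.approx(r2.beta, abs=1e-10)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_p_decreases_as_noise_vanishes(self):
        ps = []
        for sd in (0.8, 0.3, 0.05):
            es = simulate_expression(
                np.tile([0.0, 1.0], 50),
                np.repeat(["male", "female"], 50),
                -0.2, 0.2, 1.0, sd, seed=12,
            )
            ps.append(expression_interaction(es).p)
        assert ps[0] > ps[1] > ps[2]

    def test_requires_both_sexes_and_variation(self):
        es = simulate_expression(
            np.tile([0.0, 1.0], 10), np.repeat("male", 20), 0, 0, 1.0, 0.2, seed=1
        )
        with pytest.raises(ValueError, match="sexes"):
            expression_interaction(es)


def ExpressionSetWithNumericSex(es):
    from gwgi.simulate import ExpressionSet

    s = es.samples.copy()
    s["sex"] = np.where(s["sex"] == "female", 2.0, 1.0)
    return ExpressionSet(s, es.gene, 0, 0)


class TestLdR2:
    def test_identical_vectors(self):
        d = np.array([0.0, 1.0, 2.0, 0.0, 1.0])
        assert ld_r2(d, d) == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # r = 1.75/2.75 = 7/11, r2 = 49/121
        assert ld_r2([0, 1, 2, 0], [0, 2, 1, 0]) == pytest.approx(49 / 121, rel=1e-12)

    def test_independent_snps_near_zero(self, rng):
        a = rng.binomial(2, 0.3, 2000).astype(float)
        b = rng.binomial(2, 0.3, 2000).astype(float)
        assert ld_r2(a, b) < 0.01

    def test_errors(self):
        with pytest.raises(ValueError):
            ld_r2([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            ld_r2([0.0, 1.0], [0.0, 1.0])


class TestRegionZ:
    def make_records(self, n=4):
        from gwgi.meta import fixed_effect_meta
        from gwgi.scan import ScanRecord

        recs = []
        for j in range(n):
            m = fixed_effect_meta([(0.2 + 0.1 * j, 0.1)])
            recs.append(
                ScanRecord(
                    snp_id=f"snp{j}", chrom="21", pos=1000 - j, maf=0.1,
                    passed_info=True, meta=m,
                )
            )
        return recs

    def test_reference_row_has_unit_r2_and_sorted_positions(self, rng):
        recs = self.make_records()
        base = rng.binomial(2, 0.3, 500).astype(float)
        dosages = pd.DataFrame(
            {
                "snp0": base,
                "snp1": base,
                "snp2": rng.binomial(2, 0.3, 500).astype(float),
                "snp3": rng.binomial(2, 0.4, 500).astype(float),
            }
        )
        expr = {
            f"snp{j}": type("R", (), {"z": 0.5 * j})() for j in range(4)
        }
        out = region_z_comparison(recs, expr, "snp0", dosages)
        assert isinstance(out, RegionZTable)
        row = out.table.set_index("snp_id").loc["snp0"]
        assert row["ld_r2_with_reference"] == pytest.approx(1.0)
        assert list(out.table["pos"]) == sorted(out.table["pos"])
        r2_linked = out.table.set_index("snp_id").loc["snp1", "ld_r2_with_reference"]
        assert r2_linked == pytest.approx(1.0)

    def test_missing_reference_rejected(self, rng):
        recs = self.make_records()
        dosages = pd.DataFrame({"snp0": rng.binomial(2, 0.3, 100).astype(float)})
        with pytest.raises(ValueError, match="reference"):
            region_z_comparison(recs, {}, "absent", dosages)
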