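"""cis-eQTL scan: candidate-pair windows, the nominal regression against a
normal-equations oracle, BH-FDR flags, condition classification, the Welch
effect-size comparison and genotype-stratified summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ermotifs.eqtl import (
    ExpressionMatrix,
    GenotypeMatrix,
    cis_pairs,
    classify_conditions,
    condition_gene_sets,
    effect_size_difference,
    effect_size_table,
    fdr_adjust,
    genotype_summaries,
    nominal_scan,
)


def make_cohort(dosages_by_variant, expr_by_gene, condition="control"):
    samples = [f"S{i}" for i in range(len(next(iter(dosages_by_variant.values()))))]
    gm = GenotypeMatrix(
        pd.DataFrame(
            {s: [d[i] for d in dosages_by_variant.values()]
             for i, s in enumerate(samples)},
            index=list(dosages_by_variant),
        ),
        pd.DataFrame(
            {"chrom": "c", "pos": 1, "ref": "A", "alt": "G"},
            index=list(dosages_by_variant),
        ),
    )
    em = ExpressionMatrix(
        pd.DataFrame(
            {s: [e[i] for e in expr_by_gene.values()]
             for i, s in enumerate(samples)},
            index=list(expr_by_gene),
        ),
        condition,
        pd.DataFrame({"chrom": "c", "tss": 1, "strand": "+"},
                     index=list(expr_by_gene)),
    )
    return gm, em


def ols_oracle(d, e):
    """Independent least-squares fit via explicit normal equations."""
    X = np.column_stack([np.ones_like(d), d])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ e)
    resid = e - X @ beta
    n = d.size
    sigma2 = resid @ resid / (n - 2)
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return beta[1], se, p


class TestCisPairs:
    GENES = pd.DataFrame(
        [{"gene_id": "G1", "chrom": "c", "tss": 2_000_000}]
    )

    def variants(self, positions):
        return pd.DataFrame(
            {
                "variant_id": [f"v{p}" for p in positions],
                "chrom": "c",
                "pos": positions,
            }
        )

    def test_boundary_closed_at_window(self):
        pairs = cis_pairs(self.GENES, self.variants([1_000_000]), 1_000_000)
        assert len(pairs) == 1

    def test_one_past_window_excluded(self):
        pairs = cis_pairs(self.GENES, self.variants([999_999]), 1_000_000)
        assert pairs.empty

    def test_other_chromosome_excluded(self):
        v = self.variants([2_000_000])
        v["chrom"] = "other"
        assert cis_pairs(self.GENES, v, 1_000_000).empty

    def test_toy_annotation_hand_enumeration(self):
        genes = pd.DataFrame(
            [
                {"gene_id": "G1", "chrom": "c1", "tss": 100},
                {"gene_id": "G2", "chrom": "c1", "tss": 500},
                {"gene_id": "G3", "chrom": "c2", "tss": 50},
            ]
        )
        variants = pd.DataFrame(
            {
                "variant_id": ["v1", "v2", "v3", "v4", "v5"],
                "chrom": ["c1", "c1", "c1", "c2", "c2"],
                "pos": [90, 350, 720, 40, 400],
            }
        )
        pairs = cis_pairs(genes, variants, 250)
        got = set(zip(pairs["gene_id"], pairs["variant_id"]))
        assert got == {
            ("G1", "v1"), ("G1", "v2"), ("G2", "v2"), ("G2", "v3"),
            ("G3", "v4"),
        }


class TestNominalScan:
    def test_perfect_fit_flagged(self):
        gm, em = make_cohort(
            {"v": [0, 1, 1, 2]}, {"g": [0.0, 2.0, 2.0, 4.0]}
        )
        pairs = pd.DataFrame({"gene_id": ["g"], "variant_id": ["v"]})
        out = nominal_scan(pairs, gm, em)
        row = out.iloc[0]
        assert row["perfect_fit"]
        assert row["slope"] == pytest.approx(2.0)
        assert row["p_nominal"] == 0.0

    def test_constant_genotype_skipped_with_reason(self):
        gm, em = make_cohort({"v": [1, 1, 1, 1]}, {"g": [0.0, 1.0, 2.0, 3.0]})
        pairs = pd.DataFrame({"gene_id": ["g"], "variant_id": ["v"]})
        out = nominal_scan(pairs, gm, em)
        assert out.empty
        assert out.attrs["skipped"]["reason"].iloc[0] == "constant_genotype"

    def test_missing_genotypes_complete_case(self):
        gm, em = make_cohort(
            {"v": [0, np.nan, 1, 2, 1, 0]},
            {"g": [0.1, 9.9, 1.2, 2.1, 0.8, 0.2]},
        )
        pairs = pd.DataFrame({"gene_id": ["g"], "variant_id": ["v"]})
        out = nominal_scan(pairs, gm, em)
        assert out["n"].iloc[0] == 5
        d = np.array([0, 1, 2, 1, 0], dtype=float)
        e = np.array([0.1, 1.2, 2.1, 0.8, 0.2])
        slope, se, p = ols_oracle(d, e)
        assert out["slope"].iloc[0] == pytest.approx(slope, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        d = rng.integers(0, 3, n).astype(float)
        if d.std() == 0:
            d[0] = (d[0] + 1) % 3
        e = 0.3 * d + rng.normal(size=n)
        gm, em = make_cohort({"v": d}, {"g": e})
        pairs = pd.DataFrame({"gene_id": ["g"], "variant_id": ["v"]})
        out = nominal_scan(pairs, gm, em).iloc[0]
        slope, se, p = ols_oracle(d, e)
        assert out["slope"] == pytest.approx(slope, abs=1e-10)
        assert out["se"] == pytest.approx(se, abs=1e-10)
        assert out["p_nominal"] == pytest.approx(p, abs=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(123)
        n, m = 110, 800
        dosages = {f"v{i}": rng.binomial(2, 0.3, n).astype(float) for i in range(m)}
        expr = {"g": rng.normal(size=n)}
        gm, em = make_cohort(dosages, expr)
        pairs = pd.DataFrame(
            {"gene_id": "g", "variant_id": list(dosages)}
        )
        out = nominal_scan(pairs, gm, em)
        assert stats.kstest(out["p_nominal"], "uniform").pvalue > 0.01


class TestFdr:
    def test_single_pvalue_unchanged(self):
        assoc = pd.DataFrame(
            {"variant_id": ["v"], "gene_id": ["g"], "condition": "c",
             "n": [10], "slope": [1.0], "se": [0.1], "r": [0.5],
             "p_nominal": [0.01], "perfect_fit": [False]}
        )
        out = fdr_adjust(assoc, 0.05)
        assert out["p_adj"].iloc[0] == pytest.approx(0.01)

    def test_bh_step_up_by_hand(self):
        assoc = pd.DataFrame(
            {"variant_id": list("abc"), "gene_id": "g", "condition": "c",
             "n": 10, "slope": 1.0, "se": 0.1, "r": 0.5,
             "p_nominal": [0.001, 0.002, 0.009], "perfect_fit": False}
        )
        out = fdr_adjust(assoc)
        assert np.allclose(out["p_adj"], [0.003, 0.003, 0.009])

    def test_adjusted_never_below_nominal(self):
        rng = np.random.default_rng(0)
        assoc = pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(50)], "gene_id": "g",
             "condition": "c", "n": 10, "slope": 1.0, "se": 0.1, "r": 0.5,
             "p_nominal": rng.random(50), "perfect_fit": False}
        )
        out = fdr_adjust(assoc)
        assert (out["p_adj"] >= out["p_nominal"] - 1e-15).all()

    def test_lowering_alpha_never_adds_flags(self):
        rng = np.random.default_rng(1)
        assoc = pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(100)], "gene_id": "g",
             "condition": "c", "n": 10, "slope": 1.0, "se": 0.1, "r": 0.5,
             "p_nominal": rng.random(100) ** 3, "perfect_fit": False}
        )
        prev = None
        for alpha in (0.2, 0.05, 0.01, 0.001):
            flagged = set(fdr_adjust(assoc, alpha).query("significant")["variant_id"])
            if prev is not None:
                assert flagged <= prev
            prev = flagged


class TestClassification:
    def assoc(self, sig_pairs, all_pairs, condition):
        rows = []
        for vid, gid in all_pairs:
            sig = (vid, gid) in sig_pairs
            rows.append(
                {"variant_id": vid, "gene_id": gid, "condition": condition,
                 "n": 10, "slope": 1.0, "se": 0.1, "r": 0.5,
                 "p_nominal": 1e-9 if sig else 0.9,
                 "p_adj": 1e-8 if sig else 0.95,
                 "significant": sig, "perfect_fit": False}
            )
        return pd.DataFrame(rows)

    PAIRS = [("v1", "g1"), ("v2", "g2"), ("v3", "g3")]

    def test_tm_only_and_shared(self):
        a = self.assoc({("v1", "g1")}, self.PAIRS, "control")
        b = self.assoc({("v1", "g1"), ("v2", "g2")}, self.PAIRS, "tm")
        out = classify_conditions(a, b, 0.001).set_index("variant_id")["class"]
        assert out["v1"] == "shared"
        assert out["v2"] == "tm_only"
        assert out["v3"] == "neither"

    def test_identical_inputs_all_shared(self):
        a = self.assoc({("v1", "g1")}, self.PAIRS, "control")
        out = classify_conditions(a, a.assign(condition="tm"), 0.001)
        assert (out.query("`class` != 'neither'")["class"] == "shared").all()

    def test_swap_symmetry(self):
        a = self.assoc({("v1", "g1")}, self.PAIRS, "control")
        b = self.assoc({("v2", "g2")}, self.PAIRS, "tm")
        fwd = classify_conditions(a, b).set_index("variant_id")["class"]
        rev = classify_conditions(b, a).set_index("variant_id")["class"]
        swap = {"control_only": "tm_only", "tm_only": "control_only"}
        for v in fwd.index:
            assert rev[v] == swap.get(fwd[v], fwd[v])

    def test_mismatched_universes_rejected(self):
        a = self.assoc(set(), self.PAIRS, "control")
        b = self.assoc(set(), self.PAIRS[:2], "tm")
        with pytest.raises(ValueError, match="universes differ"):
            classify_conditions(a, b)

    def test_gene_sets(self):
        a = self.assoc({("v1", "g1")}, self.PAIRS, "control")
        b = self.assoc({("v2", "g2")}, self.PAIRS, "tm")
        sets = condition_gene_sets(classify_conditions(a, b))
        assert sets["control_only"] == {"g1"}
        assert sets["tm_only"] == {"g2"}


class TestEffectSize:
    def test_identical_slopes_not_significant(self):
        out = effect_size_difference(1.0, 0.1, 100, 1.0, 0.1, 100)
        assert out["difference"] == 0.0
        assert not out["significant"]

    def test_normal_limit_arithmetic(self):
        # slopes 1 vs 0, both se 0.1, large df: CI = 1 +- 1.645*0.1414
        out = effect_size_difference(1.0, 0.1, 1000, 0.0, 0.1, 1000)
        lo, hi = out["ci"]
        assert lo == pytest.approx(1 - 1.6449 * np.sqrt(0.02), abs=1e-3)
        assert hi == pytest.approx(1 + 1.6449 * np.sqrt(0.02), abs=1e-3)
        assert out["significant"]

    def test_degenerate_se_flagged_not_tested(self):
        out = effect_size_difference(1.0, 0.0, 10, 0.5, 0.1, 10)
        assert out["degenerate"] and not out["significant"]

    def test_null_flag_rate_near_ten_percent(self):
        """Equal true slopes in both conditions: ~10% flagged at 90%."""
        rng = np.random.default_rng(42)
        n, reps = 110, 400
        flags = 0
        for _ in range(reps):
            d = rng.binomial(2, 0.3, n).astype(float)
            y1 = d + rng.normal(0, 0.5, n)
            y2 = d + rng.normal(0, 0.5, n)
            s1, e1, _ = ols_oracle(d, y1)
            s2, e2, _ = ols_oracle(d, y2)
            flags += effect_size_difference(s1, e1, n, s2, e2, n)["significant"]
        sd = np.sqrt(reps * 0.1 * 0.9)
        assert abs(flags - 0.1 * reps) < 4 * sd

    def test_table_matches_scalar_function(self):
        a = pd.DataFrame(
            {"variant_id": ["v"], "gene_id": ["g"], "slope": [1.0],
             "se": [0.2], "n": [50]}
        )
        b = pd.DataFrame(
            {"variant_id": ["v"], "gene_id": ["g"], "slope": [0.2],
             "se": [0.15], "n": [50]}
        )
        table = effect_size_table(a, b).iloc[0]
        scalar = effect_size_difference(1.0, 0.2, 50, 0.2, 0.15, 50)
        assert table["difference"] == pytest.approx(scalar["difference"])
        assert table["ci_low"] == pytest.approx(scalar["ci"][0], abs=1e-12)
        assert table["ci_high"] == pytest.approx(scalar["ci"][1], abs=1e-12)
        assert bool(table["significant"]) == scalar["significant"]


class TestGenotypeSummaries:
    def cohort(self, expr_c, expr_t):
        gm, em_c = make_cohort({"v": [0, 0, 1, 1, 2, 2]}, {"g": expr_c})
        _, em_t = make_cohort({"v": [0, 0, 1, 1, 2, 2]}, {"g": expr_t},
                              condition="tm")
        return gm, em_c, em_t

    def test_equal_means_fold_change_one(self):
        e = [1.0, 1.0, 2.0, 2.0, 3.0, 3.0]
        gm, ec, et = self.cohort(e, e)
        out = genotype_summaries("v", "g", gm, ec, et)
        assert np.allclose(out["fold_change"], 1.0)

    def test_planted_log2_fold_change(self):
        ec = [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        shift = np.log2(3.3)
        et = [v + shift for v in ec]
        gm, c, t = self.cohort(ec, et)
        out = genotype_summaries("v", "g", gm, c, t)
        assert np.allclose(out["fold_change"], 3.3)

    def test_constant_expression_equal_class_means(self):
        e = [5.0] * 6
        gm, c, t = self.cohort(e, e)
        out = genotype_summaries("v", "g", gm, c, t)
        assert out["mean_control"].nunique() == 1
        assert len(out) == 3

    def test_empty_class_omitted(self):
        gm, ec = make_cohort({"v": [0, 0, 1, 1]}, {"g": [1.0, 1.0, 2.0, 2.0]})
        _, et = make_cohort({"v": [0, 0, 1, 1]}, {"g": [1.0, 1.0, 2.0, 2.0]},
                            condition="tm")
        out = genotype_summaries("v", "g", gm, ec, et)
        assert set(out["dosage"]) == {0, 1}


def test_genotype_matrix_rejects_bad_dosage():
    with pytest.raises(ValueError):
        GenotypeMatrix(
            pd.DataFrame({"s": [3.0]}, index=["v"]),
            pd.DataFrame({"chrom": "c", "pos": 1, "ref": "A", "alt": "G"},
                         index=["v"]),
        )


def test_allele_frequency_ignores_missing():
    gm = GenotypeMatrix(
        pd.DataFrame({"a": [1.0], "b": [np.nan], "c": [2.0]}, index=["v"]),
        pd.DataFrame({"chrom": "c", "pos": 1, "ref": "A", "alt": "G"},
                     index=["v"]),
    )
    assert gm.allele_frequency["v"] == pytest.approx(0.75)
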