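from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from ewasrep.concordance import (
    GeneticAnnotation,
    annotate_genetic_context,
    compare_associations,
    effect_size_regression,
    summarize_trait,
    variance_explained_column,
)
from ewasrep.ewas import ModelSpec
from ewasrep.synthetic import SyntheticConfig, generate_cohort, generate_reference_summary


def summary(probe_ids, effects, ses, trait="alcohol", ancestry="EU"):
    effects = np.asarray(effects, dtype=float)
    ses = np.asarray(ses, dtype=float)
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "trait": trait,
            "ancestry": ancestry,
            "effect": effects,
            "se": ses,
        }
    )


class TestCompareAssociations:
    def test_identical_tables_all_overlap(self):
        table = summary(["a", "b", "c"], [0.1, -0.2, 0.0], [0.05, 0.05, 0.05])
        res = compare_associations(table, table)
        assert res.records["overlap"].all()
        assert (res.records["direction_class"] == "overlap").all()

    def test_hand_computed_nonoverlap_consistent(self):
        # CIs (0.804, 1.196) and (1.804, 2.196): disjoint, same sign
        local = summary(["a"], [1.0], [0.1])
        ref = summary(["a"], [2.0], [0.1])
        rec = compare_associations(local, ref).records.iloc[0]
        assert rec["local_ci_low"] == pytest.approx(0.804, abs=1e-3)
        assert rec["local_ci_high"] == pytest.approx(1.196, abs=1e-3)
        assert rec["ref_ci_low"] == pytest.approx(1.804, abs=1e-3)
        assert not rec["overlap"]
        assert rec["direction_class"] == "consistent_nonoverlap"

    def test_opposite_signs_tight_ses(self):
        rec = compare_associations(
            summary(["a"], [0.5], [0.01]), summary(["a"], [-0.5], [0.01])
        ).records.iloc[0]
        assert rec["direction_class"] == "opposite"

    def test_zero_effect_consistent_with_either_sign(self):
        rec = compare_associations(
            summary(["a"], [0.0], [0.001]), summary(["a"], [-0.5], [0.001])
        ).records.iloc[0]
        assert rec["direction_class"] == "consistent_nonoverlap"

    def test_unmatched_probes_reported_not_dropped(self):
        local = summary(["a", "b"], [0.1, 0.2], [0.1, 0.1])
        ref = summary(["b", "c"], [0.2, 0.3], [0.1, 0.1])
        res = compare_associations(local, ref)
        assert list(res.records["probe_id"]) == ["b"]
        assert list(res.unmatched_local["probe_id"]) == ["a"]
        assert list(res.unmatched_reference["probe_id"]) == ["c"]

    def test_orientation_mismatch_error(self):
        local = summary(["a"], [0.1], [0.1])
        ref = summary(["a"], [0.1], [0.1])
        local.attrs["orientation"] = "methylation_outcome"
        ref.attrs["orientation"] = "trait_outcome"
        with pytest.raises(ValueError, match="orientation"):
            compare_associations(local, ref)

    def test_overlap_symmetric_under_swap(self, rng):
        m = 200
        local = summary(range(m), rng.normal(0, 1e-3, m), rng.uniform(1e-4, 5e-4, m))
        ref = summary(range(m), rng.normal(0, 1e-3, m), rng.uniform(1e-4, 5e-4, m))
        fwd = compare_associations(local, ref).records
        rev = compare_associations(ref, local).records
        np.testing.assert_array_equal(fwd["overlap"], rev["overlap"])

    def test_widening_ci_never_removes_overlap(self, rng):
        m = 200
        local = summary(range(m), rng.normal(0, 1e-3, m), rng.uniform(1e-4, 5e-4, m))
        ref = summary(range(m), rng.normal(0, 1e-3, m), rng.uniform(1e-4, 5e-4, m))
        before = compare_associations(local, ref).records["overlap"]
        wider = ref.assign(se=ref["se"] * 3)
        after = compare_associations(local, wider).records["overlap"]
        assert (after | ~before).all()

    def test_partition_identity(self, rng):
        m = 500
        local = summary(range(m), rng.normal(0, 1e-3, m), rng.uniform(1e-5, 2e-4, m))
        ref = summary(range(m), rng.normal(0, 1e-3, m), rng.uniform(1e-5, 2e-4, m))
        rec = compare_associations(local, ref).records
        counts = rec["direction_class"].value_counts()
        assert counts.sum() == m
        assert set(counts.index) <= {"overlap", "consistent_nonoverlap", "opposite"}


class TestClassifyComparisonTable:
    def test_matches_pairwise_comparison(self, rng):
        from ewasrep.concordance import classify_comparison_table

        m = 100
        table = pd.DataFrame(
            {
                "trait": "alcohol",
                "ancestry": "AA",
                "probe_id": [f"cg{i}" for i in range(m)],
                "local_effect": rng.normal(0, 1e-3, m),
                "local_se": rng.uniform(1e-5, 5e-4, m),
                "ref_effect": rng.normal(0, 1e-3, m),
                "ref_se": rng.uniform(1e-5, 5e-4, m),
            }
        )
        classified = classify_comparison_table(table)
        local = summary(table["probe_id"], table["local_effect"], table["local_se"])
        ref = summary(table["probe_id"], table["ref_effect"], table["ref_se"])
        records = compare_associations(local, ref).records
        np.testing.assert_array_equal(
            classified["direction_class"].to_numpy(), records["direction_class"].to_numpy()
        )

    def test_missing_columns_error(self):
        from ewasrep.concordance import classify_comparison_table

        with pytest.raises(ValueError, match="required columns"):
            classify_comparison_table(pd.DataFrame({"probe_id": ["a"]}))


class TestSummarizeTrait:
    def records(self, classes):
        return pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(len(classes))],
                "trait": "alcohol",
                "ref_ancestry": "AA",
                "local_effect": 0.1,
                "ref_effect": 0.1,
                "direction_class": classes,
            }
        )

    def test_fraction_arithmetic(self):
        s = summarize_trait(
            self.records(["overlap"] * 9 + ["consistent_nonoverlap"]),
            include_regression=False,
        )
        assert (s.frac_overlap, s.frac_consistent, s.frac_opposite) == (0.9, 0.1, 0.0)
        assert s.pct_overlap == 90

    def test_all_overlap_no_opposite(self):
        s = summarize_trait(self.records(["overlap"] * 5), include_regression=False)
        assert s.n_opposite == 0 and s.n_tests == 5

    def test_empty_error(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_trait(self.records([]))

    def test_mixed_traits_rejected(self):
        rec = self.records(["overlap", "overlap"])
        rec.loc[1, "trait"] = "bmi"
        with pytest.raises(ValueError, match="single trait"):
            summarize_trait(rec)

    def test_discordant_fraction_recovered_through_pipeline(self):
        cfg = SyntheticConfig(
            n_samples=10,
            n_probes=10_000,
            n_causal=10_000,
            effect_scale=1e-3,
            discordant_fraction=0.01,
            reference_noise_scale=0.1,
            se_profile={"kind": "constant", "value": 2e-5},
            seed=31,
        )
        _, _, truth = generate_cohort(cfg)
        ref = generate_reference_summary(truth, cfg)
        local = summary(
            truth.index, truth["true_effect"], np.full(len(truth), 2e-5)
        )
        rec = compare_associations(local, ref).records
        s = summarize_trait(rec, include_regression=False)
        tol = 3 * np.sqrt(0.01 * 0.99 / 10_000)
        assert abs(s.frac_opposite - 0.01) <= tol


class TestEffectSizeRegression:
    def test_exact_half_slope(self):
        x = np.linspace(-1e-3, 1e-3, 50)
        res = effect_size_regression(
            summary(range(50), x, 1e-4), summary(range(50), 0.5 * x, 1e-4)
        )
        assert res.slope == pytest.approx(0.5, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_equality_line(self):
        x = np.linspace(-1e-3, 1e-3, 30)
        res = effect_size_regression(summary(range(30), x, 1e-4), summary(range(30), x, 1e-4))
        assert res.slope == pytest.approx(1.0, abs=1e-12)

    def test_y_axis_convention(self):
        x = np.linspace(1e-4, 1e-3, 20)
        local = summary(range(20), x, 1e-4)
        ref = summary(range(20), 0.5 * x, 1e-4)
        assert effect_size_regression(local, ref, "reference").slope == pytest.approx(0.5)
        assert effect_size_regression(local, ref, "local").slope == pytest.approx(2.0)

    def test_too_few_probes_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            effect_size_regression(
                summary(["a", "b"], [0.1, 0.2], [0.1, 0.1]),
                summary(["a", "b"], [0.1, 0.2], [0.1, 0.1]),
            )


class TestGeneticAnnotation:
    def make_annotation(self):
        mqtl = pd.DataFrame(
            {
                "probe_id": ["cg21227253", "cg21227253", "cgTRANS"],
                "snp_id": ["rs7153432", "rs0000001", "rs0000002"],
                "type": ["cis", "cis", "trans"],
                "z": [12.9, 4.15, 5.0],
            }
        )
        maf = pd.DataFrame(
            {
                "snp_id": ["rs7153432"] * 2 + ["rs0000001"] * 2 + ["rs0000002"] * 2,
                "population": ["AFR", "EUR"] * 3,
                "maf": [0.18, 0.40, 0.30, 0.30, 0.10, 0.12],
            }
        )
        flags = pd.DataFrame({"probe_id": ["cgPOLY"], "flag": ["polymorphic"]})
        return GeneticAnnotation(mqtl=mqtl, maf=maf, flags=flags)

    def records(self, probes):
        return pd.DataFrame(
            {
                "probe_id": probes,
                "direction_class": ["opposite"] * len(probes),
            }
        )

    def test_known_maf_gap_flags_discordant(self):
        # MAF 18% in Africans vs 40% in Europeans exceeds the 10-point gap
        out, _ = annotate_genetic_context(
            self.records(["cg21227253"]), self.make_annotation()
        )
        row = out.iloc[0]
        assert row["maf_discordant"] and row["has_cis_mqtl"] and not row["has_trans_mqtl"]

    def test_equal_mafs_not_discordant(self):
        ann = self.make_annotation()
        rec = pd.DataFrame({"probe_id": ["cgEQ"], "direction_class": ["opposite"]})
        ann.mqtl = pd.DataFrame(
            {"probe_id": ["cgEQ"], "snp_id": ["rs0000001"], "type": ["cis"], "z": [5.0]}
        )
        out, _ = annotate_genetic_context(rec, ann)
        assert not out.iloc[0]["maf_discordant"]

    def test_probe_without_mqtl_all_false(self):
        out, _ = annotate_genetic_context(self.records(["cgNONE"]), self.make_annotation())
        row = out.iloc[0]
        assert not row[["has_cis_mqtl", "has_trans_mqtl", "maf_discordant"]].any()

    def test_polymorphic_flag_from_list(self):
        out, counts = annotate_genetic_context(
            self.records(["cgPOLY"]), self.make_annotation()
        )
        assert out.iloc[0]["polymorphic_probe"]
        assert counts["polymorphic_probe"] == 1 and counts["n_opposite"] == 1

    def test_missing_population_error(self):
        with pytest.raises(KeyError, match="SAS"):
            annotate_genetic_context(
                self.records(["cg21227253"]),
                self.make_annotation(),
                populations=("SAS", "EUR"),
            )

    def test_maf_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0, 0.5"):
            GeneticAnnotation(
                mqtl=pd.DataFrame(columns=["probe_id", "snp_id", "type", "z"]),
                maf=pd.DataFrame(
                    {"snp_id": ["rs1"], "population": ["AFR"], "maf": [0.7]}
                ),
            )


class TestVarianceExplainedColumn:
    def brute_force_lmg_share(self, y, X, target):
        """All-orderings sequential R-squared oracle."""
        cols = list(X.columns)

        def r2(names):
            if not names:
                return 0.0
            Z = np.column_stack([np.ones(len(y)), X[list(names)].to_numpy()])
            coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
            rss = np.sum((y - Z @ coef) ** 2)
            tss = np.sum((y - y.mean()) ** 2)
            return 1.0 - rss / tss

        total = 0.0
        orders = list(permutations(cols))
        for order in orders:
            idx = order.index(target)
            total += r2(order[: idx + 1]) - r2(order[:idx])
        return total / len(orders)

    def make_cohort(self):
        cfg = SyntheticConfig(n_samples=50, n_probes=10, n_causal=5, noise_sd=0.01, seed=44)
        return generate_cohort(cfg)

    def test_sole_predictor_share_equals_total(self):
        n = 50
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, n)
        y = 0.3 + 0.05 * x  # exact function of the exposure
        meth = pd.DataFrame([y], index=["cg1"], columns=[f"s{i}" for i in range(n)])
        pheno = pd.DataFrame({"dose": x}, index=meth.columns)
        out = variance_explained_column(meth, pheno, ModelSpec(trait="dose"), ["cg1"])
        assert out.iloc[0]["pct_var_exposure"] == pytest.approx(100.0, abs=1e-6)
        assert out.iloc[0]["pct_var_total"] == pytest.approx(100.0, abs=1e-6)

    def test_matches_brute_force_oracle(self):
        meth, pheno, _ = self.make_cohort()
        spec = ModelSpec(trait="alcohol", covariates=("age", "bmi", "wc"))
        probes = list(meth.index[:3])
        out = variance_explained_column(meth, pheno, spec, probes).set_index("probe_id")
        X = pheno[["alcohol", "age", "bmi", "wc"]].astype(float)
        for probe in probes:
            y = meth.loc[probe, pheno.index].to_numpy()
            oracle = self.brute_force_lmg_share(y, X, "alcohol")
            assert out.loc[probe, "pct_var_exposure"] == pytest.approx(
                100.0 * oracle, abs=1e-8
            )

    def test_lrt_p_matches_nested_models(self):
        from ewasrep.varpower import nested_lrt

        meth, pheno, _ = self.make_cohort()
        spec = ModelSpec(trait="alcohol", covariates=("age",))
        probe = meth.index[0]
        out = variance_explained_column(meth, pheno, spec, [probe])
        y = meth.loc[probe, pheno.index].to_numpy()
        full = pheno[["alcohol", "age"]].astype(float)
        _, _, p = nested_lrt(y, full, pheno[["age"]].astype(float))
        assert out.iloc[0]["lrt_p"] == pytest.approx(p, rel=1e-10)
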