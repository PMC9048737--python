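import dataclasses

import numpy as np
import pandas as pd
import pytest

from dysbiom import biomarkers, evaluate, feature_table as ft, synthetic
from conftest import null_config
import oracles


def rel_of(columns: dict, taxa) -> pd.DataFrame:
    return pd.DataFrame(columns, index=pd.Index(taxa, name="taxon_id"))


SIG = biomarkers.SignatureSet(frozenset({"case1", "case2"}), frozenset({"ctrl1", "ctrl2"}))
TAXA = ["case1", "case2", "ctrl1", "ctrl2", "other"]


class TestDysbiosisIndex:
    def test_formula(self):
        rel = rel_of({"s": [0.15, 0.05, 0.06, 0.04, 0.7]}, TAXA)
        di = evaluate.dysbiosis_index(rel, SIG)
        assert di["s"] == pytest.approx(2.0, abs=1e-4)

    def test_equal_masses_give_one(self):
        rel = rel_of({"s": [0.1, 0.1, 0.1, 0.1, 0.6]}, TAXA)
        assert evaluate.dysbiosis_index(rel, SIG)["s"] == pytest.approx(1.0, abs=1e-4)

    def test_zero_denominator_finite_via_pseudocount(self):
        rel = rel_of({"s": [0.15, 0.05, 0.0, 0.0, 0.8]}, TAXA)
        di = evaluate.dysbiosis_index(rel, SIG)["s"]
        assert np.isfinite(di)
        assert di == pytest.approx((0.2 + 1e-6) / 1e-6, rel=1e-6)

    def test_scale_free_in_counts(self):
        counts = pd.DataFrame(
            {"s1": [3, 1, 2, 4, 10], "s2": [1, 1, 1, 1, 6]}, index=TAXA
        )
        di1 = evaluate.dysbiosis_index(ft.relative_abundance(counts), SIG)
        di2 = evaluate.dysbiosis_index(ft.relative_abundance(counts * 17), SIG)
        pd.testing.assert_series_equal(di1, di2)

    def test_side_swap_inverts(self):
        rel = rel_of({"s1": [0.3, 0.1, 0.2, 0.1, 0.3], "s2": [0.05, 0.05, 0.4, 0.3, 0.2]}, TAXA)
        swapped = biomarkers.SignatureSet(SIG.enriched_in_control, SIG.enriched_in_case)
        di = evaluate.dysbiosis_index(rel, SIG)
        inv = evaluate.dysbiosis_index(rel, swapped)
        assert np.allclose(di * inv, 1.0, atol=1e-4)

    def test_missing_genus_contributes_zero_with_warning(self, caplog):
        rel = rel_of({"s": [0.2, 0.3, 0.5]}, ["case1", "ctrl1", "other"])
        import logging

        with caplog.at_level(logging.WARNING, logger="dysbiom.evaluate"):
            di = evaluate.dysbiosis_index(rel, SIG)
        assert np.isfinite(di["s"])
        assert any("case2" in r.message for r in caplog.records)

    def test_empty_side_rejected(self):
        rel = rel_of({"s": [1.0]}, ["case1"])
        empty = biomarkers.SignatureSet(frozenset({"case1"}), frozenset())
        with pytest.raises(ValueError):
            evaluate.dysbiosis_index(rel, empty)


class TestGroupTests:
    def test_cohort_sex_table_chi_square(self):
        # 2x3 male/female table of the modeled cohort: 7/5, 14/4, 16/4
        chi2, p, dof = evaluate.chi_square([[7, 14, 16], [5, 4, 4]])
        assert dof == 2
        assert chi2 == pytest.approx(2.039, abs=5e-4)
        assert p == pytest.approx(0.361, abs=5e-4)

    def test_wilcoxon_exact_small_sample(self):
        _, p = evaluate.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_wilcoxon_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=7)
            _, p = evaluate.wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(oracles.ranksum_exact_p(x, y), abs=1e-12)

    def test_anova_hand_computed(self):
        f, _ = evaluate.anova([1, 2, 3], [2, 3, 4])
        assert f == pytest.approx(1.5)

    def test_dispatcher_rejects_mismatched_test(self):
        values = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            evaluate.compare_groups(values, ["g1", "g2", "g3"], "wilcoxon")


class TestRocAuc:
    def test_perfect_separation(self):
        res = evaluate.roc_auc([1, 2, 3, 10, 11, 12], ["c"] * 3 + ["d"] * 3, "d")
        assert res.auc == 1.0

    def test_concordance_counting(self):
        scores = [0.1, 0.2, 0.3, 0.25, 0.4, 0.5]
        labels = [0, 0, 0, 1, 1, 1]
        res = evaluate.roc_auc(scores, labels, 1)
        assert res.auc == pytest.approx(8 / 9)
        assert res.auc == pytest.approx(
            oracles.auc_concordance([0.25, 0.4, 0.5], [0.1, 0.2, 0.3])
        )

    def test_all_ties_give_half(self):
        res = evaluate.roc_auc([1.0] * 6, [0, 0, 0, 1, 1, 1], 1)
        assert res.auc == 0.5

    def test_curve_monotone(self):
        rng = np.random.default_rng(5)
        res = evaluate.roc_auc(rng.normal(size=30), rng.integers(0, 2, 30) + 0, 1)
        assert (np.diff(res.sensitivities) >= -1e-12).all()
        assert (np.diff(res.specificities) <= 1e-12).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate.roc_auc([1, 2], [1, 1], 1)


class TestMultivariateAuc:
    def test_strong_effect_scenario_separates(self):
        cfg = dataclasses.replace(synthetic.SimulationConfig(), seed=5)
        table, meta, *_ = synthetic.simulate_dataset(cfg)
        genus = ft.collapse_to_rank(table, synthetic.simulate_taxonomy(list(table.index)), "genus")
        rel = ft.relative_abundance(genus)
        sig_rel = rel.loc[sorted(set(synthetic.CASE_ENRICHED_GENERA + synthetic.CONTROL_ENRICHED_GENERA))]
        mask = meta["group"].isin(["FRI", "HC"])
        res = evaluate.multivariate_auc(
            sig_rel.loc[:, mask[mask].index], meta.loc[mask, "group"], "FRI", seed=5
        )
        assert res.auc >= 0.9

    def test_null_labels_mean_auc_near_half(self):
        # leave-pair-out keeps the cross-validated AUC unbiased under
        # label permutation (leave-one-out would sit well below 0.5)
        rng = np.random.default_rng(0)
        n = 16
        aucs = []
        for rep in range(200):
            X = pd.DataFrame(
                rng.lognormal(size=(3, n)) / 100,
                index=["a", "b", "c"], columns=[f"s{i}" for i in range(n)],
            )
            labels = pd.Series(
                rng.permutation(["FRI"] * 8 + ["HC"] * 8), index=X.columns
            )
            aucs.append(evaluate.multivariate_auc(X, labels, "FRI", seed=rep).auc)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 1e-3

    def test_uninformative_genus_barely_moves_auc(self):
        cfg = dataclasses.replace(synthetic.SimulationConfig(), seed=5)
        table, meta, *_ = synthetic.simulate_dataset(cfg)
        rel = ft.relative_abundance(table)
        informative = [f"asv_{g}" for g in synthetic.CASE_ENRICHED_GENERA]
        mask = meta["group"].isin(["FRI", "HC"])
        ids = mask[mask].index
        base = evaluate.multivariate_auc(
            rel.loc[informative, ids], meta.loc[ids, "group"], "FRI", seed=1
        ).auc
        plus = evaluate.multivariate_auc(
            rel.loc[informative + ["asv_0002"], ids], meta.loc[ids, "group"], "FRI", seed=1
        ).auc
        assert abs(plus - base) < 0.05


class TestOddsRatios:
    def _meta(self, case_marker, ctrl_marker):
        n1, n0 = len(case_marker), len(ctrl_marker)
        return pd.DataFrame(
            {
                "group": ["FRI"] * n1 + ["FH"] * n0,
                "m": list(case_marker) + list(ctrl_marker),
            },
            index=[f"s{i}" for i in range(n1 + n0)],
        )

    def test_two_by_two_matches_cross_product_ratio(self):
        meta = self._meta([1] * 10 + [0] * 10, [1] * 5 + [0] * 15)
        out = evaluate.odds_ratios(meta, ["m"], standardize=False)
        assert out.loc["m", "OR"] == pytest.approx(3.0, abs=1e-6)

    def test_label_swap_inverts_odds_ratio(self):
        rng = np.random.default_rng(1)
        meta = self._meta(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        out = evaluate.odds_ratios(meta, ["m"], standardize=False)
        swapped = meta.copy()
        swapped["group"] = np.where(meta["group"] == "FRI", "FH", "FRI")
        out_sw = evaluate.odds_ratios(swapped, ["m"], standardize=False)
        assert out.loc["m", "OR"] * out_sw.loc["m", "OR"] == pytest.approx(1.0, abs=1e-9)

    def test_null_marker_ci_covers_one(self):
        rng = np.random.default_rng(2)
        covered = 0
        reps = 200
        for _ in range(reps):
            meta = self._meta(rng.normal(size=250), rng.normal(size=250))
            out = evaluate.odds_ratios(meta, ["m"])
            covered += out.loc["m", "ci_low"] <= 1.0 <= out.loc["m", "ci_high"]
        from scipy.stats import binom

        lo, hi = binom.interval(0.999, reps, 0.95)
        assert lo <= covered <= hi

    def test_constant_marker_rejected(self):
        meta = self._meta([1.0] * 10, [1.0] * 10)
        with pytest.raises(ValueError, match="constant"):
            evaluate.odds_ratios(meta, ["m"])


class TestMarkerTaxonCorrelations:
    def _inputs(self, marker_vals, taxon_vals):
        n = len(marker_vals)
        rel = pd.DataFrame({f"s{i}": [taxon_vals[i]] for i in range(n)},
                           index=pd.Index(["t"], name="taxon_id"))
        meta = pd.DataFrame({"m": marker_vals}, index=[f"s{i}" for i in range(n)])
        return rel, meta

    def test_monotone_pairs(self):
        rel, meta = self._inputs([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        out = evaluate.marker_taxon_correlations(rel, meta, ["m"])
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        rel, meta = self._inputs([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        out = evaluate.marker_taxon_correlations(rel, meta, ["m"])
        assert out["rho"].iloc[0] == pytest.approx(-1.0)

    def test_constant_vector_reported_missing(self):
        rel, meta = self._inputs([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        out = evaluate.marker_taxon_correlations(rel, meta, ["m"])
        assert np.isnan(out["rho"].iloc[0])

    def test_copula_link_recovers_target_rho(self):
        cfg = dataclasses.replace(
            null_config(2, n_per_group={"FRI": 17, "FH": 17, "HC": 16}, n_taxa=40),
            marker_links=(("asv_Escherichia", "asv_Escherichia", 0.6),),
        )
        # marker name may be arbitrary; reuse taxon id as the marker label
        table, meta, *_ = synthetic.simulate_dataset(cfg)
        rel = ft.relative_abundance(table)
        out = evaluate.marker_taxon_correlations(
            rel.loc[["asv_Escherichia"]], meta, ["asv_Escherichia"]
        )
        rho = out["rho"].iloc[0]
        assert rho == pytest.approx(0.6, abs=0.2)
        assert rho > 0

    def test_bh_adjustment_monotone_in_p(self, study_dataset, study_genus):
        meta = study_dataset["metadata"]
        markers = ["CRP", "ESR"]
        out = evaluate.marker_taxon_correlations(
            study_genus["filtered"].iloc[:10], meta, markers
        )
        ok = out.dropna(subset=["p"]).sort_values("p")
        assert (ok["p_adj"] >= ok["p"] - 1e-12).all()
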