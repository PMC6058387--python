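import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctewas.diffmeth import (
    RegressionSpec,
    build_design_matrix,
    call_ct_dmcgs,
    celltype_ttest,
    classify_direction,
    fit_cpg_regression,
    region_distribution,
    run_ewas,
)
from ctewas.errors import ContractError, ValidationError
from ctewas.synthetic import generate_sorted_cohort, make_default_design, null_design

from conftest import small_sheet


class TestCelltypeTTest:
    def test_matches_scipy_welch_oracle(self, sorted_cohort):
        beta, sheet, _ = sorted_cohort
        table = celltype_ttest(beta.iloc[:80], sheet)
        ctrl = sheet[sheet["diagnosis"] == "control"]
        xn = beta.iloc[:80][ctrl.index[ctrl["cell_fraction"] == "neuron"]].to_numpy()
        xg = beta.iloc[:80][ctrl.index[ctrl["cell_fraction"] == "glia"]].to_numpy()
        ref_t, ref_p = stats.ttest_ind(xn, xg, axis=1, equal_var=False)
        np.testing.assert_allclose(table["statistic"], ref_t, atol=1e-12)
        np.testing.assert_allclose(table["p"], ref_p, atol=1e-12)

    def test_identical_groups_give_p_one(self):
        sheet = small_sheet(8)
        sheet["cell_fraction"] = ["neuron"] * 4 + ["glia"] * 4
        vals = np.tile([0.2, 0.3, 0.4, 0.5], (3, 2))
        beta = pd.DataFrame(vals, index=["cg0", "cg1", "cg2"], columns=sheet.index)
        table = celltype_ttest(beta, sheet)
        assert (table["statistic"] == 0).all()
        assert (table["p"] == 1).all()

    def test_zero_variance_both_groups(self):
        sheet = small_sheet(8)
        sheet["cell_fraction"] = ["neuron"] * 4 + ["glia"] * 4
        beta = pd.DataFrame(
            [[0.2] * 8, [0.2] * 4 + [0.6] * 4], index=["flat", "split"], columns=sheet.index
        )
        table = celltype_ttest(beta, sheet)
        assert table.loc["flat", "p"] == 1 and table.loc["flat", "effect"] == 0
        assert table.loc["split", "p"] < 1e-300
        assert table.loc["split", "effect"] == pytest.approx(-0.4)

    def test_strong_planted_probe_is_extreme(self, design, sorted_cohort):
        beta, sheet, _ = sorted_cohort
        delta = np.abs(design.mu_neuron - design.mu_glia)
        strong = design.probe_ids[delta >= 0.4]
        table = celltype_ttest(beta, sheet)
        assert (table.loc[strong, "p"] < 1e-10).all()

    def test_too_few_samples_rejected(self):
        sheet = small_sheet(4)
        sheet["cell_fraction"] = ["neuron", "neuron", "neuron", "glia"]
        beta = pd.DataFrame(
            np.random.default_rng(0).random((3, 4)), index=["a", "b", "c"], columns=sheet.index
        )
        with pytest.raises(ContractError):
            celltype_ttest(beta, sheet)

    def test_pooled_variance_flag(self, sorted_cohort):
        beta, sheet, _ = sorted_cohort
        table = celltype_ttest(beta.iloc[:20], sheet, equal_var=True)
        n_ctrl = (sheet["diagnosis"] == "control").sum()
        assert (table["df"] == n_ctrl - 2).all()


class TestCallCtDmcgs:
    def make_results(self):
        return pd.DataFrame(
            {
                "effect": [0.19, 0.25, -0.30, 0.5],
                "p": [1e-30, 1e-30, 1e-30, 0.2],
                "bonferroni_p": [1e-26, 1e-26, 1e-26, 1.0],
            },
            index=["boundary", "auto_ok", "hypo_ok", "weak"],
        )

    def make_annotation(self, x_probe=None):
        ann = pd.DataFrame(
            {
                "chromosome": ["1", "2", "3", "4"],
                "position": [1, 2, 3, 4],
                "gene": "",
                "region": "Body",
                "autosomal": True,
            },
            index=["boundary", "auto_ok", "hypo_ok", "weak"],
        )
        if x_probe:
            ann.loc[x_probe, ["chromosome", "autosomal"]] = ["X", False]
        return ann

    def test_thresholds_and_direction_labels(self):
        called = call_ct_dmcgs(self.make_results(), self.make_annotation())
        assert set(called.index) == {"auto_ok", "hypo_ok"}
        assert called.loc["auto_ok", "direction"] == "hyper"
        assert called.loc["hypo_ok", "direction"] == "hypo"

    def test_x_chromosome_probe_excluded(self):
        called = call_ct_dmcgs(self.make_results(), self.make_annotation(x_probe="auto_ok"))
        assert set(called.index) == {"hypo_ok"}

    def test_missing_annotation_rejected(self):
        with pytest.raises(ValidationError):
            call_ct_dmcgs(self.make_results(), self.make_annotation().iloc[:2])

    def test_recovers_planted_truth(self, design, sorted_cohort):
        beta, sheet, ann = sorted_cohort
        called = call_ct_dmcgs(celltype_ttest(beta, sheet), ann)
        truth = pd.Index(design.probe_ids[design.is_ct])
        sens = len(called.index.intersection(truth)) / len(truth)
        fdr = len(called.index.difference(truth)) / max(len(called), 1)
        assert sens >= 0.9
        assert fdr <= 0.05


class TestCpgRegression:
    def make_data(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.random(n) * 50 + 30, rng.integers(0, 2, n)])
        y = 0.3 + 0.002 * X[:, 1] + 0.01 * X[:, 2] + rng.normal(0, 0.02, n)
        return y, X

    def test_matches_statsmodels_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        y, X = self.make_data()
        fit = fit_cpg_regression(y, X, names=["intercept", "age", "sex"])
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit["coef"], ref.params, atol=1e-10)
        np.testing.assert_allclose(fit["se"], ref.bse, atol=1e-10)
        np.testing.assert_allclose(fit["p"], ref.pvalues, atol=1e-10)

    def test_exact_linear_fit(self):
        n = 30
        x = np.linspace(30, 90, n)
        X = np.column_stack([np.ones(n), x])
        y = 0.1 + 0.004 * x
        fit = fit_cpg_regression(y, X)
        assert fit["coef"].iloc[1] == pytest.approx(0.004, abs=1e-12)
        assert fit["p"].iloc[1] < 1e-200

    def test_rank_deficient_rejected(self):
        y, X = self.make_data()
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(ContractError):
            fit_cpg_regression(y, X)

    def test_intercept_shift_invariance(self):
        y, X = self.make_data()
        a = fit_cpg_regression(y, X)
        b = fit_cpg_regression(y + 0.123, X)
        np.testing.assert_allclose(a["coef"].iloc[1:], b["coef"].iloc[1:], atol=1e-12)
        assert b["coef"].iloc[0] - a["coef"].iloc[0] == pytest.approx(0.123, abs=1e-10)

    def test_welch_equals_ols_with_equal_group_variances(self):
        # two equal-size groups whose sample variances match exactly
        rng = np.random.default_rng(5)
        base = rng.normal(0.4, 0.05, 30)
        y = np.concatenate([base, base + 0.03])
        g = np.repeat([0.0, 1.0], 30)
        X = np.column_stack([np.ones(60), g])
        ols = fit_cpg_regression(y, X)
        t, p = stats.ttest_ind(y[30:], y[:30], equal_var=False)
        assert abs(ols["p"].iloc[1] - p) < 1e-6


class TestRunEwas:
    def test_matches_per_probe_fit(self, sorted_cohort):
        beta, sheet, _ = sorted_cohort
        spec = RegressionSpec("braak", "glia", ("age", "sex"))
        table = run_ewas(beta.iloc[:25], sheet, None, spec)
        X_df = build_design_matrix(sheet, spec)
        for probe in beta.index[:25:5]:
            fit = fit_cpg_regression(
                beta.loc[probe, X_df.index].to_numpy(), X_df.to_numpy()
            )
            assert table.loc[probe, "effect"] == pytest.approx(fit["coef"].iloc[1], abs=1e-12)
            assert table.loc[probe, "p"] == pytest.approx(fit["p"].iloc[1], abs=1e-12)

    def test_type_one_error_calibrated(self):
        d = null_design(1000, 17)
        beta, sheet, _ = generate_sorted_cohort(d, 50)
        table = run_ewas(beta, sheet, None, RegressionSpec("age", "neuron", ("sex",)))
        frac = (table["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_planted_age_probes_recovered(self):
        d = make_default_design(10_000, 1)
        beta, sheet, _ = generate_sorted_cohort(d, 50)
        spec = RegressionSpec("age", "neuron", ("sex",), ("control",))
        table = run_ewas(beta, sheet, None, spec)
        planted = d.age_slope_neuron != 0
        ids = d.probe_ids[planted]
        recall = (table.loc[ids, "rank"] <= 1000).mean()
        assert recall >= 0.8
        rel_err = np.abs(
            table.loc[ids, "effect"].to_numpy() - d.age_slope_neuron[planted]
        ) / np.abs(d.age_slope_neuron[planted])
        assert np.median(rel_err) <= 0.25

    def test_permuting_predictor_destroys_signal(self):
        d = make_default_design(3000, 2)
        beta, sheet, _ = generate_sorted_cohort(d, 50)
        rng = np.random.default_rng(0)
        shuffled = sheet.copy()
        neuron = shuffled["cell_fraction"] == "neuron"
        shuffled.loc[neuron, "age"] = rng.permutation(shuffled.loc[neuron, "age"].to_numpy())
        spec = RegressionSpec("age", "neuron", ("sex",), ("control",))
        table = run_ewas(beta, shuffled, None, spec)
        planted = d.age_slope_neuron != 0
        recall = (table.loc[d.probe_ids[planted], "rank"] <= 1000).mean()
        assert recall < 0.3  # at background level

    def test_braak_null_rarely_significant(self):
        hits = 0
        for seed in range(20):
            d = null_design(1000, 200 + seed)
            beta, sheet, _ = generate_sorted_cohort(d, 40)
            table = run_ewas(beta, sheet, None, RegressionSpec("braak", "neuron", ("age", "sex")))
            hits += table["bonferroni_p"].min() >= 0.05
        assert hits >= 18

    def test_ranks_are_permutation_with_deterministic_ties(self, sorted_cohort):
        beta, sheet, _ = sorted_cohort
        table = run_ewas(beta.iloc[:50], sheet, None, RegressionSpec("braak", "neuron", ("age",)))
        assert sorted(table["rank"]) == list(range(1, 51))

    def test_empty_subset_rejected(self, sorted_cohort):
        beta, sheet, _ = sorted_cohort
        with pytest.raises(ContractError):
            run_ewas(beta, sheet, None, RegressionSpec("braak", "bulk", ("age",)))

    def test_predictor_cannot_be_covariate(self):
        with pytest.raises(ContractError):
            RegressionSpec("age", "neuron", ("age", "sex"))


class TestClassifyDirection:
    def test_monotone_probe_is_hyper(self, sorted_cohort):
        beta, sheet, _ = sorted_cohort
        ctrl = sheet[sheet["diagnosis"] == "control"].sort_values("age")
        fake = beta.iloc[:3].copy()
        fake.loc[:, :] = 0.2
        fake.loc[fake.index[0], ctrl.index[-8:]] = 0.8
        labels = classify_direction(fake, sheet, fake.index, "aging")
        assert labels.iloc[0] == "hyper"
        assert (labels.iloc[1:] == "unchanged").all()

    def test_matches_group_mean_oracle(self, sorted_cohort):
        beta, sheet, _ = sorted_cohort
        probes = beta.index[:40]
        labels = classify_direction(beta, sheet, probes, "aging")
        ctrl = sheet[sheet["diagnosis"] == "control"].sort_values("age")
        young, old = ctrl.index[:8], ctrl.index[-8:]
        diff = beta.loc[probes, old].mean(axis=1) - beta.loc[probes, young].mean(axis=1)
        expected = np.where(diff > 0, "hyper", np.where(diff < 0, "hypo", "unchanged"))
        assert (labels.to_numpy() == expected).all()

    def test_negative_slope_probes_mostly_hypo(self):
        d = make_default_design(5000, 9)
        beta, sheet, _ = generate_sorted_cohort(d, 50)
        neg = d.probe_ids[d.age_slope_neuron < 0]
        neuron_beta = beta[sheet.index[sheet["cell_fraction"] == "neuron"]]
        labels = classify_direction(neuron_beta, sheet, neg, "aging")
        assert (labels == "hypo").mean() >= 0.9


class TestRegionDistribution:
    def test_set_equal_background_gives_unit_ratios(self, sorted_cohort):
        _, _, ann = sorted_cohort
        table = region_distribution(ann.index, ann, ann.index)
        present = table["count"] > 0
        np.testing.assert_allclose(table.loc[present, "ratio"], 1.0, atol=1e-12)

    def test_counts_match_brute_force(self, sorted_cohort):
        _, _, ann = sorted_cohort
        probes = ann.index[::7]
        table = region_distribution(probes, ann, ann.index)
        for region in table.index:
            expected = sum(ann.loc[p, "region"] == region for p in probes)
            assert table.loc[region, "count"] == expected

    def test_body_enrichment_by_construction(self, sorted_cohort):
        _, _, ann = sorted_cohort
        body = ann.index[ann["region"] == "Body"][:50]
        other = ann.index[ann["region"] != "Body"][:10]
        table = region_distribution(body.append(other), ann, ann.index)
        assert table.loc["Body", "ratio"] > 1
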