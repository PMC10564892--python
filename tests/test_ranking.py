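import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import r2_score

from pepatlas.geometry import build_backbone
from pepatlas.ranking import (
    RegressionSpec,
    TemplateRankingModel,
    TemplateRankingResults,
    hamming,
    loo_benchmark,
    remove_homologs,
    template_is_stable,
    validate_drift,
)
from pepatlas.synthetic import SyntheticFeatureSpec, make_feature_table

FAST = RegressionSpec(c_grid=(1.0, 100.0), epsilon_grid=(0.01, 0.1), cv_folds=3)


@pytest.fixture(scope="module")
def clean_table():
    return make_feature_table(
        SyntheticFeatureSpec(n_targets=15, n_templates=8, n_features=12,
                             noise_std=0.0, seed=42)
    )


class TestHomologRemoval:
    def pair(self, a, b):
        return pd.DataFrame([{"target_peptide": a, "template_peptide": b,
                              "target_id": "t", "template_id": "r"}])

    @pytest.mark.parametrize("template,removed", [
        ("GLAFSGVAK", True),    # identical
        ("GLAFSGVAW", True),    # distance 1
        ("GAAFSGAAW", True),    # distance 3 — still homolog
        ("AAAFSGAAW", False),   # distance 4 — retained
    ])
    def test_hamming_boundary(self, template, removed):
        out = remove_homologs(self.pair("GLAFSGVAK", template))
        assert (len(out) == 0) == removed

    def test_length_mismatch_skipped_and_logged(self):
        out = remove_homologs(self.pair("GLAFSGVAK", "GLAFSGVAKK"))
        assert len(out) == 0
        assert out.attrs["skipped"] != []

    def test_hamming_requires_equal_length(self):
        with pytest.raises(ValueError):
            hamming("AA", "AAA")


class TestDriftValidation:
    def test_identical_model_kept(self):
        bb = build_backbone(9, -75.0, 145.0)
        assert validate_drift(bb, bb)

    def test_single_torsion_dialed_past_limit_drops(self):
        template = build_backbone(9, -75.0, 145.0)
        phi = np.full(9, -75.0)
        # 2(1-cos(90)) = 2.0 > 1.5 at one position
        phi[4] += 90.0
        drifted = build_backbone(9, phi, 145.0)
        assert not validate_drift(drifted, template)
        # 2(1-cos(45)) ~ 0.586 stays within the limit
        phi[4] = -75.0 + 45.0
        mild = build_backbone(9, phi, 145.0)
        assert validate_drift(mild, template)

    def test_template_stability_uses_tighter_limit(self):
        crystal = build_backbone(9, -75.0, 145.0)
        phi = np.full(9, -75.0)
        phi[5] += 63.0  # D ~ 2(1-cos 63) ~ 1.09 > 1.0
        relaxed = build_backbone(9, phi, 145.0)
        assert not template_is_stable(crystal, relaxed)
        assert validate_drift(relaxed, crystal)  # still within 1.5


class TestTraining:
    def test_noiseless_planted_features_recovered(self, clean_table):
        targets = list(dict.fromkeys(clean_table["target_id"]))
        test_targets = set(targets[:3])
        train = clean_table[~clean_table["target_id"].isin(test_targets)]
        held = clean_table[clean_table["target_id"].isin(test_targets)]
        held = held[held["true_dscore"] <= 7.0]
        res = TemplateRankingModel(train, FAST).fit(seed=0)
        r2 = r2_score(held["true_dscore"], res.predict(held))
        assert r2 > 0.9

    def test_high_dscore_rows_excluded_from_fit(self):
        table = make_feature_table(
            SyntheticFeatureSpec(n_targets=8, n_templates=6, n_features=8,
                                 noise_std=0.0, seed=1)
        )
        table.loc[table.index[:5], "true_dscore"] = 7.5
        res = TemplateRankingModel(table, FAST).fit(seed=0)
        n_kept = (table["true_dscore"] <= 7.0).sum()
        assert res.n_train == n_kept

    def test_predictions_finite_on_training_rows(self, clean_table):
        res = TemplateRankingModel(clean_table, FAST).fit(seed=0)
        assert np.isfinite(res.predict(clean_table)).all()

    def test_too_few_rows_error(self, clean_table):
        with pytest.raises(ValueError, match="10 training rows"):
            TemplateRankingModel(clean_table.head(5), FAST).fit()

    def test_summary_reports_chosen_hyperparameters(self, clean_table):
        res = TemplateRankingModel(clean_table, FAST).fit(seed=0)
        text = res.summary()
        assert "C " in text and "epsilon" in text and "R^2" in text


@pytest.fixture(scope="module")
def fitted(clean_table):
    return TemplateRankingModel(clean_table, FAST).fit(seed=0)


class TestSelection:
    def test_single_candidate_selected_without_threshold(self, fitted, clean_table):
        one = clean_table.head(1)
        sel = fitted.rank_and_select(one)
        assert not sel.abstained
        assert sel.template_id == one["template_id"].iloc[0]

    def test_selection_is_argmin_of_predictions(self, fitted, clean_table):
        for tid, grp in list(clean_table.groupby("target_id"))[:5]:
            sel = fitted.rank_and_select(grp)
            preds = fitted.predict(grp)
            assert sel.template_id == grp["template_id"].iloc[int(np.argmin(preds))]

    def test_abstains_above_threshold(self, fitted, clean_table):
        grp = clean_table[clean_table["target_id"] == clean_table["target_id"].iloc[0]]
        sel = fitted.rank_and_select(grp, abstain_threshold=-10.0)
        assert sel.abstained and sel.template_id is None

    def test_zero_candidates_abstains_with_reason(self, fitted, clean_table):
        sel = fitted.rank_and_select(clean_table.head(0))
        assert sel.abstained and sel.reason == "no_candidates"


class TestPersistence:
    def test_json_round_trip_reproduces_predictions(self, clean_table):
        res = TemplateRankingModel(clean_table, FAST).fit(seed=0)
        predict, cols = TemplateRankingResults.predictor_from_json(res.to_json())
        X = clean_table[cols].to_numpy(float)
        assert np.allclose(predict(X), res.pipeline.predict(X), atol=1e-9)


class TestBenchmark:
    def test_oracle_features_give_perfect_accuracy(self):
        # features fully determine the true D-score (no noise dimensions)
        table = make_feature_table(
            SyntheticFeatureSpec(n_targets=15, n_templates=8, n_features=3,
                                 n_informative=3, noise_std=0.0, seed=42)
        )
        bench = loo_benchmark(table, FAST, seed=0)
        assert bench.accuracy == 1.0
        assert len(bench.outcomes) == table["target_id"].nunique()

    def test_permuted_features_collapse_to_baseline(self):
        table = make_feature_table(
            SyntheticFeatureSpec(n_targets=15, n_templates=8, n_features=10,
                                 noise_std=0.0, seed=3)
        )
        rng = np.random.default_rng(0)
        fcols = [c for c in table.columns if c.startswith("f")]
        table[fcols] = rng.permutation(table[fcols].to_numpy())
        bench = loo_benchmark(table, FAST, seed=0)
        assert abs(bench.accuracy - bench.random_baseline) < 0.25

    def test_selected_models_beat_random_on_noisy_features(self):
        table = make_feature_table(
            SyntheticFeatureSpec(n_targets=30, n_templates=8, n_features=10,
                                 noise_std=0.4, seed=7)
        )
        bench = loo_benchmark(table, FAST, seed=0)
        selected = bench.outcomes["true_dscore"].dropna().to_numpy()
        pool = table["true_dscore"].to_numpy()
        stat, p = mannwhitneyu(selected, pool, alternative="less")
        assert p < 1e-3

    def test_no_leakage_from_held_out_rows(self, clean_table):
        target = clean_table["target_id"].iloc[0]
        train = clean_table[clean_table["target_id"] != target]
        held = clean_table[clean_table["target_id"] == target]
        res = TemplateRankingModel(train, FAST).fit(seed=0)
        corrupted = held.copy()
        fcols = [c for c in held.columns if c.startswith("f")]
        base_preds = res.predict(held)
        # refit after perturbing held-out rows in the full table: the
        # training split is unchanged, so predictions must be identical
        table2 = pd.concat([train, corrupted.assign(**{fcols[0]: 999.0})])
        res2 = TemplateRankingModel(
            table2[table2["target_id"] != target], FAST
        ).fit(seed=0)
        assert np.allclose(res2.predict(held), base_preds)

    def test_benchmark_deterministic_under_fixed_seed(self, clean_table):
        b1 = loo_benchmark(clean_table, FAST, seed=5)
        b2 = loo_benchmark(clean_table, FAST, seed=5)
        pd.testing.assert_frame_equal(b1.outcomes, b2.outcomes)
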