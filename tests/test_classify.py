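import numpy as np
import pytest

from conftest import make_feature_table
from fetrad.classify import (
    ClassificationConfig,
    TumorClassifier,
    leaky_best_feature_auc,
    nested_cv_auc,
    univariate_auc,
)

FAST = ClassificationConfig(n_repeats=3, n_folds=5, inner_folds=3, C_grid=(0.1, 1.0, 10.0), seed=0)


class TestNestedCV:
    def test_perfectly_separable_feature_gives_auc_one(self):
        table = make_feature_table(
            n_patients=10, effect={("TTP", "firstorder_Mean"): 50.0}
        )
        report = nested_cv_auc(table, ("TTP", "firstorder_Mean"), "all", FAST)
        assert report.mean == 1.0

    def test_determinism(self):
        table = make_feature_table(n_patients=10)
        a = nested_cv_auc(table, "TTP", "all", FAST)
        b = nested_cv_auc(table, "TTP", "all", FAST)
        assert np.array_equal(a.fold_aucs, b.fold_aucs)
        assert np.array_equal(a.chosen_C, b.chosen_C, equal_nan=True)

    def test_permuted_label_null_auc_near_half(self):
        """Randomly permuted labels: mean nested-CV AUC within [0.45, 0.55]."""
        table = make_feature_table(
            n_patients=14, effect={("TBR_20_40", "firstorder_Mean"): 2.0}
        )
        aucs = []
        for seed in range(10):
            cfg = ClassificationConfig(
                n_repeats=3, n_folds=5, inner_folds=3, C_grid=(0.1, 1.0, 10.0), seed=seed
            )
            aucs.append(
                nested_cv_auc(
                    table, "TBR_20_40", "all", cfg, permute_labels_seed=seed
                ).mean
            )
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_mean_sd_recomputable_from_folds(self):
        table = make_feature_table(n_patients=10)
        r = nested_cv_auc(table, "All", "all", FAST)
        assert r.mean == pytest.approx(r.fold_aucs.mean())
        assert r.sd == pytest.approx(r.fold_aucs.std(ddof=1))
        assert r.fold_aucs.shape == (FAST.n_repeats, FAST.n_folds)
        assert np.all((r.fold_aucs >= 0) & (r.fold_aucs <= 1))

    def test_stratified_folds_balanced(self):
        """With the balanced two-rows-per-patient design every outer fold keeps
        the global class ratio."""
        from sklearn.model_selection import StratifiedKFold

        y = np.array([0, 1] * 20)
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        for _, te in skf.split(np.zeros((40, 1)), y):
            assert y[te].mean() == 0.5

    def test_group_by_patient_keeps_pairs_together(self):
        table = make_feature_table(n_patients=10)
        cfg = ClassificationConfig(
            n_repeats=2, n_folds=5, inner_folds=3, C_grid=(1.0,), seed=1, group_by_patient=True
        )
        r = nested_cv_auc(table, "TTP", "all", cfg)
        assert r.fold_aucs.shape == (2, 5)

    def test_nonfinite_features_rejected(self):
        table = make_feature_table(n_patients=8)
        idx = table.index[table["kind"] == "TTP"][0]
        table.loc[idx, "firstorder_Mean"] = np.nan
        with pytest.raises(ValueError):
            nested_cv_auc(table, "TTP", "all", FAST)


UNI = ClassificationConfig(n_repeats=2, n_folds=5, inner_folds=3, C_grid=(1.0,), seed=0)


class TestUnivariate:
    def test_single_feature_consistency_and_ordering(self):
        table = make_feature_table(n_patients=8)
        uni = univariate_auc(table, "all", UNI, image_kinds=("TTP",))
        # ranking is sorted by mean AUC descending, name as tiebreak
        keys = [(-r.mean, r.feature_set) for r in uni]
        assert keys == sorted(keys)
        # a singleton report equals nested_cv_auc on that feature
        top = uni[0]
        feat = top.feature_set.split(":")[1]
        assert top.mean == pytest.approx(nested_cv_auc(table, ("TTP", feat), "all", UNI).mean)

    def test_injected_ttp_effect_ranks_ttp_features_top(self):
        effect = {
            ("TTP", "firstorder_Mean"): 4.0,
            ("TTP", "firstorder_Median"): 4.0,
            ("TTP", "glcm_Idmn"): 4.0,
        }
        table = make_feature_table(n_patients=12, effect=effect)
        uni = univariate_auc(table, "all", UNI)
        top_kinds = {r.feature_set.split(":")[0] for r in uni[:3]}
        assert top_kinds == {"TTP"}


class TestLeakageAudit:
    def test_leaky_selection_inflates_null_auc(self):
        """Selecting the best of 279 null features on the full data, then
        cross-validating it, must beat the honest null."""
        leaky_means, honest_means = [], []
        for seed in range(4):
            table = make_feature_table(n_patients=12, rng=np.random.default_rng(200 + seed))
            cfg = ClassificationConfig(
                n_repeats=3, n_folds=5, inner_folds=3, C_grid=(1.0,), seed=seed
            )
            leaky_means.append(leaky_best_feature_auc(table, "all", cfg).mean)
            honest_means.append(nested_cv_auc(table, "All", "all", cfg).mean)
        assert np.mean(leaky_means) > np.mean(honest_means) + 0.05
        assert np.mean(leaky_means) > 0.60


class TestClassifierModel:
    def test_model_results_summary(self):
        table = make_feature_table(n_patients=8)
        cv = TumorClassifier(
            table, feature_sets=("TTP", "All"), subgroups=("all",), config=FAST
        ).fit()
        frame = cv.to_frame()
        assert set(frame["feature_set"]) == {"TTP", "All"}
        assert "Nested-CV logistic regression AUC" in cv.summary()
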