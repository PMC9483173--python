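import numpy as np
import pandas as pd
import pytest

from hergml.evaluation import ABSTAIN, confusion, cooper_stats
from hergml.modeling import (
    BalancedRandomForestClassifier,
    ConsensusModel,
    ModelingError,
    TrainedModelBundle,
    consensus_predict,
    kfold_cv,
    predict_labels,
    predict_proba,
    tune_and_train,
)

TINY_SPACES = {
    "BRF": {"n_estimators": [50]},
    "RF": {"n_estimators": [50]},
    "KNN": {"n_neighbors": [3, 5]},
    "GB": {"n_estimators": [50], "learning_rate": [0.1]},
    "XGB": {"n_estimators": [50], "learning_rate": [0.1, 0.3], "max_depth": [3]},
    "MLP": {"hidden_layer_sizes": [(32,)]},
    "SVM": {"C": [1.0, 10.0], "gamma": ["scale"]},
}


class TestTuneAndTrain:
    @pytest.mark.parametrize("algo", ["BRF", "RF", "KNN", "GB", "XGB", "MLP", "SVM"])
    def test_separable_data_reaches_high_cv_ba(self, separable_data, algo):
        X, y = separable_data
        bundle = tune_and_train(algo, X, y, search_space=TINY_SPACES[algo], seed=0)
        assert bundle.cv_metrics["mean"]["BA"] >= 0.95
        assert bundle.algorithm_id == algo

    def test_same_seed_same_winner(self, separable_data):
        X, y = separable_data
        a = tune_and_train("KNN", X, y, search_space={"n_neighbors": [3, 5, 7]}, seed=5)
        b = tune_and_train("KNN", X, y, search_space={"n_neighbors": [3, 5, 7]}, seed=5)
        assert a.hyperparameters == b.hyperparameters

    def test_random_search_respects_budget_and_records_tuner(self, separable_data):
        X, y = separable_data
        bundle = tune_and_train(
            "SVM", X, y,
            search_space={"C": [0.1, 1, 10, 100], "gamma": ["scale", 0.01, 0.1]},
            budget=3, seed=1,
        )
        assert bundle.tuner == "random"

    def test_brf_with_smote_forbidden_by_default(self, separable_data):
        X, y = separable_data
        with pytest.raises(ModelingError):
            tune_and_train("BRF", X, y, smote_used=True)

    def test_empty_grid_raises(self, separable_data):
        X, y = separable_data
        with pytest.raises(ModelingError):
            tune_and_train("KNN", X, y, search_space={"n_neighbors": []})

    def test_label_permutation_gives_chance_level_cv(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (120, 5))
        y = rng.permutation(np.array(["ACT"] * 60 + ["INA"] * 60))
        bas = []
        for seed in range(3):
            b = tune_and_train("RF", X, y, search_space={"n_estimators": [50]}, seed=seed)
            bas.append(b.cv_metrics["mean"]["BA"])
        assert 0.4 <= np.mean(bas) <= 0.6


class TestBRF:
    def test_each_tree_sees_balanced_sample(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (60, 4))
        y = np.array(["ACT"] * 10 + ["INA"] * 50)
        clf = BalancedRandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        assert len(clf.estimators_) == 20
        proba = clf.predict_proba(X)
        assert proba.shape == (60, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_less_majority_biased_than_always_majority(self, separable_data):
        X, y = separable_data
        clf = BalancedRandomForestClassifier(n_estimators=50, random_state=1).fit(X, y)
        c = confusion(list(y), list(clf.predict(X)))
        se, sp, ba = cooper_stats(c)
        assert ba >= 0.95


class TestPredict:
    def test_scores_in_unit_interval_and_duplicates_identical(self, separable_data):
        X, y = separable_data
        bundle = tune_and_train("RF", X, y, search_space=TINY_SPACES["RF"], seed=0)
        X2 = np.vstack([X, X[:1]])
        scores = predict_proba(bundle, X2)
        assert np.all((scores >= 0) & (scores <= 1))
        assert scores[0] == scores[-1]

    def test_deep_act_region_scores_high(self, separable_data):
        X, y = separable_data
        bundle = tune_and_train("RF", X, y, search_space=TINY_SPACES["RF"], seed=0)
        act_row = X[np.argmax(X[:, 0])][None, :]
        assert predict_proba(bundle, act_row)[0] > 0.9

    def test_feature_mismatch_names_columns(self, separable_data):
        X, y = separable_data
        bundle = tune_and_train(
            "RF", X, y, search_space=TINY_SPACES["RF"], seed=0,
            selected_features=["f0", "f1", "f2", "f3"],
        )
        df = pd.DataFrame(X[:, :3], columns=["f0", "f1", "bogus"])
        with pytest.raises(ModelingError, match="f2"):
            predict_proba(bundle, df)


class TestKFold:
    def test_folds_partition_and_mean_is_hand_average(self, separable_data):
        X, y = separable_data
        from sklearn.ensemble import RandomForestClassifier

        cv = kfold_cv(RandomForestClassifier(n_estimators=30, random_state=0), X, y, k=5, seed=0)
        assert cv["k"] == 5 and len(cv["folds"]) == 5
        for m in ("SE", "SP", "BA", "MCC", "AUC"):
            assert cv["mean"][m] == pytest.approx(np.mean([f[m] for f in cv["folds"]]))
        assert cv["mean"]["BA"] == pytest.approx(1.0)

    def test_stratified_folds_preserve_ratio(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([1] * 20 + [0] * 100)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, te in skf.split(np.zeros((120, 1)), y):
            assert abs((y[te] == 1).sum() - 4) <= 1

    def test_too_few_rows(self):
        from sklearn.neighbors import KNeighborsClassifier

        with pytest.raises(ModelingError):
            kfold_cv(KNeighborsClassifier(), np.zeros((3, 2)), ["ACT", "INA", "ACT"], k=5)


@pytest.fixture(scope="module")
def members(separable_data):
    X, y = separable_data
    b1 = tune_and_train("RF", X, y, search_space=TINY_SPACES["RF"], seed=0, threshold=6)
    b2 = tune_and_train("KNN", X, y, search_space=TINY_SPACES["KNN"], seed=0, threshold=6)
    return b1, b2


class TestConsensus:
    def test_concordant_votes_emit_label(self, members, separable_data):
        X, y = separable_data
        cm = ConsensusModel(members=list(members))
        labels, scores = consensus_predict(cm, [X, X])
        deep_act = int(np.argmax(X[:, 0]))
        assert labels[deep_act] == "ACT"
        assert np.all((scores >= 0) & (scores <= 1))

    def test_discordance_abstains_and_conserves(self, members):
        b1, b2 = members
        rng = np.random.default_rng(4)
        X = rng.normal(0, 0.3, (200, 4))  # near the boundary: disagreements likely
        cm = ConsensusModel(members=[b1, b2])
        labels, _ = consensus_predict(cm, [X, X])
        n_pred = int(np.sum(labels != ABSTAIN))
        n_abst = int(np.sum(labels == ABSTAIN))
        assert n_pred + n_abst == 200
        disagree = predict_labels(b1, X) != predict_labels(b2, X)
        assert np.array_equal(labels == ABSTAIN, disagree)

    def test_consensus_ba_at_least_min_member(self, members, separable_data):
        X, y = separable_data
        rng = np.random.default_rng(5)
        Xn = X + rng.normal(0, 0.8, X.shape)
        cm = ConsensusModel(members=list(members))
        labels, _ = consensus_predict(cm, [Xn, Xn])
        keep = labels != ABSTAIN
        if keep.sum() and len(set(y[keep])) == 2:
            ba_cons = cooper_stats(confusion(list(y[keep]), list(labels[keep])))[2]
            member_bas = []
            for b in members:
                preds = predict_labels(b, Xn)
                member_bas.append(cooper_stats(confusion(list(y), list(preds)))[2])
            assert ba_cons >= min(member_bas) - 1e-9

    def test_threshold_mismatch_rejected(self, members, separable_data):
        X, y = separable_data
        b1, _ = members
        b3 = tune_and_train("KNN", X, y, search_space=TINY_SPACES["KNN"], seed=0, threshold=5)
        with pytest.raises(ModelingError):
            ConsensusModel(members=[b1, b3])

    def test_member_count_bounds(self, members):
        with pytest.raises(ModelingError):
            ConsensusModel(members=[members[0]])


class TestBundleIO:
    def test_save_load_round_trip(self, separable_data, tmp_path):
        from hergml.applicability_domain import fit_ad

        X, y = separable_data
        bundle = tune_and_train(
            "RF", X, y, search_space=TINY_SPACES["RF"], seed=0,
            selected_features=["f0", "f1", "f2", "f3"],
            norm_stats=pd.DataFrame({"mean": np.zeros(4), "sd": np.ones(4)},
                                    index=["f0", "f1", "f2", "f3"]),
        )
        bundle.ad = fit_ad(X)
        bundle.save(tmp_path / "b")
        back = TrainedModelBundle.load(tmp_path / "b")
        assert back.algorithm_id == "RF"
        assert back.selected_features == bundle.selected_features
        assert np.allclose(predict_proba(back, X), predict_proba(bundle, X))
        assert back.ad.p == bundle.ad.p
        assert np.allclose(back.ad.gram_inverse, bundle.ad.gram_inverse)
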