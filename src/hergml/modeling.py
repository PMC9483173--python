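"""Classifier training, tuning, and abstaining consensus prediction.

Seven algorithm identifiers are supported: BRF (balanced random forest with
equal-size per-class bootstraps), RF, KNN, GB, XGB, MLP, and SVM.
Hyperparameters are chosen by exhaustive grid search — except SVM and XGB,
which use a budgeted random search over the same kind of space — scored by
mean balanced accuracy over stratified 5-fold cross-validation; the winner
is refit on the full training data.

A consensus model combines two or three trained bundles sharing the same
potency threshold and emits a class call only when all members agree;
discordant rows are reported as ABSTAIN.  The consensus score is the mean of
the member probabilities.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from hergml.applicability_domain import ADModel
from hergml.balancing import balanced_bootstrap
from hergml.evaluation import ABSTAIN, ACT, INA, confusion, cooper_stats, mcc, auc

BUNDLE_FORMAT_VERSION = 1


class ModelingError(ValueError):
    pass


class BalancedRandomForestClassifier(BaseEstimator, ClassifierMixin):
    """Random forest whose per-tree bootstrap draws equal counts per class.

    Each tree is fit on a balanced bootstrap (minority-count draws with
    replacement from each class), removing the majority-class bias of an
    ordinary forest on unbalanced data.  Probabilities are the mean of the
    per-tree leaf probabilities.
    """

    def __init__(self, n_estimators: int = 100, max_features="sqrt", random_state=None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ModelingError("BRF needs both classes present")
        samples = balanced_bootstrap(y_idx, self.n_estimators, seed=self.random_state)
        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        for idx in samples:
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y_idx[idx])
            self.estimators_.append(tree)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        for tree in self.estimators_:
            p = tree.predict_proba(X)
            for local, cls_idx in enumerate(tree.classes_):
                proba[:, int(cls_idx)] += p[:, local]
        return proba / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _make_estimator(algorithm_id: str, params: dict, seed: Optional[int]):
    p = dict(params)
    if algorithm_id == "BRF":
        return BalancedRandomForestClassifier(random_state=seed, **p)
    if algorithm_id == "RF":
        return RandomForestClassifier(random_state=seed, **p)
    if algorithm_id == "KNN":
        return KNeighborsClassifier(**p)
    if algorithm_id == "GB":
        return GradientBoostingClassifier(random_state=seed, **p)
    if algorithm_id == "XGB":
        return XGBClassifier(random_state=seed, eval_metric="logloss", verbosity=0, **p)
    if algorithm_id == "MLP":
        return MLPClassifier(random_state=seed, max_iter=800, **p)
    if algorithm_id == "SVM":
        # Platt-scaled probabilities via calibration on the RBF SVC
        return CalibratedClassifierCV(SVC(random_state=seed, **p), ensemble=False)
    raise ModelingError(f"unknown algorithm {algorithm_id!r}")


#: Literature-standard default search spaces (overridable per call/config).
DEFAULT_SEARCH_SPACES: dict[str, dict[str, list]] = {
    "BRF": {"n_estimators": [100, 300], "max_features": ["sqrt", 0.3]},
    "RF": {"n_estimators": [100, 300], "max_features": ["sqrt", 0.3]},
    "KNN": {"n_neighbors": [3, 5, 7, 9]},
    "GB": {"n_estimators": [100, 300], "learning_rate": [0.05, 0.1, 0.3]},
    "XGB": {
        "n_estimators": [100, 300],
        "learning_rate": [0.05, 0.1, 0.3],
        "max_depth": [3, 5, 7],
        "subsample": [0.7, 1.0],
    },
    "MLP": {"hidden_layer_sizes": [(64,), (128,), (64, 64)]},
    "SVM": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 1e-3, 1e-2, 1e-1, 1.0]},
}

#: Families tuned by budgeted random search instead of an exhaustive grid.
RANDOM_SEARCH_FAMILIES = {"SVM", "XGB"}
DEFAULT_RANDOM_BUDGET = 10


@dataclass
class TrainedModelBundle:
    algorithm_id: str
    model: object
    hyperparameters: dict
    selected_features: list[str]
    norm_stats: Optional[pd.DataFrame]
    smote_used: bool
    threshold: int
    cv_metrics: dict
    master_seed: Optional[int]
    tuner: str = "grid"
    ad: Optional[ADModel] = None

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.model, d / "model.joblib")
        meta = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "algorithm_id": self.algorithm_id,
            "hyperparameters": _jsonable(self.hyperparameters),
            "selected_features": self.selected_features,
            "norm_stats": None
            if self.norm_stats is None
            else {
                "index": list(self.norm_stats.index),
                "mean": self.norm_stats["mean"].tolist(),
                "sd": self.norm_stats["sd"].tolist(),
            },
            "smote_used": self.smote_used,
            "threshold": self.threshold,
            "cv_metrics": _jsonable(self.cv_metrics),
            "master_seed": self.master_seed,
            "tuner": self.tuner,
            "ad": None
            if self.ad is None
            else {
                "gram_inverse": self.ad.gram_inverse.tolist(),
                "p": self.ad.p,
                "n": self.ad.n,
            },
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "TrainedModelBundle":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        if meta["format_version"] != BUNDLE_FORMAT_VERSION:
            raise ModelingError(f"unsupported bundle format {meta['format_version']}")
        ns = meta["norm_stats"]
        stats = (
            None
            if ns is None
            else pd.DataFrame({"mean": ns["mean"], "sd": ns["sd"]}, index=ns["index"])
        )
        ad_meta = meta.get("ad")
        ad = (
            None
            if ad_meta is None
            else ADModel(
                gram_inverse=np.asarray(ad_meta["gram_inverse"]),
                p=ad_meta["p"],
                n=ad_meta["n"],
            )
        )
        return cls(
            algorithm_id=meta["algorithm_id"],
            model=joblib.load(d / "model.joblib"),
            hyperparameters=meta["hyperparameters"],
            selected_features=meta["selected_features"],
            norm_stats=stats,
            smote_used=meta["smote_used"],
            threshold=meta["threshold"],
            cv_metrics=meta["cv_metrics"],
            master_seed=meta["master_seed"],
            tuner=meta.get("tuner", "grid"),
            ad=ad,
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _encode(y: Sequence) -> np.ndarray:
    """ACT -> 1, INA -> 0 (also accepts already-numeric labels)."""
    y = np.asarray(y)
    if y.dtype.kind in "iufb":
        return y.astype(int)
    return np.asarray([1 if v == ACT else 0 for v in y])


def _decode(y_enc: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(y_enc) == 1, ACT, INA)


def _grid_configs(space: dict[str, list]) -> list[dict]:
    keys = sorted(space)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(space[k] for k in keys))]


def _cv_balanced_accuracy(est, X, y_enc, k: int, seed: Optional[int]) -> float:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    bas = []
    for tr, te in skf.split(X, y_enc):
        m = clone(est)
        m.fit(X[tr], y_enc[tr])
        pred = m.predict(X[te])
        c = confusion(list(_decode(y_enc[te])), list(_decode(pred)))
        bas.append(cooper_stats(c)[2])
    return float(np.mean(bas))


def tune_and_train(
    algorithm_id: str,
    X_train: np.ndarray,
    y_train: Sequence,
    search_space: Optional[dict[str, list]] = None,
    budget: Optional[int] = None,
    seed: Optional[int] = None,
    threshold: int = 6,
    selected_features: Optional[Sequence[str]] = None,
    norm_stats: Optional[pd.DataFrame] = None,
    smote_used: bool = False,
    allow_brf_smote: bool = False,
) -> TrainedModelBundle:
    """Search the hyperparameter space by 5-fold CV BA and refit the winner.

    SVM and XGB use a budgeted random search (default 10 configurations)
    over the same space definition; everything else is an exhaustive grid.
    """
    if algorithm_id == "BRF" and smote_used and not allow_brf_smote:
        raise ModelingError(
            "BRF already balances by per-tree sampling; combining it with "
            "SMOTE double-balances (pass allow_brf_smote=True to override)"
        )
    X = np.asarray(X_train, dtype=float)
    y_enc = _encode(y_train)
    if len(np.unique(y_enc)) < 2:
        raise ModelingError("training labels must contain both classes")
    space = search_space if search_space is not None else DEFAULT_SEARCH_SPACES[algorithm_id]
    configs = _grid_configs(space)
    if not configs:
        raise ModelingError("empty hyperparameter grid")
    tuner = "grid"
    if algorithm_id in RANDOM_SEARCH_FAMILIES:
        tuner = "random"
        b = budget if budget is not None else DEFAULT_RANDOM_BUDGET
        if b < len(configs):
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(configs), size=b, replace=False)
            configs = [configs[i] for i in sorted(idx)]

    best_ba, best_cfg = -np.inf, None
    for cfg in configs:
        est = _make_estimator(algorithm_id, cfg, seed)
        ba = _cv_balanced_accuracy(est, X, y_enc, k=5, seed=seed)
        if ba > best_ba:
            best_ba, best_cfg = ba, cfg

    final = _make_estimator(algorithm_id, best_cfg, seed)
    final.fit(X, y_enc)
    cv = kfold_cv(_make_estimator(algorithm_id, best_cfg, seed), X, y_enc, k=5, seed=seed)
    return TrainedModelBundle(
        algorithm_id=algorithm_id,
        model=final,
        hyperparameters=best_cfg,
        selected_features=list(selected_features) if selected_features is not None else [],
        norm_stats=norm_stats,
        smote_used=smote_used,
        threshold=threshold,
        cv_metrics=cv,
        master_seed=seed,
        tuner=tuner,
    )


def predict_proba(bundle: TrainedModelBundle, X) -> np.ndarray:
    """Probability of the blocker (ACT) class, one score per row.

    A DataFrame input is checked against the bundle's selected features;
    missing and extra columns are named in the error.
    """
    if isinstance(X, pd.DataFrame):
        want = bundle.selected_features
        if want:
            missing = [c for c in want if c not in X.columns]
            extra = [c for c in X.columns if c not in set(want)]
            if missing:
                raise ModelingError(f"missing features {missing}; extra features {extra}")
            X = X[want]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    model = bundle.model
    proba = model.predict_proba(X)
    classes = list(getattr(model, "classes_", [0, 1]))
    return proba[:, classes.index(1)]


def predict_labels(bundle: TrainedModelBundle, X) -> np.ndarray:
    """Hard ACT/INA calls at the 0.5 probability cutoff."""
    return _decode(predict_proba(bundle, X) >= 0.5)


def kfold_cv(estimator, X: np.ndarray, y: Sequence, k: int = 5, seed: Optional[int] = None) -> dict:
    """Stratified k-fold metrics (SE/SP/BA/MCC/AUC per fold and their means)."""
    X = np.asarray(X, dtype=float)
    y_enc = _encode(y)
    if len(y_enc) < k:
        raise ModelingError(f"n={len(y_enc)} < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(X, y_enc):
        m = clone(estimator)
        m.fit(X[tr], y_enc[tr])
        labels = list(_decode(y_enc[te]))
        preds = list(_decode(m.predict(X[te])))
        proba = m.predict_proba(X[te])
        classes = list(m.classes_)
        scores = proba[:, classes.index(1)]
        c = confusion(labels, preds)
        se, sp, ba = cooper_stats(c)
        folds.append({"SE": se, "SP": sp, "BA": ba, "MCC": mcc(c), "AUC": auc(scores, labels)})
    means = {m: float(np.mean([f[m] for f in folds])) for m in ("SE", "SP", "BA", "MCC", "AUC")}
    return {"folds": folds, "mean": means, "k": k}


@dataclass
class ConsensusModel:
    """2-3 trained bundles voting by concordance (unanimity by default)."""

    members: list[TrainedModelBundle]
    rule: str = "unanimity"

    def __post_init__(self) -> None:
        if not 2 <= len(self.members) <= 3:
            raise ModelingError("consensus needs 2 or 3 members")
        thresholds = {m.threshold for m in self.members}
        if len(thresholds) != 1:
            raise ModelingError(f"members disagree on threshold: {sorted(thresholds)}")
        if self.rule not in ("unanimity", "majority"):
            raise ModelingError(f"unknown voting rule {self.rule!r}")

    @property
    def threshold(self) -> int:
        return self.members[0].threshold


def consensus_predict(
    consensus: ConsensusModel, X_per_member: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    """Concordance voting with abstention.

    ``X_per_member`` is one matrix per member (members may use different
    feature sets); pass the same matrix repeated when they share features.
    Returns (labels, scores): labels in {ACT, INA, ABSTAIN}; scores are the
    mean member probability (defined for every row, abstained or not).
    """
    if len(X_per_member) != len(consensus.members):
        raise ModelingError("one input matrix per member required")
    calls = np.vstack([
        predict_proba(m, X) >= 0.5 for m, X in zip(consensus.members, X_per_member)
    ])
    scores = np.vstack([
        predict_proba(m, X) for m, X in zip(consensus.members, X_per_member)
    ]).mean(axis=0)
    n = calls.shape[1]
    labels = np.full(n, ABSTAIN, dtype=object)
    n_pos = calls.sum(axis=0)
    n_members = len(consensus.members)
    if consensus.rule == "unanimity":
        labels[n_pos == n_members] = ACT
        labels[n_pos == 0] = INA
    else:
        labels[n_pos * 2 > n_members] = ACT
        labels[n_pos * 2 < n_members] = INA
    return labels, scores
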