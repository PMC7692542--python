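"""High/low attraction classification protocol.

Participants are labeled by a median split of the attraction composite
(ties go low: scores strictly above the median are "high"), randomly
partitioned 70/30 into training and test sets, features are selected on the
training set only (CFS, then SVM-RFE down to 23), and a random forest and a
multilayer perceptron — hyperparameters fixed to the documented grid — are
scored by five-fold cross-validation on the training set and once on the
held-out test set against the majority-class baseline.

By default the partition and the folds group by dyad (both members of a
dyad land on the same side of every split), because synchrony features are
dyad-level and would otherwise leak across the boundary; a participant-level
mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .config import ConfigError, PipelineConfig
from .core import DataError
from .selection import CFSSelector, SVMRFESelector

log = logging.getLogger(__name__)

LABELS = ("low", "high")  # low = negative class, high = positive class


def median_split(scores) -> np.ndarray:
    """Binary labels from a median split: score > median -> "high"."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise DataError("median split requires at least two scores")
    if np.all(scores == scores[0]):
        raise DataError("degenerate median split: all scores identical")
    median = np.median(scores)
    return np.where(scores > median, "high", "low")


@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    folds: dict = field(default_factory=dict)   # id -> fold number
    seed: int = 0


def _grouped_stratified_split(
    ids, labels, groups, train_fraction, rng
) -> tuple[list, list]:
    """70/30 split of whole groups, stratified by the group's label pattern."""
    df = pd.DataFrame({"id": ids, "label": labels, "group": groups})
    patterns = df.groupby("group")["label"].apply(
        lambda s: "".join(sorted(s))
    )
    train_groups: list = []
    test_groups: list = []
    for _, members in patterns.groupby(patterns):
        grp = list(members.index)
        rng.shuffle(grp)
        n_train = int(round(train_fraction * len(grp)))
        train_groups += grp[:n_train]
        test_groups += grp[n_train:]
    train_ids = list(df[df.group.isin(train_groups)]["id"])
    test_ids = list(df[df.group.isin(test_groups)]["id"])
    return train_ids, test_ids


def make_split(
    ids,
    labels,
    groups=None,
    train_fraction: float = 0.7,
    seed: int = 0,
    cv_folds: int = 5,
    group_by_dyad: bool = True,
) -> SplitPlan:
    """Random 70/30 train/test partition plus a 5-fold plan on the train set.

    Stratified by label where group sizes permit; when ``group_by_dyad`` both
    members of a dyad always fall on the same side of every split and fold.
    """
    ids = list(ids)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if group_by_dyad and groups is not None:
        groups = list(groups)
        train_ids, test_ids = _grouped_stratified_split(
            ids, labels, groups, train_fraction, rng
        )
        group_of = dict(zip(ids, groups))
        train_groups = list(dict.fromkeys(group_of[i] for i in train_ids))
        rng.shuffle(train_groups)
        fold_of_group = {g: k % cv_folds for k, g in enumerate(train_groups)}
        folds = {i: fold_of_group[group_of[i]] for i in train_ids}
    else:
        order = np.arange(len(ids))
        # stratified participant-level split
        train_idx: list[int] = []
        test_idx: list[int] = []
        for lab in np.unique(labels):
            stratum = order[labels == lab]
            rng.shuffle(stratum)
            n_train = int(round(train_fraction * len(stratum)))
            train_idx += list(stratum[:n_train])
            test_idx += list(stratum[n_train:])
        train_ids = [ids[i] for i in sorted(train_idx)]
        test_ids = [ids[i] for i in sorted(test_idx)]
        shuffled = list(train_ids)
        rng.shuffle(shuffled)
        folds = {i: k % cv_folds for k, i in enumerate(shuffled)}
    if set(train_ids) & set(test_ids):
        raise DataError("train and test sets overlap")
    return SplitPlan(train_ids, test_ids, folds, seed)


_RF_DOMAIN = {"n_estimators", "criterion", "max_depth", "max_features",
              "min_samples_leaf", "min_samples_split", "bootstrap",
              "random_state"}
_MLP_DOMAIN = {"hidden_layer_sizes", "activation", "alpha", "solver",
               "beta_1", "beta_2", "epsilon", "learning_rate",
               "learning_rate_init", "max_iter", "early_stopping", "shuffle",
               "tol", "n_iter_no_change", "random_state"}


def fit_random_forest(X, y, hyperparams: dict) -> RandomForestClassifier:
    """Random forest with the documented hyperparameter block.

    ``max_features`` is clamped to the available feature count when fewer
    features survived selection.
    """
    unknown = set(hyperparams) - _RF_DOMAIN
    if unknown:
        raise ConfigError(f"unknown random-forest hyperparameters: {sorted(unknown)}")
    X = np.asarray(X, dtype=float)
    if len(np.unique(y)) < 2:
        raise DataError("training labels contain a single class")
    params = dict(hyperparams)
    if isinstance(params.get("max_features"), int):
        clamped = min(params["max_features"], X.shape[1])
        if clamped != params["max_features"]:
            log.info("clamping max_features from %d to %d",
                     params["max_features"], clamped)
        params["max_features"] = clamped
    model = RandomForestClassifier(**params)
    model.fit(X, y)
    return model


def fit_mlp(X, y, hyperparams: dict) -> Pipeline:
    """Multilayer perceptron behind a training-set standardizer."""
    unknown = set(hyperparams) - _MLP_DOMAIN
    if unknown:
        raise ConfigError(f"unknown MLP hyperparameters: {sorted(unknown)}")
    if len(np.unique(y)) < 2:
        raise DataError("training labels contain a single class")
    params = dict(hyperparams)
    if isinstance(params.get("hidden_layer_sizes"), list):
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
    model = Pipeline([
        ("scale", StandardScaler()),
        ("mlp", MLPClassifier(**params)),
    ])
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        model.fit(np.asarray(X, dtype=float), y)
    n_iter = model.named_steps["mlp"].n_iter_
    if n_iter >= params.get("max_iter", 200):
        log.warning("MLP did not converge within %d iterations", n_iter)
    return model


def cross_validate_model(
    fit_fn, X, y, fold_assignment: np.ndarray
) -> tuple[float, float, list[float]]:
    """Mean and SD of held-out-fold accuracies for a model-fitting callable.

    Folds containing a single training class are skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    accs = []
    for fold in np.unique(fold_assignment):
        hold = fold_assignment == fold
        if len(np.unique(y[~hold])) < 2:
            log.warning("fold %s skipped: single-class training labels", fold)
            continue
        model = fit_fn(X[~hold], y[~hold])
        accs.append(float(np.mean(model.predict(X[hold]) == y[hold])))
    if not accs:
        raise DataError("no usable cross-validation folds")
    return float(np.mean(accs)), float(np.std(accs)), accs


@dataclass
class ClassifierReport:
    model_name: str
    cv_accuracy: float
    cv_sd: float
    fold_accuracies: list[float]
    test_accuracy: float
    majority_baseline: float
    confusion: dict
    sensitivity: float
    specificity: float
    selected_features: list[str]
    hyperparams: dict

    def as_dict(self) -> dict:
        return {
            "model": self.model_name,
            "cv_accuracy": self.cv_accuracy,
            "cv_sd": self.cv_sd,
            "fold_accuracies": self.fold_accuracies,
            "test_accuracy": self.test_accuracy,
            "majority_baseline": self.majority_baseline,
            "confusion": self.confusion,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "selected_features": self.selected_features,
            "hyperparameters": {k: str(v) for k, v in self.hyperparams.items()},
        }


def evaluate(model, X_test, y_test) -> dict:
    """Accuracy, confusion counts, sensitivity/specificity, majority baseline.

    "high" is the positive class; the baseline is the frequency of the most
    common class among the test labels.
    """
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise DataError("empty test set")
    pred = model.predict(np.asarray(X_test, dtype=float))
    tp = int(np.sum((pred == "high") & (y_test == "high")))
    tn = int(np.sum((pred == "low") & (y_test == "low")))
    fp = int(np.sum((pred == "high") & (y_test == "low")))
    fn = int(np.sum((pred == "low") & (y_test == "high")))
    total = len(y_test)
    majority = max(np.mean(y_test == "high"), np.mean(y_test == "low"))
    return {
        "accuracy": (tp + tn) / total,
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "majority_baseline": float(majority),
    }


def run_classification(
    table: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    seed: int | None = None,
) -> dict[str, ClassifierReport]:
    """Full protocol on a feature table holding an ``attraction`` column.

    Labels participants by median split, partitions 70/30 (dyad-grouped by
    default), selects features with CFS then SVM-RFE on the training rows
    only, and reports cross-validated and test performance of both
    classifiers.
    """
    cfg = cfg or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    outcome_cols = {"dyad_id", "attraction", "impression_accuracy",
                    "affective_valence"}
    feature_cols = [c for c in table.columns
                    if c not in outcome_cols and table[c].dtype != object]
    labels = median_split(table["attraction"].to_numpy())
    plan = make_split(
        list(table.index), labels,
        groups=list(table["dyad_id"]) if "dyad_id" in table else None,
        train_fraction=cfg.train_fraction, seed=seed,
        cv_folds=cfg.cv_folds, group_by_dyad=cfg.group_by_dyad,
    )
    label_of = dict(zip(table.index, labels))
    X = table[feature_cols]
    X_train = X.loc[plan.train_ids].to_numpy(dtype=float)
    y_train = np.array([label_of[i] for i in plan.train_ids])
    X_test = X.loc[plan.test_ids].to_numpy(dtype=float)
    y_test = np.array([label_of[i] for i in plan.test_ids])
    y01 = (y_train == "high").astype(float)

    cfs = CFSSelector().fit(X_train, y01)
    kept = cfs.selected_
    if len(kept) > cfg.rfe_target_k:
        rfe = SVMRFESelector(target_k=cfg.rfe_target_k, random_state=seed)
        rfe.fit(X_train[:, kept], y01)
        kept = kept[rfe.selected_]
    selected_names = [feature_cols[i] for i in kept]
    log.info("selected %d features", len(selected_names))

    Xtr = X_train[:, kept]
    Xte = X_test[:, kept]
    folds = np.array([plan.folds[i] for i in plan.train_ids])

    reports = {}
    for name, params, fitter in (
        ("random_forest", cfg.random_forest, fit_random_forest),
        ("mlp", cfg.mlp, fit_mlp),
    ):
        fit_fn = lambda Xf, yf, p=params, f=fitter: f(Xf, yf, p)
        cv_mean, cv_sd, accs = cross_validate_model(fit_fn, Xtr, y_train, folds)
        model = fit_fn(Xtr, y_train)
        ev = evaluate(model, Xte, y_test)
        reports[name] = ClassifierReport(
            model_name=name,
            cv_accuracy=cv_mean, cv_sd=cv_sd, fold_accuracies=accs,
            test_accuracy=ev["accuracy"],
            majority_baseline=ev["majority_baseline"],
            confusion=ev["confusion"],
            sensitivity=ev["sensitivity"], specificity=ev["specificity"],
            selected_features=selected_names,
            hyperparams=params,
        )
    return reports
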