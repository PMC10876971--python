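"""Boosted classifier for ecDNA cargo genes under extreme class imbalance.

The training protocol: random hyperparameter search, stratified group
k-fold cross-validation (all rows of one tumor sample stay in one fold,
folds balanced on sample-level positivity), early stopping when the
held-out area under the precision-recall curve (auPRC) stops improving,
then a final refit on all data at the winning configuration.  auPRC is the
primary metric because cargo genes are a ~0.35% minority: under such
imbalance ROC area saturates while precision-recall remains informative.

Missing feature values (tumor-only minor_cn/pLOH, genes with no overlapping
segment) are routed natively by the gradient-boosted trees; the
copy-number-only logistic baseline median-imputes instead.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from .feature_engineering import FEATURE_COLUMNS

log = logging.getLogger(__name__)

DEFAULT_SEARCH_SPACE: dict[str, tuple] = {
    "eta": ("loguniform", 0.01, 0.3),
    "max_depth": ("choice", [3, 4, 5, 6, 7, 8]),
    "subsample": ("uniform", 0.5, 1.0),
    "colsample_bytree": ("uniform", 0.5, 1.0),
    "min_child_weight": ("choice", [1, 5, 10]),
    "scale_pos_weight": ("choice", [1.0, "balanced"]),
}


@dataclass
class ModelConfig:
    """Training protocol configuration (defaults match the published scale:
    10 folds, 1000 random-search draws, patience 10, at most 500 rounds)."""

    k_folds: int = 10
    n_search: int = 1000
    patience: int = 10
    max_rounds: int = 500
    search_space: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_SEARCH_SPACE)
    )
    seed: int = 0
    p_cut: float = 0.5

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_search < 1:
            raise ValueError("n_search must be >= 1")


@dataclass
class EvalMetrics:
    auPRC: float
    auROC: float
    precision: float  # NaN when there are no predicted positives
    sensitivity: float
    specificity: float


@dataclass
class TrainedClassifier:
    booster: xgb.Booster
    feature_names: list[str]
    hyperparameters: dict
    best_rounds: int
    cv_history: pd.DataFrame  # trial, fold, best_iteration, val_auprc
    cv_auprc: float  # mean held-out auPRC of the winning trial
    p_cut: float = 0.5

    def save(self, path) -> None:
        raw = self.booster.save_raw(raw_format="json").decode()
        payload = {
            "format_version": 1,
            "feature_names": self.feature_names,
            "hyperparameters": self.hyperparameters,
            "best_rounds": self.best_rounds,
            "cv_auprc": self.cv_auprc,
            "p_cut": self.p_cut,
            "cv_history": self.cv_history.to_dict(orient="list"),
            "booster": json.loads(raw),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(payload["booster"]).encode()))
        return cls(
            booster=booster,
            feature_names=payload["feature_names"],
            hyperparameters=payload["hyperparameters"],
            best_rounds=payload["best_rounds"],
            cv_history=pd.DataFrame(payload["cv_history"]),
            cv_auprc=payload["cv_auprc"],
            p_cut=payload["p_cut"],
        )


# ---------------------------------------------------------------------------
# metrics


def _check_two_classes(labels: np.ndarray) -> None:
    u = np.unique(labels)
    if len(u) < 2:
        raise ValueError("both classes must be present")


def average_precision(labels, scores) -> float:
    """Step-wise average precision (sum of precision at each recall
    increment); tied scores are grouped at one threshold."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def auroc(labels, scores) -> float:
    """ROC area = Mann-Whitney concordance probability, ties counted 1/2."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def threshold_metrics(labels, scores, cutoff: float) -> tuple[float, float, float]:
    """(precision, sensitivity, specificity) at ``score >= cutoff``.

    With no predicted positives, precision is undefined and reported NaN.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    if tp + fp == 0:
        log.warning("no predicted positives at cutoff %.3g; precision undefined", cutoff)
        precision = float("nan")
    else:
        precision = tp / (tp + fp)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return precision, sensitivity, specificity


# ---------------------------------------------------------------------------
# cross-validation


def stratified_group_kfold(
    groups, group_labels, k: int, seed: int = 0
) -> dict[str, int]:
    """Assign each group to one of ``k`` folds, balancing the number of
    positive groups per fold as evenly as integer counts allow.

    Deterministic for a given seed: groups are shuffled, then positive and
    negative groups are dealt round-robin.
    """
    groups = list(groups)
    labels = list(group_labels)
    if len(groups) != len(labels):
        raise ValueError("groups and group_labels must align")
    if len(set(groups)) != len(groups):
        raise ValueError("groups must be unique")
    if k > len(groups):
        raise ValueError(f"k={k} exceeds number of groups ({len(groups)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    pos = [groups[i] for i in order if labels[i]]
    neg = [groups[i] for i in order if not labels[i]]
    assignment: dict[str, int] = {}
    for i, g in enumerate(pos):
        assignment[g] = i % k
    for i, g in enumerate(neg):
        # continue dealing so folds stay size-balanced overall
        assignment[g] = (len(pos) + i) % k
    return assignment


def _sample_params(space: dict[str, tuple], rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "loguniform":
            lo, hi = math.log(spec[1]), math.log(spec[2])
            out[name] = float(math.exp(rng.uniform(lo, hi)))
        elif kind == "uniform":
            out[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "choice":
            out[name] = spec[1][int(rng.integers(len(spec[1])))]
        else:
            raise ValueError(f"unknown distribution kind {kind!r}")
    return out


def _as_matrix(features: pd.DataFrame) -> np.ndarray:
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    return features[FEATURE_COLUMNS].to_numpy(dtype=float)


def train(table: pd.DataFrame, config: ModelConfig | None = None) -> TrainedClassifier:
    """Random-search + grouped-CV training of the boosted cargo-gene model.

    ``table`` holds the identifier columns, the 11 features and a binary
    ``label`` column; rows sharing a ``sample_id`` never straddle folds.
    """
    if config is None:
        config = ModelConfig()
    labels = table["label"].to_numpy(dtype=int)
    _check_two_classes(labels)
    X = _as_matrix(table)
    groups = table["sample_id"].to_numpy()

    group_ids = list(pd.unique(groups))
    group_pos = table.groupby("sample_id", sort=False)["label"].max()
    assignment = stratified_group_kfold(
        group_ids, [int(group_pos[g]) for g in group_ids], config.k_folds, config.seed
    )
    fold_of_row = np.array([assignment[g] for g in groups])

    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    rng = np.random.default_rng(config.seed)

    folds = []
    for f in range(config.k_folds):
        val = fold_of_row == f
        if labels[val].sum() == 0 or labels[~val].sum() == 0:
            log.warning("fold %d has a single-class split; still evaluated", f)
        folds.append(
            (
                xgb.DMatrix(X[~val], label=labels[~val], feature_names=FEATURE_COLUMNS),
                xgb.DMatrix(X[val], label=labels[val], feature_names=FEATURE_COLUMNS),
                labels[val],
            )
        )

    base_params = {
        "objective": "binary:logistic",
        "eval_metric": "aucpr",
        "tree_method": "hist",
        "nthread": 1,
        "seed": int(config.seed % (2**31)),
    }

    history_rows = []
    best: tuple[float, dict, float] | None = None  # (mean_auprc, params, mean_rounds)
    for trial in range(config.n_search):
        sampled = _sample_params(config.search_space, rng)
        params = dict(base_params)
        for k_, v in sampled.items():
            params[k_] = (n_neg / max(n_pos, 1)) if v == "balanced" else v
        fold_scores, fold_rounds = [], []
        for fold_idx, (dtrain, dval, yval) in enumerate(folds):
            evals_result: dict = {}
            bst = xgb.train(
                params,
                dtrain,
                num_boost_round=config.max_rounds,
                evals=[(dval, "val")],
                early_stopping_rounds=config.patience,
                evals_result=evals_result,
                verbose_eval=False,
            )
            n_rounds = bst.best_iteration + 1
            pred = bst.predict(dval, iteration_range=(0, n_rounds))
            try:
                score = average_precision(yval, pred)
            except ValueError:  # single-class validation fold
                score = float("nan")
            fold_scores.append(score)
            fold_rounds.append(n_rounds)
            history_rows.append(
                {
                    "trial": trial,
                    "fold": fold_idx,
                    "best_iteration": n_rounds,
                    "val_auprc": score,
                }
            )
        mean_score = float(np.nanmean(fold_scores))
        if best is None or mean_score > best[0]:
            best = (mean_score, dict(params), float(np.mean(fold_rounds)))

    assert best is not None
    mean_auprc, best_params, mean_rounds = best
    best_rounds = max(1, int(round(mean_rounds)))
    dall = xgb.DMatrix(X, label=labels, feature_names=FEATURE_COLUMNS)
    final = xgb.train(best_params, dall, num_boost_round=best_rounds)

    return TrainedClassifier(
        booster=final,
        feature_names=list(FEATURE_COLUMNS),
        hyperparameters={
            k_: v for k_, v in best_params.items() if k_ not in ("nthread",)
        },
        best_rounds=best_rounds,
        cv_history=pd.DataFrame(history_rows),
        cv_auprc=mean_auprc,
        p_cut=config.p_cut,
    )


def predict_gene_prob(model: TrainedClassifier, features: pd.DataFrame) -> np.ndarray:
    """Per-row cargo-gene probability in [0, 1]; missing feature values are
    routed natively by the trees."""
    X = _as_matrix(features)
    dmat = xgb.DMatrix(X, feature_names=model.feature_names)
    return model.booster.predict(dmat)


def evaluate_sample_level(
    model: TrainedClassifier, features: pd.DataFrame, gene_labels
) -> EvalMetrics:
    """Sample-level metrics: sample score = max gene probability within the
    sample; a sample is truly positive iff it has >= 1 true cargo gene."""
    probs = predict_gene_prob(model, features)
    df = pd.DataFrame(
        {
            "sample_id": features["sample_id"].to_numpy(),
            "prob": probs,
            "label": np.asarray(gene_labels, dtype=int),
        }
    )
    agg = df.groupby("sample_id").agg(score=("prob", "max"), truth=("label", "max"))
    precision, sensitivity, specificity = threshold_metrics(
        agg["truth"], agg["score"], model.p_cut
    )
    return EvalMetrics(
        auPRC=average_precision(agg["truth"], agg["score"]),
        auROC=auroc(agg["truth"], agg["score"]),
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
    )


# ---------------------------------------------------------------------------
# copy-number-only baseline


@dataclass
class CnOnlyBaseline:
    """Single-feature logistic model on total_cn (median-imputed)."""

    model: LogisticRegression
    impute_value: float
    p_cut: float = 0.5

    def predict_prob(self, features: pd.DataFrame) -> np.ndarray:
        x = features["total_cn"].to_numpy(dtype=float)
        x = np.where(np.isnan(x), self.impute_value, x).reshape(-1, 1)
        return self.model.predict_proba(x)[:, 1]


def train_cn_only_baseline(table: pd.DataFrame) -> CnOnlyBaseline:
    labels = table["label"].to_numpy(dtype=int)
    _check_two_classes(labels)
    x = table["total_cn"].to_numpy(dtype=float)
    med = float(np.nanmedian(x))
    x = np.where(np.isnan(x), med, x)
    if np.all(x == x[0]):
        raise ValueError("total_cn is constant; baseline is degenerate")
    lr = LogisticRegression(max_iter=1000)
    lr.fit(x.reshape(-1, 1), labels)
    return CnOnlyBaseline(model=lr, impute_value=med)


def cv_baseline_auprc(table: pd.DataFrame, k: int, seed: int = 0) -> float:
    """Mean held-out auPRC of the copy-number-only logistic baseline under
    the same grouped, stratified folds used for the boosted model."""
    labels = table["label"].to_numpy(dtype=int)
    _check_two_classes(labels)
    groups = table["sample_id"].to_numpy()
    group_ids = list(pd.unique(groups))
    group_pos = table.groupby("sample_id", sort=False)["label"].max()
    assignment = stratified_group_kfold(
        group_ids, [int(group_pos[g]) for g in group_ids], k, seed
    )
    fold_of_row = np.array([assignment[g] for g in groups])
    scores = []
    for f in range(k):
        val = fold_of_row == f
        try:
            base = train_cn_only_baseline(table[~val])
            scores.append(average_precision(labels[val], base.predict_prob(table[val])))
        except ValueError:
            scores.append(float("nan"))
    return float(np.nanmean(scores))


def out_of_fold_probs(
    table: pd.DataFrame, model: TrainedClassifier, k: int, seed: int = 0
) -> np.ndarray:
    """Out-of-fold probabilities: refit the winning configuration per fold
    (same grouped folds) and score each row with the model that never saw
    its sample.  Gives an honest held-out view for sample-level metrics."""
    labels = table["label"].to_numpy(dtype=int)
    X = _as_matrix(table)
    groups = table["sample_id"].to_numpy()
    group_ids = list(pd.unique(groups))
    group_pos = table.groupby("sample_id", sort=False)["label"].max()
    assignment = stratified_group_kfold(
        group_ids, [int(group_pos[g]) for g in group_ids], k, seed
    )
    fold_of_row = np.array([assignment[g] for g in groups])
    params = dict(model.hyperparameters)
    params["nthread"] = 1
    oof = np.zeros(len(table))
    for f in range(k):
        val = fold_of_row == f
        dtrain = xgb.DMatrix(X[~val], label=labels[~val], feature_names=FEATURE_COLUMNS)
        dval = xgb.DMatrix(X[val], feature_names=FEATURE_COLUMNS)
        bst = xgb.train(params, dtrain, num_boost_round=model.best_rounds)
        oof[val] = bst.predict(dval)
    return oof


def feature_importance(model: TrainedClassifier) -> dict[str, float]:
    """Normalized gain shares per feature (>= 0, summing to 1)."""
    if model.booster is None:
        raise ValueError("untrained model")
    raw = model.booster.get_score(importance_type="gain")
    shares = {f: float(raw.get(f, 0.0)) for f in model.feature_names}
    total = sum(shares.values())
    if total <= 0:
        # a stump-only model never split: spread uniformly
        return {f: 1.0 / len(shares) for f in shares}
    return {f: v / total for f, v in shares.items()}
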