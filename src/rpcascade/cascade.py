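"""Cascaded classifier stage: labelled-set assembly, training, rescoring.

The cascade treats an upstream predictor's scores as input features rather
than final answers: validated positives and uniformly sampled unvalidated
pairs (presumed negatives) are described by their RP context features, a
tree-ensemble classifier is trained on them, and its probability output
becomes the refined score for every pair. Two model families are
supported: a gradient-boosted tree ensemble (xgboost) and a random forest
(scikit-learn), with defaults fixed at the tuned values.

Hold-out discipline follows the recency principle: positives carrying the
configured recency tag (validated only in the newest database release)
form the test set, which guards against leakage through the upstream
predictor's own training data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from .score_store import LabelSet, ScoreTable

__all__ = [
    "SplitConfig",
    "GBMParams",
    "RFParams",
    "ModelConfig",
    "FittedModel",
    "sample_negatives",
    "split_labels",
    "train",
    "predict",
    "dos",
    "save_model",
    "load_model",
]


@dataclass
class SplitConfig:
    test_tag: str | None = None  # recency label marking test positives
    test_fraction: float = 0.05  # used only when no tag is given
    balance: bool = True
    seed: int = 0


@dataclass
class GBMParams:
    learning_rate: float = 0.3
    gamma: float = 0.0
    max_depth: int = 6
    rounds: int = 200
    early_stopping: int = 5
    objective: str = "binary:logistic"
    eval_metric: str = "auc"
    validation_fraction: float = 0.1  # carved from training rows for early stopping


@dataclass
class RFParams:
    n_trees: int = 100
    max_depth: int = 19
    max_features_per_split: int = 4  # absolute count of candidate features per split


@dataclass
class ModelConfig:
    kind: str = "gbm"  # "gbm" | "rf"
    gbm: GBMParams = field(default_factory=GBMParams)
    rf: RFParams = field(default_factory=RFParams)

    def __post_init__(self) -> None:
        if self.kind not in ("gbm", "rf"):
            raise ValueError(f"kind must be 'gbm' or 'rf', got {self.kind!r}")


@dataclass
class FittedModel:
    estimator: object
    kind: str
    columns: list[str]
    config: ModelConfig
    seed: int
    best_iteration: int | None
    feature_importance: pd.Series

    @property
    def schema_hash(self) -> str:
        return hashlib.sha256("\x1f".join(self.columns).encode()).hexdigest()[:16]


def sample_negatives(
    table: ScoreTable,
    labels: LabelSet,
    count: int,
    seed: int,
    *,
    exclude: set[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """Uniform sample (without replacement) of scored, unvalidated pairs.

    ``exclude`` removes additional pairs from the pool (e.g. negatives
    already drawn for another partition, to keep partitions disjoint).
    """
    banned = set(labels.positives)
    if exclude:
        banned |= exclude
    pool = [(a, b) for a, b, _ in table.pairs if (a, b) not in banned]
    if count > len(pool):
        raise ValueError(f"requested {count} negatives but pool holds only {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=count, replace=False)
    return [pool[i] for i in sorted(idx)]


def split_labels(labels: LabelSet, cfg: SplitConfig) -> tuple[list, list]:
    """Partition positives into train/test by recency tag or seeded fraction."""
    positives = sorted(labels.positives)
    if cfg.test_tag is not None:
        test = [p for p in positives if labels.recency_tag.get(p) == cfg.test_tag]
        train_ = [p for p in positives if labels.recency_tag.get(p) != cfg.test_tag]
        if not test:
            raise ValueError(f"no positive carries the test tag {cfg.test_tag!r}")
    else:
        rng = np.random.default_rng(cfg.seed)
        n_test = int(round(cfg.test_fraction * len(positives)))
        mask = np.zeros(len(positives), dtype=bool)
        mask[rng.choice(len(positives), size=n_test, replace=False)] = True
        test = [p for p, m in zip(positives, mask) if m]
        train_ = [p for p, m in zip(positives, mask) if not m]
    if not train_ or not test:
        raise ValueError("split produced an empty train or test side")
    return train_, test


def train(
    features: pd.DataFrame,
    y: np.ndarray,
    cfg: ModelConfig | None = None,
    seed: int = 0,
) -> FittedModel:
    """Fit the cascaded classifier on an RP feature matrix.

    The gbm variant holds out a seeded fraction of the training rows as the
    early-stopping evaluation set; the rf variant fits on all rows.
    """
    cfg = cfg or ModelConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    columns = list(features.columns)

    if cfg.kind == "gbm":
        p = cfg.gbm
        rng = np.random.default_rng(seed)
        n = len(y)
        n_val = max(2, int(round(p.validation_fraction * n)))
        val_idx = np.zeros(n, dtype=bool)
        val_idx[rng.choice(n, size=n_val, replace=False)] = True
        if len(np.unique(y[~val_idx])) < 2 or len(np.unique(y[val_idx])) < 2:
            # tiny or skewed input: refit the holdout stratified
            val_idx = np.zeros(n, dtype=bool)
            for cls in np.unique(y):
                cls_pos = np.flatnonzero(y == cls)
                k = max(1, int(round(p.validation_fraction * len(cls_pos))))
                val_idx[rng.choice(cls_pos, size=k, replace=False)] = True
        est = XGBClassifier(
            n_estimators=p.rounds,
            learning_rate=p.learning_rate,
            gamma=p.gamma,
            max_depth=p.max_depth,
            objective=p.objective,
            eval_metric=p.eval_metric,
            early_stopping_rounds=p.early_stopping,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
        est.fit(X[~val_idx], y[~val_idx], eval_set=[(X[val_idx], y[val_idx])], verbose=False)
        best_iter = int(est.best_iteration)
        gains = est.get_booster().get_score(importance_type="gain")
        importance = pd.Series(
            [gains.get(f"f{i}", 0.0) for i in range(len(columns))], index=columns
        )
    else:
        p = cfg.rf
        est = RandomForestClassifier(
            n_estimators=p.n_trees,
            max_depth=p.max_depth,
            max_features=min(p.max_features_per_split, len(columns)),
            random_state=seed,
            n_jobs=1,
        )
        est.fit(X, y)
        best_iter = None
        importance = pd.Series(est.feature_importances_, index=columns)

    return FittedModel(est, cfg.kind, columns, cfg, seed, best_iter, importance)


def predict(model: FittedModel, features: pd.DataFrame) -> np.ndarray:
    """Refined probability-scale scores in [0, 1] for a feature matrix."""
    missing = [c for c in model.columns if c not in features.columns]
    extra = [c for c in features.columns if c not in model.columns]
    if missing or extra:
        raise ValueError(f"feature schema mismatch: missing {missing}, extra {extra}")
    X = features[model.columns].to_numpy(dtype=float)
    return model.estimator.predict_proba(X)[:, 1]


def dos(refined, original) -> np.ndarray:
    """Difference of Scores: refined minus original, elementwise.

    Large positive values flag pairs the original predictor scored low but
    the cascade scores high — putative false negatives of the original.
    """
    refined = np.asarray(refined, dtype=float)
    original = np.asarray(original, dtype=float)
    if refined.shape != original.shape:
        raise ValueError(f"length mismatch: {refined.shape} vs {original.shape}")
    return refined - original


def save_model(model: FittedModel, path) -> None:
    joblib.dump(
        {
            "estimator": model.estimator,
            "kind": model.kind,
            "columns": model.columns,
            "config": model.config,
            "seed": model.seed,
            "best_iteration": model.best_iteration,
            "feature_importance": model.feature_importance,
            "schema_hash": model.schema_hash,
        },
        path,
    )


def load_model(path) -> FittedModel:
    blob = joblib.load(path)
    model = FittedModel(
        blob["estimator"],
        blob["kind"],
        blob["columns"],
        blob["config"],
        blob["seed"],
        blob["best_iteration"],
        blob["feature_importance"],
    )
    if model.schema_hash != blob["schema_hash"]:
        raise ValueError("stored schema hash does not match column list")
    return model
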