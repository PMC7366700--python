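"""End-to-end orchestration of the cascaded rescoring workflow.

Ties the stages together: filter labels against the score table, build
per-entity curves and baselines, extract RP features, assemble balanced
train/test datasets with recency-aware splitting and per-partition
negative sampling, train the cascade, and score test pairs. Exists so the
CLI, the examples and the evaluation scripts share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cascade, evaluation
from .cascade import FittedModel, ModelConfig, SplitConfig
from .features import batch_features
from .o2a import baselines_for_table
from .score_store import LabelSet, ScoreTable, filter_labels

__all__ = ["Datasets", "PipelineResult", "assemble_datasets", "run_pipeline"]


@dataclass
class Datasets:
    train_pairs: list[tuple[str, str]]
    train_y: np.ndarray
    test_pairs: list[tuple[str, str]]
    test_y: np.ndarray


@dataclass
class PipelineResult:
    model: FittedModel
    datasets: Datasets
    train_X: pd.DataFrame
    test_X: pd.DataFrame
    refined_test: np.ndarray  # cascade scores on test pairs
    original_test: np.ndarray  # raw input scores on test pairs
    report: evaluation.EvalReport | None


def assemble_datasets(
    table: ScoreTable,
    labels: LabelSet,
    split: SplitConfig,
) -> Datasets:
    """Balanced, disjoint train/test pair sets with sampled negatives.

    Positives are partitioned by recency tag (or a seeded fraction);
    negatives are drawn uniformly from scored unvalidated pairs,
    separately per partition so train and test never share a row.
    """
    train_pos, test_pos = cascade.split_labels(labels, split)
    n_train_neg = len(train_pos) if split.balance else 0
    n_test_neg = len(test_pos) if split.balance else 0
    test_neg = cascade.sample_negatives(table, labels, n_test_neg, split.seed + 1)
    train_neg = cascade.sample_negatives(
        table, labels, n_train_neg, split.seed + 2, exclude=set(test_neg)
    )
    train_pairs = train_pos + train_neg
    test_pairs = test_pos + test_neg
    train_y = np.r_[np.ones(len(train_pos)), np.zeros(len(train_neg))].astype(int)
    test_y = np.r_[np.ones(len(test_pos)), np.zeros(len(test_neg))].astype(int)
    return Datasets(train_pairs, train_y, test_pairs, test_y)


def run_pipeline(
    table: ScoreTable,
    labels: LabelSet,
    split: SplitConfig | None = None,
    model_cfg: ModelConfig | None = None,
    *,
    seed: int = 0,
    n_boot: int = 0,
    span: float = 0.3,
    sensitivity: float = 1.0,
) -> PipelineResult:
    """Filter, featurize, train and score; optionally bootstrap-evaluate.

    When ``n_boot > 0`` the result carries a paired-bootstrap comparison of
    the cascade's refined score against the raw input score on the test set.
    """
    split = split or SplitConfig(test_tag=None, seed=seed)
    table, labels, _ = filter_labels(table, labels)
    curves, baselines = baselines_for_table(table, span=span, sensitivity=sensitivity)
    data = assemble_datasets(table, labels, split)
    train_X = batch_features(curves, baselines, data.train_pairs)
    test_X = batch_features(curves, baselines, data.test_pairs)
    model = cascade.train(train_X, data.train_y, model_cfg, seed=seed)
    refined = cascade.predict(model, test_X)
    original = test_X["raw_score"].to_numpy()
    report = None
    if n_boot > 0:
        report = evaluation.compare_models(
            {"refined": refined, "original": original}, data.test_y, n_boot=n_boot, seed=seed
        )
    return PipelineResult(model, data, train_X, test_X, refined, original, report)
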