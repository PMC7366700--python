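"""Synthetic score tables with the reciprocal structure the cascade exploits.

The generator emulates the shape of an integrative miRNA-target score
table: sparse coverage of the bipartite pair space, per-entity view sizes
that vary, and — crucially — per-entity additive score offsets. Each
A-entity (miRNA-like) and B-entity (gene-like) draws a latent offset
``~ Normal(0, baseline_spread)``; a scored pair's logit is the sum of its
two offsets plus noise, and planted positives add a fixed ``signal`` lift:

    score(a, b) = sigmoid(offset_a + offset_b + signal * positive + noise)

The offsets are what make one global threshold suboptimal: a true
interaction of a low-offset entity can score below a non-interaction of a
high-offset one. Local, per-entity thresholds — what the RP features
encode — recover the planted structure, so the generator provides a
ground-truth setting where context features provably help.

A configurable fraction of positives is tagged ``"test_recent"`` so the
recency-based train/test split can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .score_store import LabelSet, ScoreTable

__all__ = ["SynthConfig", "SynthTruth", "generate", "two_slope_curve"]

TEST_TAG = "test_recent"


@dataclass
class SynthConfig:
    """Study conditions for the synthetic bipartite score table.

    Defaults give a 60 x 400 table at 60% density (~14,400 scored pairs):
    desk-scale, yet the A axis yields dense (n > 100) curves that exercise
    the LOESS+Kneedle baseline branch while the B axis yields sparse
    (n <= 100) curves that exercise the median branch.
    """

    n_a: int = 60
    n_b: int = 400
    density: float = 0.6  # fraction of all pairs that carry a score
    pos_rate: float = 0.1  # fraction of scored pairs planted positive
    baseline_spread: float = 1.5  # sd of per-entity latent offsets (logit scale)
    signal: float = 2.0  # logit lift of planted positives
    noise_sd: float = 0.5  # logit-scale score noise
    knee_frac: float = 0.1  # intended head fraction above each entity's knee
    test_tag_frac: float = 0.15  # fraction of positives tagged as recent (test)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("density", "pos_rate", "knee_frac"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_a * self.n_b * self.density < 100:
            raise ValueError("configuration yields fewer than 100 scored pairs")


@dataclass
class SynthTruth:
    """Ground truth: per-pair planted labels and per-entity latent state."""

    pairs: pd.DataFrame  # entity_a, entity_b, score, positive, tag
    entities: pd.DataFrame  # axis, entity_id, offset, n_pairs, pos_frac (intended head)
    dropped: list[tuple[str, str]] = field(default_factory=list)


def generate(cfg: SynthConfig) -> tuple[ScoreTable, LabelSet, SynthTruth]:
    """Draw a synthetic (ScoreTable, LabelSet, SynthTruth) triple.

    Byte-reproducible for a fixed seed. Entities that end up with zero
    scored pairs (possible at very low density) are dropped and listed in
    ``truth.dropped``.
    """
    rng = np.random.default_rng(cfg.seed)
    a_ids = [f"mir{i:03d}" for i in range(cfg.n_a)]
    b_ids = [f"gene{j:04d}" for j in range(cfg.n_b)]
    off_a = rng.normal(0.0, cfg.baseline_spread, cfg.n_a)
    off_b = rng.normal(0.0, cfg.baseline_spread, cfg.n_b)

    total = cfg.n_a * cfg.n_b
    n_scored = int(round(cfg.density * total))
    flat = rng.choice(total, size=n_scored, replace=False)
    flat.sort()
    ai, bi = np.divmod(flat, cfg.n_b)

    n_pos = int(round(cfg.pos_rate * n_scored))
    pos_mask = np.zeros(n_scored, dtype=bool)
    pos_mask[rng.choice(n_scored, size=n_pos, replace=False)] = True

    logit = off_a[ai] + off_b[bi] + cfg.signal * pos_mask + rng.normal(0.0, cfg.noise_sd, n_scored)
    scores = np.clip(expit(logit), 1e-6, 1.0 - 1e-6)

    tag_mask = np.zeros(n_scored, dtype=bool)
    pos_idx = np.flatnonzero(pos_mask)
    n_tag = int(round(cfg.test_tag_frac * n_pos))
    if n_tag:
        tag_mask[rng.choice(pos_idx, size=n_tag, replace=False)] = True

    pairs = [(a_ids[i], b_ids[j], float(s)) for i, j, s in zip(ai, bi, scores)]
    table = ScoreTable.from_pairs(pairs)
    dropped = [("A", a) for a in a_ids if a not in table.index_a]
    dropped += [("B", b) for b in b_ids if b not in table.index_b]

    positives = {(a_ids[i], b_ids[j]) for i, j in zip(ai[pos_mask], bi[pos_mask])}
    tags = {(a_ids[i], b_ids[j]): TEST_TAG for i, j in zip(ai[tag_mask], bi[tag_mask])}
    labels = LabelSet(positives=positives, recency_tag=tags)

    truth_pairs = pd.DataFrame(
        {
            "entity_a": [a_ids[i] for i in ai],
            "entity_b": [b_ids[j] for j in bi],
            "score": scores,
            "positive": pos_mask,
            "tag": np.where(tag_mask, TEST_TAG, ""),
        }
    )
    ent_rows = []
    for axis, ids, offs, idx in (("A", a_ids, off_a, ai), ("B", b_ids, off_b, bi)):
        counts = pd.Series(idx).value_counts()
        pos_counts = pd.Series(idx[pos_mask]).value_counts()
        for k, eid in enumerate(ids):
            n_k = int(counts.get(k, 0))
            if n_k == 0:
                continue
            ent_rows.append(
                {
                    "axis": axis,
                    "entity_id": eid,
                    "offset": float(offs[k]),
                    "n_pairs": n_k,
                    "pos_frac": float(pos_counts.get(k, 0)) / n_k,
                }
            )
    truth = SynthTruth(truth_pairs, pd.DataFrame(ent_rows), dropped)
    return table, labels, truth


def two_slope_curve(
    n: int = 500,
    knee_frac: float = 0.1,
    *,
    y_top: float = 1.0,
    y_knee: float = 0.8,
    y_bottom: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Piecewise-linear descending curve with a planted knee.

    Scores fall steeply from ``y_top`` to ``y_knee`` over the first
    ``knee_frac`` fraction of ranks, then gently from ``y_knee`` to
    ``y_bottom`` over the rest. Returns (scores, knee_index). Optional
    Gaussian noise is added, and the curve re-sorted to stay descending.
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    k = max(1, int(round(knee_frac * n)))
    head = np.linspace(y_top, y_knee, k, endpoint=False)
    tail = np.linspace(y_knee, y_bottom, n - k)
    y = np.concatenate([head, tail])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_sd, n), 0.0, 1.0)
        y = np.sort(y)[::-1]
    return y, k
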