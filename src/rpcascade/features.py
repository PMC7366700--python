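"""Reciprocal Perspective feature extraction.

For a pair (X, Y) the RP features describe where the pair sits on X's and
Y's One-to-All curves relative to each entity's local baseline:

==========  ==============================================================
raw_score   the initial predictor score m, passed through untransformed
rxy, ryx    percentile rank of the pair in X's / Y's curve (0 = top)
arro        adjusted reciprocal rank order, (1 - rxy) * (1 - ryx):
            1 iff uniquely top-ranked from both perspectives
rxt, ryt    percentile rank at X's / Y's local cutoff
sxt, syt    score at X's / Y's local cutoff
pdx, pdy    signed percentile margin over the local cutoff (rxt - rxy);
            positive = better than the local threshold
fdx, fdy    fold difference of m from the local cutoff score,
            (m - s_t) / max(s_t, eps); positive = above threshold
stdx, stdy  standard-score distance of m from the curve mean, using the
            population sd (0 when the curve is constant)
==========  ==============================================================

Binary above-threshold indicators are deliberately not computed: the
model can learn a global threshold from the raw score, and the fold
differences carry the local-threshold information in graded form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .o2a import Baseline, O2ACurve

__all__ = ["RPFeatureVector", "FEATURE_COLUMNS", "pair_features", "batch_features"]

EPS = 1e-6

FEATURE_COLUMNS = [
    "raw_score",
    "rxy",
    "ryx",
    "arro",
    "rxt",
    "sxt",
    "ryt",
    "syt",
    "pdx",
    "pdy",
    "fdx",
    "fdy",
    "stdx",
    "stdy",
]


@dataclass
class RPFeatureVector:
    raw_score: float
    rxy: float
    ryx: float
    arro: float
    rxt: float
    sxt: float
    ryt: float
    syt: float
    pdx: float
    pdy: float
    fdx: float
    fdy: float
    stdx: float
    stdy: float

    def as_row(self) -> list[float]:
        return [getattr(self, c) for c in FEATURE_COLUMNS]


def _std_distance(m: float, mean: float, sd: float) -> float:
    return (m - mean) / sd if sd > 0 else 0.0


def pair_features(
    pair: tuple[str, str],
    curve_a: O2ACurve,
    base_a: Baseline,
    curve_b: O2ACurve,
    base_b: Baseline,
) -> RPFeatureVector:
    """Compute the RP feature vector of one pair from its two O2A contexts.

    ``curve_a``/``base_a`` belong to the pair's A-side entity (its partners
    are B-side ids), and vice versa.
    """
    a, b = pair
    try:
        rxy = curve_a.percentile_of(b)
    except KeyError:
        raise KeyError(f"pair {pair!r} missing from the A-perspective curve of {a!r}") from None
    try:
        ryx = curve_b.percentile_of(a)
    except KeyError:
        raise KeyError(f"pair {pair!r} missing from the B-perspective curve of {b!r}") from None
    k = curve_a.partners.index(b)
    m = float(curve_a.scores[k])
    return RPFeatureVector(
        raw_score=m,
        rxy=rxy,
        ryx=ryx,
        arro=(1.0 - rxy) * (1.0 - ryx),
        rxt=base_a.cutoff_percentile,
        sxt=base_a.cutoff_score,
        ryt=base_b.cutoff_percentile,
        syt=base_b.cutoff_score,
        pdx=base_a.cutoff_percentile - rxy,
        pdy=base_b.cutoff_percentile - ryx,
        fdx=(m - base_a.cutoff_score) / max(base_a.cutoff_score, EPS),
        fdy=(m - base_b.cutoff_score) / max(base_b.cutoff_score, EPS),
        stdx=_std_distance(m, base_a.mean_score, base_a.sd_score),
        stdy=_std_distance(m, base_b.mean_score, base_b.sd_score),
    )


def batch_features(
    curves: dict[tuple[str, str], O2ACurve],
    baselines: dict[tuple[str, str], Baseline],
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Feature matrix for a pair list; rows follow the input order.

    ``curves`` and ``baselines`` are keyed by ("A"|"B", entity_id) as
    produced by :func:`rpcascade.o2a.baselines_for_table`.
    """
    rows = np.empty((len(pairs), len(FEATURE_COLUMNS)))
    for i, (a, b) in enumerate(pairs):
        try:
            curve_a, base_a = curves[("A", a)], baselines[("A", a)]
        except KeyError:
            raise KeyError(f"no baseline for A-entity {a!r}") from None
        try:
            curve_b, base_b = curves[("B", b)], baselines[("B", b)]
        except KeyError:
            raise KeyError(f"no baseline for B-entity {b!r}") from None
        rows[i] = pair_features((a, b), curve_a, base_a, curve_b, base_b).as_row()
    index = pd.MultiIndex.from_tuples(pairs, names=["entity_a", "entity_b"]) if pairs else None
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS, index=index)
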