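"""One-to-All (O2A) rank-order curves and per-entity local baselines.

An O2A curve is the descending rank-order plot of every prediction score
involving one fixed entity, seen from one perspective of the bipartite
score table. Its knee — the point of maximum curvature between the
high-scoring head and the long tail — serves as that entity's *local*
decision threshold, replacing a single global score cutoff.

Dense curves (n > 100) are LOESS-smoothed and their knee located with the
Kneedle algorithm; sparse curves (n <= 100) fall back to the median of the
score distribution, which is robust at small n where curvature is
meaningless.

Ranks are expressed as percentile ranks in [0, 1] (top rank -> 0) so that
positions are comparable across entities with very different numbers of
scored partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "O2ACurve",
    "Baseline",
    "build_o2a",
    "loess_smooth",
    "kneedle_knee",
    "locate_baseline",
]

#: curves with at most this many points use the median baseline
SPARSE_N = 100


@dataclass
class O2ACurve:
    """Rank-ordered scores of one entity from one perspective."""

    entity_id: str
    axis: str
    partners: list[str]
    scores: np.ndarray  # descending
    percentiles: np.ndarray  # non-decreasing, in [0, 1]

    @property
    def n(self) -> int:
        return len(self.partners)

    def percentile_of(self, partner_id: str) -> float:
        try:
            k = self.partners.index(partner_id)
        except ValueError:
            raise KeyError(
                f"partner {partner_id!r} not in O2A curve of {self.entity_id!r} (axis {self.axis})"
            ) from None
        return float(self.percentiles[k])


@dataclass
class Baseline:
    """Local cutoff of one entity: the (score, percentile) decision point."""

    entity_id: str
    axis: str
    cutoff_score: float
    cutoff_percentile: float
    method: str  # "kneedle" | "median"
    mean_score: float
    sd_score: float
    n: int


def build_o2a(view: list[tuple[str, float]], entity_id: str, axis: str) -> O2ACurve:
    """Sort an entity view into a descending O2A curve with percentile ranks.

    Ties in score are broken by partner id (deterministic ordering); tied
    scores share the mean percentile of their rank block. Rank k (1-based)
    maps to percentile (k-1)/(n-1); a single-point curve gets 0.5.
    """
    if not view:
        raise ValueError(f"empty view for entity {entity_id!r}")
    ordered = sorted(view, key=lambda ps: (-ps[1], ps[0]))
    partners = [p for p, _ in ordered]
    scores = np.asarray([s for _, s in ordered], dtype=float)
    n = len(ordered)
    if n == 1:
        percentiles = np.array([0.5])
    else:
        base = np.arange(n, dtype=float) / (n - 1)
        percentiles = np.empty(n)
        start = 0
        while start < n:
            stop = start
            while stop < n and scores[stop] == scores[start]:
                stop += 1
            percentiles[start:stop] = base[start:stop].mean()
            start = stop
    return O2ACurve(entity_id, axis, partners, scores, percentiles)


def loess_smooth(curve: O2ACurve, span: float = 0.3) -> np.ndarray:
    """LOESS (locally weighted linear) fit of the curve over normalized rank.

    Returns fitted values at each rank, clipped to [0, 1]. ``span`` is the
    fraction of points in each local window.
    """
    if not (0.0 < span <= 1.0):
        raise ValueError(f"span must be in (0, 1], got {span}")
    n = curve.n
    x = np.arange(n, dtype=float) / max(n - 1, 1)
    # it=0: robustness reweighting misreads the short head of a monotone
    # rank curve as outliers and collapses the fit onto the tail line
    fitted = lowess(curve.scores, x, frac=span, it=0, return_sorted=False)
    return np.clip(fitted, 0.0, 1.0)


def kneedle_knee(
    x: np.ndarray,
    y: np.ndarray,
    sensitivity: float = 1.0,
) -> tuple[int, float] | None:
    """Kneedle knee detection for a non-increasing curve.

    Both coordinates are min-max normalized to the unit square; the
    difference curve d = chord - y_norm (the chord runs from the first to
    the last point) is formed, and the first local maximum of d exceeding
    the sensitivity-adjusted threshold S * mean(dx) is accepted as the knee.
    Returns (knee_index, y_at_knee) on the original curve, or None when no
    local maximum qualifies (e.g. a straight line, where d is identically 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(y) < 3:
        raise ValueError("kneedle needs matched x/y with at least 3 points")
    if np.any(np.diff(y) > 1e-12):
        raise ValueError("kneedle expects a non-increasing y curve")
    xr = x[-1] - x[0]
    yr = y[0] - y[-1]
    if xr <= 0:
        raise ValueError("x must be strictly increasing overall")
    if yr <= 0:
        return None  # flat curve: no knee
    xn = (x - x[0]) / xr
    yn = (y - y[-1]) / yr
    # chord from (0, 1) to (1, 0) of the normalized decreasing curve
    diff = (1.0 - xn) - yn
    threshold = sensitivity * float(np.mean(np.diff(xn)))
    for i in range(1, len(diff) - 1):
        if diff[i] > diff[i - 1] and diff[i] >= diff[i + 1]:
            if diff[i] > threshold:
                return i, float(y[i])
    return None


def _refine_knee(scores: np.ndarray, coarse_idx: int, half_width: int) -> int:
    """Sharpen a smoothed knee estimate against the raw curve.

    LOESS rounds a sharp corner, which drags the maximum of the
    chord-difference curve a fraction of the smoothing window toward the
    tail. The raw O2A scores are already non-increasing, so the exact
    maximum of the raw difference curve within one window of the coarse
    estimate recovers the unbiased knee rank.
    """
    n = len(scores)
    yr = scores[0] - scores[-1]
    if yr <= 0:
        return coarse_idx
    xn = np.arange(n, dtype=float) / (n - 1)
    yn = (scores - scores[-1]) / yr
    diff = (1.0 - xn) - yn
    lo = max(0, coarse_idx - half_width)
    hi = min(n, coarse_idx + half_width + 1)
    return lo + int(np.argmax(diff[lo:hi]))


def locate_baseline(
    curve: O2ACurve,
    *,
    span: float = 0.3,
    sensitivity: float = 1.0,
) -> Baseline:
    """Estimate the entity's local baseline from its O2A curve.

    Dense curves (n > 100) are LOESS-smoothed and handed to Kneedle; the
    cutoff score is read from the *raw* curve at the knee rank (the smoothed
    value is a fit artifact). Sparse curves (n <= 100), and dense curves on
    which Kneedle finds no knee, use the median of the scores; the cutoff
    percentile is then that of the point whose score is nearest the median
    (ties resolved to the lower, i.e. better, rank). The population mean and
    standard deviation of the curve's scores are recorded alongside.
    """
    scores = curve.scores
    n = curve.n
    mean = float(scores.mean())
    sd = float(scores.std())  # population (n divisor); 0 for n = 1
    knee = None
    if n > SPARSE_N:
        smoothed = loess_smooth(curve, span)
        # lowess output can wiggle slightly; enforce the monotone shape kneedle expects
        smoothed = np.minimum.accumulate(smoothed)
        x = np.arange(n, dtype=float)
        knee = kneedle_knee(x, smoothed, sensitivity)
    if knee is not None:
        idx = _refine_knee(scores, knee[0], half_width=max(5, int(round(span * n / 2))))
        return Baseline(
            curve.entity_id,
            curve.axis,
            cutoff_score=float(scores[idx]),
            cutoff_percentile=float(curve.percentiles[idx]),
            method="kneedle",
            mean_score=mean,
            sd_score=sd,
            n=n,
        )
    if n == 1:
        return Baseline(
            curve.entity_id, curve.axis, float(scores[0]), 0.5, "median", mean, sd, n
        )
    med = float(np.median(scores))
    dist = np.abs(scores - med)
    # lower (better) rank wins ties; tolerance absorbs the 1-ulp asymmetry of
    # the central pair around an even-n median so the choice is transform-stable
    idx = int(np.flatnonzero(dist <= dist.min() + 1e-12 + 1e-9 * abs(med))[0])
    return Baseline(
        curve.entity_id,
        curve.axis,
        cutoff_score=med,
        cutoff_percentile=float(curve.percentiles[idx]),
        method="median",
        mean_score=mean,
        sd_score=sd,
        n=n,
    )


def baselines_for_table(table, *, span: float = 0.3, sensitivity: float = 1.0):
    """Compute curves and baselines for every entity on both axes.

    Returns ``(curves, baselines)``: two dicts keyed by ("A"|"B", entity_id).
    """
    from .score_store import entity_view

    curves: dict[tuple[str, str], O2ACurve] = {}
    baselines: dict[tuple[str, str], Baseline] = {}
    for axis, index in (("A", table.index_a), ("B", table.index_b)):
        for eid in index:
            curve = build_o2a(entity_view(table, axis, eid), eid, axis)
            curves[(axis, eid)] = curve
            baselines[(axis, eid)] = locate_baseline(curve, span=span, sensitivity=sensitivity)
    return curves, baselines
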