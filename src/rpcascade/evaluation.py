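"""Evaluation and ranking: bootstrap AUCs, significance, DoS, tiering.

Model comparison follows a paired-bootstrap design: test rows are
resampled (stratified, with replacement) once per iteration and every
model is scored on the same resample, yielding per-model ROC/PR AUC
distributions whose difference is tested with Welch's unequal-variances
t-test. Refined scores are further analysed by the Difference of Scores
(DoS) filter, the lambda-weighted combined score, and the mirDIP-style
confidence tiering of the ranked predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score

__all__ = [
    "EvalReport",
    "roc_pr_auc",
    "bootstrap_auc",
    "welch_test",
    "combined_score",
    "dos_candidates",
    "tier_assignment",
    "compare_models",
]

TIER_FRACTIONS = [("top1", 0.01), ("top5", 0.05), ("top10", 0.10), ("top33", 0.33)]
BOTTOM_TIER = "bottom66"


@dataclass
class EvalReport:
    """Bootstrap summaries (mu +/- sigma) and Welch p-values per model pair."""

    roc_auc_mean: dict[str, float]
    roc_auc_sd: dict[str, float]
    pr_auc_mean: dict[str, float]
    pr_auc_sd: dict[str, float]
    p_value_roc: dict[tuple[str, str], float]
    p_value_pr: dict[tuple[str, str], float]
    n_boot: int
    seed: int


def roc_pr_auc(scores, y, *, pr_convention: str = "step") -> tuple[float, float]:
    """ROC AUC (trapezoidal over all thresholds) and PR AUC for one model.

    ``pr_convention`` selects the PR summary: ``"step"`` (stepwise precision
    interpolation, i.e. average precision — the default) or ``"trapezoid"``.
    Tied scores are grouped into single threshold steps by construction.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute AUCs")
    roc = float(roc_auc_score(y, scores))
    if pr_convention == "step":
        pr = float(average_precision_score(y, scores))
    elif pr_convention == "trapezoid":
        precision, recall, _ = precision_recall_curve(y, scores)
        pr = float(_trapezoid_auc(recall, precision))
    else:
        raise ValueError(f"unknown PR convention {pr_convention!r}")
    return roc, pr


def bootstrap_auc(
    scores,
    y,
    n_boot: int = 1000,
    seed: int = 0,
    *,
    pr_convention: str = "step",
) -> dict[str, dict[str, np.ndarray]]:
    """Stratified bootstrap distributions of ROC and PR AUC.

    ``scores`` may be a single score vector or a mapping of model name to
    score vector; in the mapping case every model is evaluated on the same
    resample per iteration (paired design), which is the sharper comparison.
    Stratified resampling (within-class, with replacement, class counts
    preserved) guarantees both classes in every resample. Returns
    ``{model: {"roc": vector, "pr": vector}}``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    named = scores if isinstance(scores, dict) else {"model": scores}
    y = np.asarray(y)
    arrays = {k: np.asarray(v, dtype=float) for k, v in named.items()}
    for k, v in arrays.items():
        if v.shape != y.shape:
            raise ValueError(f"scores {k!r} length {len(v)} != labels length {len(y)}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if all(len(np.unique(v)) < 2 for v in arrays.values()):
        raise ValueError("constant scores: ROC curve degenerates to a single point")
    rng = np.random.default_rng(seed)
    class_idx = [np.flatnonzero(y == cls) for cls in np.unique(y)]
    out = {k: {"roc": np.empty(n_boot), "pr": np.empty(n_boot)} for k in arrays}
    for it in range(n_boot):
        take = np.concatenate([rng.choice(ci, size=len(ci), replace=True) for ci in class_idx])
        yb = y[take]
        for k, v in arrays.items():
            roc, pr = roc_pr_auc(v[take], yb, pr_convention=pr_convention)
            out[k]["roc"][it] = roc
            out[k]["pr"][it] = pr
    return out if isinstance(scores, dict) else out["model"]


def welch_test(auc_a, auc_b) -> float:
    """Two-sided Welch's unequal-variances t-test p-value."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in AUC samples")
    if a.std() == 0 and b.std() == 0:
        if np.allclose(a.mean(), b.mean()):
            return 1.0
        raise ValueError("zero variance in both samples")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compare_models(
    scores: dict[str, np.ndarray],
    y,
    n_boot: int = 1000,
    seed: int = 0,
    *,
    pr_convention: str = "step",
) -> EvalReport:
    """Paired-bootstrap evaluation of several models on one test set."""
    boot = bootstrap_auc(scores, y, n_boot=n_boot, seed=seed, pr_convention=pr_convention)
    names = list(scores)
    p_roc, p_pr = {}, {}
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            p_roc[(na, nb)] = welch_test(boot[na]["roc"], boot[nb]["roc"])
            p_pr[(na, nb)] = welch_test(boot[na]["pr"], boot[nb]["pr"])
    return EvalReport(
        roc_auc_mean={k: float(boot[k]["roc"].mean()) for k in names},
        roc_auc_sd={k: float(boot[k]["roc"].std()) for k in names},
        pr_auc_mean={k: float(boot[k]["pr"].mean()) for k in names},
        pr_auc_sd={k: float(boot[k]["pr"].std()) for k in names},
        p_value_roc=p_roc,
        p_value_pr=p_pr,
        n_boot=n_boot,
        seed=seed,
    )


def combined_score(m, r, lam: float, *, normalize: bool = False) -> np.ndarray:
    """Lambda-weighted combined score s = (1 - lambda) * m * lambda * r.

    Implemented exactly as printed; note the weighting collapses to the
    rank-neutral scalar (1 - lambda) * lambda times m * r, so for any fixed
    lambda in (0, 1) the induced ranking equals the ranking by the plain
    product m * r. ``normalize`` min-max rescales the batch into [0, 1].
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    m = np.asarray(m, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any((m < 0) | (m > 1)) or np.any((r < 0) | (r > 1)):
        raise ValueError("scores must lie in [0, 1]")
    s = (1.0 - lam) * m * lam * r
    if normalize and len(s):
        lo, hi = s.min(), s.max()
        if hi > lo:
            s = (s - lo) / (hi - lo)
    return s


def dos_candidates(
    pairs: list[tuple[str, str]],
    refined,
    original,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Putative novel interactions: DoS >= threshold, in two sort orders.

    Returns (by_dos, by_refined): the surviving pairs sorted by DoS
    descending and by refined score descending. Ties break by refined score
    then pair key, deterministically.
    """
    refined = np.asarray(refined, dtype=float)
    original = np.asarray(original, dtype=float)
    if not (len(pairs) == len(refined) == len(original)):
        raise ValueError("pairs, refined and original must be aligned")
    df = pd.DataFrame(
        {
            "entity_a": [a for a, _ in pairs],
            "entity_b": [b for _, b in pairs],
            "refined": refined,
            "original": original,
            "dos": refined - original,
        }
    )
    surv = df[df["dos"] >= threshold]
    by_dos = surv.sort_values(
        ["dos", "refined", "entity_a", "entity_b"], ascending=[False, False, True, True]
    ).reset_index(drop=True)
    by_refined = surv.sort_values(
        ["refined", "dos", "entity_a", "entity_b"], ascending=[False, False, True, True]
    ).reset_index(drop=True)
    return by_dos, by_refined


def tier_assignment(refined) -> list[str]:
    """mirDIP-convention confidence tiers on the refined-score ranking.

    The ranked predictions are split into nested cumulative top-1%, 5%,
    10% and 33% sets (boundary counts ceil(fraction * N)); the remainder is
    the bottom-66% tier. Each position reports its innermost tier. Ties in
    score are broken by original position (stable sort).
    """
    refined = np.asarray(refined, dtype=float)
    n = len(refined)
    if n == 0:
        raise ValueError("need at least one score")
    order = np.argsort(-refined, kind="stable")
    labels = np.full(n, BOTTOM_TIER, dtype=object)
    for name, frac in reversed(TIER_FRACTIONS):
        cut = int(np.ceil(frac * n))
        labels[order[:cut]] = name
    return list(labels)
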