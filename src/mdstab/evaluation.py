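"""Ranking evaluation: ROC, stability-weighted ROC, AUC bounds, sweeps.

Mutations are labeled stabilizing when their measured ΔTm exceeds a
threshold (0 °C by default — neutral counts as unsuccessful).  The
stability-weighted ROC scales each positive's true-positive-rate step by
its share of the total ΔTm gain, so ranking a +7 °C mutation above a
+0.5 °C one is rewarded; negatives step uniformly and are not scaled.

For partially untested rankings, combinatorial AUC bounds flip the k
top-ranked (upper bound) or k bottom-ranked (lower bound) untested
mutations to positive for every k, and the fraction sweep averages the
AUC over random placements of a given fraction of hidden positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledRanking",
    "RocResult",
    "roc",
    "weighted_roc",
    "auc_bounds",
    "fraction_sweep",
]


@dataclass
class LabeledRanking:
    """Scores plus experimental labels for a set of mutations.

    ``delta_tm`` is NaN for untested mutations; a mutation is a positive
    iff its ΔTm is known and exceeds ``threshold`` (strict).
    """

    ids: list[str]
    scores: np.ndarray
    delta_tm: np.ndarray  # °C; NaN = untested
    threshold: float = 0.0

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.delta_tm = np.asarray(self.delta_tm, dtype=float)
        if not (len(self.ids) == self.scores.size == self.delta_tm.size):
            raise ValueError("ids, scores and delta_tm must have equal length")

    @property
    def tested(self) -> np.ndarray:
        return ~np.isnan(self.delta_tm)

    @property
    def labels(self) -> np.ndarray:
        """+1 positive, 0 negative, −1 untested."""
        out = np.full(self.scores.size, -1, dtype=int)
        out[self.tested & (self.delta_tm > self.threshold)] = 1
        out[self.tested & (self.delta_tm <= self.threshold)] = 0
        return out

    @property
    def n_untested(self) -> int:
        return int((~self.tested).sum())


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    weighted: bool = False

    def __post_init__(self):
        if not (self.fpr[0] == 0 and self.tpr[0] == 0 and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def _step_roc(scores: np.ndarray, positive: np.ndarray, pos_weights: np.ndarray) -> RocResult:
    """ROC by descending score with tie blocks as diagonal segments.

    ``pos_weights`` are the TPR increments per positive (summing to 1);
    negatives each contribute an FPR increment of 1/N_neg.  AUC by
    trapezoid, which equals the step-function area plus half the tie
    blocks' diagonal corrections.
    """
    n_neg = int((~positive).sum())
    n_pos = int(positive.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="mergesort")
    s, p, w = scores[order], positive[order], pos_weights[order]
    fpr = [0.0]
    tpr = [0.0]
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s[j] == s[i]:
            j += 1
        tpr.append(tpr[-1] + w[i:j][p[i:j]].sum())
        fpr.append(fpr[-1] + (~p[i:j]).sum() / n_neg)
        i = j
    fpr = np.asarray(fpr)
    tpr = np.asarray(tpr)
    fpr[-1] = round(fpr[-1], 12)
    tpr[-1] = round(tpr[-1], 12)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, auc=float(np.clip(auc, 0.0, 1.0)))


def _resolve(ranking_or_scores, labels=None):
    if isinstance(ranking_or_scores, LabeledRanking):
        r = ranking_or_scores
        lab = r.labels
        if (lab == -1).any():
            raise ValueError("ranking contains untested mutations; use auc_bounds/fraction_sweep")
        return r.scores, lab.astype(bool), r.delta_tm
    scores = np.asarray(ranking_or_scores, dtype=float)
    lab = np.asarray(labels)
    return scores, lab.astype(bool), None


def roc(ranking_or_scores, labels=None) -> RocResult:
    """Standard ROC/AUC by descending score (uniform positive steps)."""
    scores, positive, _ = _resolve(ranking_or_scores, labels)
    n_pos = int(positive.sum())
    if n_pos == 0 or int((~positive).sum()) == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    weights = np.where(positive, 1.0 / n_pos, 0.0)
    return _step_roc(scores, positive, weights)


def weighted_roc(ranking_or_scores, labels=None, delta_tm=None) -> RocResult:
    """Stability-weighted ROC: positive i steps TPR by ΔTm_i / Σ ΔTm."""
    scores, positive, dtm = _resolve(ranking_or_scores, labels)
    if delta_tm is not None:
        dtm = np.asarray(delta_tm, dtype=float)
    if dtm is None:
        raise ValueError("weighted ROC needs per-mutation ΔTm values")
    if np.isnan(dtm[positive]).any():
        raise ValueError("every positive needs a ΔTm value for weighting")
    total = dtm[positive].sum()
    if total <= 0:
        raise ValueError("total positive ΔTm must be positive")
    weights = np.zeros(scores.size)
    weights[positive] = dtm[positive] / total
    out = _step_roc(scores, positive, weights)
    out.weighted = True
    return out


def auc_bounds(ranking: LabeledRanking) -> dict:
    """Best/worst-case AUC over the untested mutations.

    For each assumed count k of hidden positives, the upper bound flips
    the k best-ranked untested mutations to positive (remaining untested
    count negative) and the lower bound the k worst-ranked.  Returns the
    per-k curves and the global (min, max).
    """
    lab = ranking.labels
    untested = np.flatnonzero(lab == -1)
    order = untested[np.argsort(-ranking.scores[untested], kind="mergesort")]
    u = order.size

    def auc_with(flipped: np.ndarray) -> float:
        labels = (lab == 1) | np.isin(np.arange(lab.size), flipped)
        return roc(ranking.scores, labels).auc

    upper = [auc_with(order[:k]) for k in range(0, u + 1)]
    lower = [auc_with(order[u - k :]) for k in range(0, u + 1)]
    return {
        "k": list(range(0, u + 1)),
        "upper": upper,
        "lower": lower,
        "max": max(upper),
        "min": min(lower),
    }


def fraction_sweep(
    ranking: LabeledRanking,
    fractions,
    reps: int = 1000,
    seed: int | None = None,
) -> dict[float, float]:
    """Mean AUC when a given fraction of untested mutations is assumed
    stabilizing, averaged over ``reps`` random placements."""
    rng = np.random.default_rng(seed)
    lab = ranking.labels
    untested = np.flatnonzero(lab == -1)
    u = untested.size
    if u == 0:
        raise ValueError("fraction sweep needs untested mutations")
    out = {}
    for f in fractions:
        k = int(round(f * u))
        if k == 0 or k == u:
            flipped = untested[:k]
            labels = (lab == 1) | np.isin(np.arange(lab.size), flipped)
            out[f] = roc(ranking.scores, labels).auc
            continue
        aucs = []
        for _ in range(reps):
            flipped = rng.choice(untested, size=k, replace=False)
            labels = (lab == 1) | np.isin(np.arange(lab.size), flipped)
            aucs.append(roc(ranking.scores, labels).auc)
        out[f] = float(np.mean(aucs))
    return out
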