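"""Empirical ROC curves, AUC, and operating-point selection.

Two clinical questions drive this module: how well the baseline serum BDNF
level separates depressed patients from healthy controls (patients run
*lower*, so a low score votes positive), and how well the early NI
enhancement separates eventual treatment responders from non-responders
(higher votes positive).  AUC is the trapezoidal area over the full
threshold staircase, which with ties credited one half equals the
pair-counting (Mann-Whitney) statistic; the hand-written pair-counting
estimator is kept as an independent oracle.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn import metrics as skm

ORIENTATIONS = ("higher_is_positive", "lower_is_positive")


@dataclasses.dataclass
class RocResult:
    """Operating points, AUC and the Youden-optimal point of one ROC curve.

    ``points`` rows are (threshold, sensitivity, specificity) ordered from the
    most conservative threshold (sensitivity 0) to the most liberal
    (sensitivity 1).  A case is called positive when its score is >= threshold
    for ``higher_is_positive`` orientation, <= threshold otherwise.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float
    optimal_sensitivity: float
    optimal_specificity: float
    n_pos: int
    n_neg: int
    orientation: str

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds, self.sensitivity, self.specificity))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "sensitivity": self.sensitivity,
             "specificity": self.specificity}
        )


def _check_inputs(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim != 1 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    if np.isnan(scores).any():
        raise ValueError("scores must not contain missing values")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[int],
    orientation: str = "higher_is_positive",
) -> RocResult:
    """Empirical ROC with thresholds at the distinct score values.

    For ``lower_is_positive`` the scores are negated internally and the
    thresholds mapped back to the original scale.  AUC is the trapezoidal
    integral of sensitivity over 1 - specificity across the full staircase.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    scores, labels = _check_inputs(scores, labels)
    signed = scores if orientation == "higher_is_positive" else -scores
    fpr, tpr, thr = skm.roc_curve(labels, signed, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    # skm's leading threshold is +inf (the "call nothing positive" point);
    # keep it as +/-inf on the caller's scale.
    thresholds = thr if orientation == "higher_is_positive" else -thr
    sens = tpr
    spec = 1.0 - fpr
    opt = _youden_scan(thresholds, sens, spec)
    return RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc,
        optimal_threshold=opt[0], optimal_sensitivity=opt[1],
        optimal_specificity=opt[2],
        n_pos=int(labels.sum()), n_neg=int((1 - labels).sum()),
        orientation=orientation,
    )


def auc_pair_counting(
    scores: Sequence[float],
    labels: Sequence[int],
    orientation: str = "higher_is_positive",
) -> float:
    """AUC as (concordant positive-negative pairs + ties/2) / (n_pos * n_neg).

    Direct O(n_pos * n_neg) enumeration; the independent oracle for
    :func:`roc_curve`.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    scores, labels = _check_inputs(scores, labels)
    signed = scores if orientation == "higher_is_positive" else -scores
    pos = signed[labels == 1]
    neg = signed[labels == 0]
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins) / (pos.size * neg.size)


def _youden_scan(thresholds, sens, spec):
    """Maximise J = sens + spec - 1; ties -> higher sensitivity, lower threshold."""
    j = sens + spec - 1.0
    best = 0
    for i in range(1, len(j)):
        if (j[i], sens[i], -thresholds[i]) > (j[best], sens[best], -thresholds[best]):
            best = i
    return float(thresholds[best]), float(sens[best]), float(spec[best])


def youden_optimal(roc: RocResult) -> tuple[float, float, float]:
    """The (threshold, sensitivity, specificity) maximising Youden's J."""
    return _youden_scan(roc.thresholds, roc.sensitivity, roc.specificity)


def _rank_auc(scores: np.ndarray, pos_mask: np.ndarray) -> float:
    """Tie-aware AUC via the rank-sum identity (internal, permutation helper)."""
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n_pos = int(pos_mask.sum())
    n_neg = scores.size - n_pos
    return (ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def auc_permutation_test(
    scores: Sequence[float],
    labels: Sequence[int],
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    orientation: str = "higher_is_positive",
) -> tuple[float, float, np.ndarray]:
    """Permutation null for the AUC: shuffle labels, recompute.

    Returns (observed AUC, one-sided p for AUC exceeding chance, null AUCs).
    """
    scores, labels = _check_inputs(scores, labels)
    signed = scores if orientation == "higher_is_positive" else -scores
    rng = rng or np.random.default_rng()
    observed = _rank_auc(signed, labels == 1)
    perm_labels = rng.permuted(
        np.tile(labels == 1, (n_permutations, 1)), axis=1
    )
    from scipy.stats import rankdata

    ranks = rankdata(signed)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    null = (perm_labels @ ranks - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    p = (1 + (null >= observed).sum()) / (1 + n_permutations)
    return float(observed), float(p), null


def bootstrap_auc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    orientation: str = "higher_is_positive",
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for the AUC (stratified by class)."""
    scores, labels = _check_inputs(scores, labels)
    signed = scores if orientation == "higher_is_positive" else -scores
    rng = rng or np.random.default_rng()
    pos = signed[labels == 1]
    neg = signed[labels == 0]
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos, pos.size, replace=True)
        n = rng.choice(neg, neg.size, replace=True)
        diff = p[:, None] - n[None, :]
        aucs[i] = ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (p.size * n.size)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
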