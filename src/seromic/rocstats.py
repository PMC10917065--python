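"""ROC primitives and multiple-testing adjustments used by the screening
and panel-discovery stages.

AUC is trapezoidal over the empirical ROC with tie handling that makes it
identical to the Mann-Whitney U statistic divided by n1*n0.  The optimal
cutpoint maximizes the Youden index (sensitivity + specificity - 1) over
midpoints between adjacent distinct scores, with positives called at
score >= cutoff; ties go to the higher-specificity, then lower, cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = _check_pvals(pvals)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvals) -> np.ndarray:
    """Bonferroni adjusted p-values: min(1, m*p)."""
    p = _check_pvals(pvals)
    if p.size == 0:
        return p
    return multipletests(p, method="bonferroni")[1]


def _check_two_class(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return y


def roc_auc(scores, labels) -> float:
    """Area under the empirical ROC curve (ties averaged)."""
    y = _check_two_class(labels)
    s = np.asarray(scores, dtype=float)
    return float(roc_auc_score(y, s))


@dataclass
class Cutpoint:
    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    degenerate: bool = False


def optimal_cutpoint(scores, labels, criterion: str = "youden") -> Cutpoint:
    """Youden-optimal classification cutoff for score >= cutoff positive.

    Candidate cutoffs are the midpoints between adjacent distinct scores.
    When every score is identical there is no midpoint: the degenerate
    cutoff equals that score (everything positive; sensitivity 1,
    specificity 0) and the result is flagged.
    """
    if criterion != "youden":
        raise ValueError(f"unsupported criterion {criterion!r}")
    y = _check_two_class(labels)
    s = np.asarray(scores, dtype=float)
    distinct = np.unique(s)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if distinct.size == 1:
        return Cutpoint(cutoff=float(distinct[0]), sensitivity=1.0, specificity=0.0,
                        youden=0.0, degenerate=True)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    best: Cutpoint | None = None
    for c in mids:
        pos = s >= c
        sens = float((pos & y).sum() / n_pos)
        spec = float((~pos & ~y).sum() / n_neg)
        j = sens + spec - 1.0
        cand = Cutpoint(cutoff=float(c), sensitivity=sens, specificity=spec, youden=j)
        if best is None or (j, spec, -c) > (best.youden, best.specificity, -best.cutoff):
            best = cand
    assert best is not None
    return best


def combination_score(values, marker_cutoffs: dict[str, float],
                      rule: str = "count_positive", weights: dict[str, float] | None = None):
    """Panel score of one or many samples over a marker set.

    ``values`` is a DataFrame (samples x antigens) or Series holding the
    member markers' RFUs.  ``count_positive`` (default) counts member
    markers at or above their per-marker cutoff — invariant under any
    monotone transform applied jointly to data and cutoffs.  ``linear``
    combines the members with the supplied weights (used by the logistic
    panel rule, whose weights are fitted upstream).
    """
    import pandas as pd  # local import to keep the numeric core light

    markers = list(marker_cutoffs)
    if isinstance(values, pd.Series):
        values = values.to_frame().T
    missing = [m for m in markers if m not in values.columns]
    if missing:
        raise KeyError(f"missing member marker RFU(s): {missing}")
    sub = values[markers].astype(float)
    if rule == "count_positive":
        cuts = pd.Series(marker_cutoffs)
        return sub.ge(cuts, axis=1).sum(axis=1).astype(float)
    if rule == "linear":
        if weights is None:
            raise ValueError("linear rule requires weights")
        w = pd.Series({m: weights[m] for m in markers})
        return sub.mul(w, axis=1).sum(axis=1)
    raise ValueError(f"unknown combination rule {rule!r}")
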