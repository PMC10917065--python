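"""Combinatorial ROC biomarker-panel discovery.

The procedure mirrors combinatorial ROC practice: antigens are first
screened one at a time for a case-versus-pooled-controls difference
(Mann-Whitney by default) with Benjamini-Hochberg FDR control at 1%; the
surviving candidates (falling back to raw p < 0.05 when none survive, as
happens for weakly reactive isotypes) are then combined exhaustively into
panels of 2-6 markers.  Each panel scores a sample by the number of member
markers at or above their per-marker Youden cutoff, and the panel itself is
summarized by the ROC AUC of that score plus sensitivity/specificity at the
panel-level Youden cutpoint.  Panels are ranked by AUC, then sensitivity,
then specificity.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import RFUMatrix
from .rocstats import Cutpoint, bh_adjust, combination_score, optimal_cutpoint, roc_auc

log = logging.getLogger(__name__)

_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def roman_numeral(n: int) -> str:
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def marker_screen(
    values: pd.DataFrame | RFUMatrix,
    groups: pd.Series,
    case_label: str,
    control_labels,
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Per-antigen two-sided case vs pooled-controls test with BH adjustment.

    Returns a DataFrame indexed by antigen with the statistic, raw and
    BH-adjusted p, the direction of elevation (sign of the case-minus-
    control median difference), and a flag for antigens constant across all
    samples (assigned p = 1).
    """
    if isinstance(values, RFUMatrix):
        values = values.values
    control_labels = list(control_labels)
    groups = groups.reindex(values.index)
    case = values.loc[groups == case_label]
    ctrl = values.loc[groups.isin(control_labels)]
    if len(case) < 3 or len(ctrl) < 3:
        raise ValueError("marker_screen needs n >= 3 on each side")
    x = case.to_numpy(dtype=float)
    y = ctrl.to_numpy(dtype=float)
    constant = np.ptp(np.concatenate([x, y]), axis=0) == 0
    if test == "mannwhitney":
        res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided",
                                 method="asymptotic")
        stat, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    elif test == "welch":
        res = stats.ttest_ind(x, y, axis=0, equal_var=False)
        stat, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    else:
        raise ValueError(f"unknown screening test {test!r}")
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    direction = np.sign(np.median(x, axis=0) - np.median(y, axis=0))
    out = pd.DataFrame(
        {
            "statistic": stat,
            "p_raw": p,
            "p_adj": bh_adjust(p),
            "direction": direction,
            "constant": constant,
        },
        index=values.columns,
    )
    out.index.name = "antigen_id"
    return out


@dataclass
class PanelResult:
    """One scored marker combination."""

    label: str
    markers: tuple[str, ...]
    marker_cutoffs: dict[str, float]
    rule: str
    auc: float
    sensitivity: float
    specificity: float
    cutoff: float
    youden: float
    degenerate: bool = False
    rank: int = 0


def _batched_auc(scores: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """AUC (tie-averaged) of each row of ``scores`` against ``case_mask``."""
    ranks = stats.rankdata(scores, axis=1)
    n1 = int(case_mask.sum())
    n0 = case_mask.size - n1
    r1 = ranks[:, case_mask].sum(axis=1)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def enumerate_panels(
    values: pd.DataFrame,
    case_mask,
    candidates: list[str],
    size_range: tuple[int, int] = (2, 6),
    rule: str = "count_positive",
    top_m: int | None = 20,
    max_panels: int = 200_000,
    seed: int = 0,
) -> list[PanelResult]:
    """Exhaustively score all marker subsets with sizes in ``size_range``.

    ``candidates`` must already be ranked (best first); only the first
    ``top_m`` enter the enumeration.  Labels are roman numerals in
    enumeration order; ``rank`` is assigned after sorting by AUC
    descending, ties by sensitivity, specificity, then marker ids.
    """
    y = np.asarray(case_mask, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes required")
    if top_m is not None:
        candidates = list(candidates[:top_m])
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size_range")
    if len(candidates) < lo:
        raise ValueError(f"need at least {lo} candidate markers, have {len(candidates)}")
    hi = min(hi, len(candidates))
    from math import comb
    total = sum(comb(len(candidates), k) for k in range(lo, hi + 1))
    if total > max_panels:
        raise ValueError(
            f"{total} panels exceed the budget of {max_panels}; "
            "lower top_m or narrow size_range"
        )

    cutoffs = {m: optimal_cutpoint(values[m].to_numpy(dtype=float), y).cutoff
               for m in candidates}
    pos = values[candidates].ge(pd.Series(cutoffs), axis=1).to_numpy()

    results: list[PanelResult] = []
    counter = itertools.count(1)
    for k in range(lo, hi + 1):
        combos = list(itertools.combinations(range(len(candidates)), k))
        idx = np.asarray(combos)
        if rule == "count_positive":
            scores = pos[:, idx].sum(axis=2).T.astype(float)  # panels x samples
            aucs = _batched_auc(scores, y)
            for row, combo, auc_val in zip(scores, combos, aucs):
                markers = tuple(sorted(candidates[i] for i in combo))
                cp = optimal_cutpoint(row, y)
                results.append(PanelResult(
                    label=roman_numeral(next(counter)),
                    markers=markers,
                    marker_cutoffs={m: cutoffs[m] for m in markers},
                    rule=rule,
                    auc=float(auc_val),
                    sensitivity=cp.sensitivity,
                    specificity=cp.specificity,
                    cutoff=cp.cutoff,
                    youden=cp.youden,
                    degenerate=cp.degenerate,
                ))
        elif rule == "logistic":
            for combo in combos:
                markers = tuple(sorted(candidates[i] for i in combo))
                score = _logistic_score(values[list(markers)], y, seed)
                cp = optimal_cutpoint(score, y)
                results.append(PanelResult(
                    label=roman_numeral(next(counter)),
                    markers=markers,
                    marker_cutoffs={m: cutoffs[m] for m in markers},
                    rule=rule,
                    auc=roc_auc(score, y),
                    sensitivity=cp.sensitivity,
                    specificity=cp.specificity,
                    cutoff=cp.cutoff,
                    youden=cp.youden,
                    degenerate=cp.degenerate,
                ))
        else:
            raise ValueError(f"unknown combination rule {rule!r}")
    ranked = sorted(results, key=lambda r: (-r.auc, -r.sensitivity, -r.specificity, r.markers))
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    return ranked


def _logistic_score(member_values: pd.DataFrame, y: np.ndarray, seed: int) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression

    x = member_values.to_numpy(dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(max_iter=1000, random_state=seed)
    clf.fit((x - mu) / sd, y)
    return clf.decision_function((x - mu) / sd)


def panels_table(panels: list[PanelResult]) -> pd.DataFrame:
    """Ranked combination table: label, markers, AUC, sensitivity, specificity."""
    return pd.DataFrame(
        [
            {
                "rank": p.rank,
                "label": p.label,
                "markers": "+".join(p.markers),
                "n_markers": len(p.markers),
                "auc": p.auc,
                "sensitivity": p.sensitivity,
                "specificity": p.specificity,
                "cutoff": p.cutoff,
                "rule": p.rule,
            }
            for p in sorted(panels, key=lambda r: r.rank)
        ]
    )


class PanelDiscovery:
    """Screen-then-enumerate biomarker panel model for one channel.

    ``fit`` screens case vs pooled controls, applies BH FDR control at
    ``fdr`` (falling back to raw p < ``fallback_alpha`` when no antigen
    survives), and exhaustively scores panels built from the top
    candidates.
    """

    def __init__(
        self,
        rfu,
        annotations: pd.DataFrame,
        case: str,
        controls,
        fdr: float = 0.01,
        size_range: tuple[int, int] = (2, 6),
        top_m: int = 20,
        rule: str = "count_positive",
        test: str = "mannwhitney",
        fallback_alpha: float = 0.05,
        exclude_samples: list[str] | None = None,
        max_panels: int = 200_000,
        seed: int = 0,
    ):
        if isinstance(rfu, RFUMatrix):
            self.channel = rfu.channel
            self.values = rfu.values
        else:
            self.channel = ""
            self.values = rfu
        ann = annotations.set_index("sample_id") if "sample_id" in annotations.columns \
            else annotations
        self.groups = ann["group"].reindex(self.values.index)
        self.case = case
        self.controls = list(controls)
        self.fdr = fdr
        self.size_range = tuple(size_range)
        self.top_m = top_m
        self.rule = rule
        self.test = test
        self.fallback_alpha = fallback_alpha
        self.exclude_samples = list(exclude_samples or [])
        self.max_panels = max_panels
        self.seed = seed

    def fit(self) -> "PanelDiscoveryResults":
        keep = self.groups.isin([self.case] + self.controls)
        keep &= ~self.groups.index.isin(self.exclude_samples)
        vals = self.values.loc[keep]
        groups = self.groups.loc[keep]
        screen = marker_screen(vals, groups, self.case, self.controls, test=self.test)
        surviving = screen.index[screen["p_adj"] < self.fdr]
        fallback = False
        if len(surviving) < self.size_range[0]:
            # too few FDR survivors to build any panel: proceed with every
            # antigen that is individually significant at raw p
            fallback = True
            surviving = screen.index[screen["p_raw"] < self.fallback_alpha]
            log.warning(
                "only %d antigen(s) passed BH FDR %.3g; falling back to %d antigens "
                "at raw p < %.3g",
                (screen["p_adj"] < self.fdr).sum(), self.fdr, len(surviving),
                self.fallback_alpha,
            )
        ranked = screen.loc[surviving].sort_values(
            ["p_adj", "p_raw"], kind="stable"
        ).index.tolist()
        y = (groups == self.case).to_numpy()
        panels = enumerate_panels(
            vals, y, ranked, size_range=self.size_range, rule=self.rule,
            top_m=self.top_m, max_panels=self.max_panels, seed=self.seed,
        )
        return PanelDiscoveryResults(model=self, marker_stats=screen,
                                     candidates=ranked[: self.top_m],
                                     panels=panels, fallback_used=fallback)


@dataclass
class PanelDiscoveryResults:
    model: PanelDiscovery
    marker_stats: pd.DataFrame
    candidates: list[str]
    panels: list[PanelResult]
    fallback_used: bool

    @property
    def top_panel(self) -> PanelResult:
        return min(self.panels, key=lambda p: p.rank)

    def summary(self, top: int = 5) -> pd.DataFrame:
        return panels_table(self.panels).head(top)
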