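"""Control-anchored autoantibody positivity calling and reactivity profiling.

The central rule of the analysis: for every antigen, the positivity
threshold is the control-group mean plus two control-group standard
deviations of the (normalized) RFU, and a sample is called positive for the
antigen when its RFU lies *strictly above* that threshold.  On top of the
boolean call matrix this module computes

* per-sample positive-antigen counts and the symbol-grid reactivity
  categories (absent / weak / moderate / strong / very strong, with counts
  above 80 antigens labelled PSA — a polyspecific "sticky" phenotype rather
  than genuine titer);
* the per-sample antigen ratio (positive count / negative count) and the
  isotype-vs-subclass forest statistic: mean over samples of
  (isotype ratio - subclass ratio) with its 5%/95% confidence bounds, where
  more negative means the subclass carries more of the isotype's binding;
* one-way ANOVA with pairwise-versus-control Welch tests (Bonferroni), and
  paired IgG-vs-IgA positive-proportion comparisons.

:class:`PositivityModel` wraps the rule as a fitted model: thresholds are
estimated from the designated control samples by :meth:`~PositivityModel.fit`,
which returns a :class:`PositivityResults`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import RFUMatrix

PSA_COUNT = 80  # strictly more than this many positive antigens => PSA

CATEGORY_BINS = [
    ("absent", 0, 0),
    ("weak", 1, 29),
    ("moderate", 30, 47),
    ("strong", 48, 63),
    ("very_strong", 64, PSA_COUNT),
]

CATEGORY_SYMBOLS = {
    "absent": "–",  # en dash, as printed in reactivity grids
    "weak": "+",
    "moderate": "++",
    "strong": "+++",
    "very_strong": "++++",
    "PSA": "PSA",
}

STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def significance_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p <= level:
            return stars
    return "ns"


@dataclass
class PositivityThresholds:
    """Per-antigen mean+2SD thresholds estimated from a control group."""

    table: pd.DataFrame  # index antigen_id; columns mean, sd, threshold, n, degenerate
    control_group: str
    control_n: int

    @property
    def threshold(self) -> pd.Series:
        return self.table["threshold"]

    @property
    def degenerate(self) -> pd.Series:
        return self.table["degenerate"]


@dataclass
class PositivityMatrix:
    """Boolean call matrix with its thresholds and per-sample counts."""

    calls: pd.DataFrame  # nullable boolean, sample x antigen
    thresholds: PositivityThresholds
    channel: str = ""

    @property
    def positive_count(self) -> pd.Series:
        return self.calls.sum(axis=1).astype(int)

    @property
    def negative_count(self) -> pd.Series:
        return (self.calls == False).sum(axis=1).astype(int)  # noqa: E712 (nullable boolean)


def compute_thresholds(
    values: pd.DataFrame | RFUMatrix,
    control_sample_ids,
    control_group: str = "",
) -> PositivityThresholds:
    """Estimate mean+2SD positivity thresholds from control samples.

    Antigens with fewer than two non-missing control values are excluded
    from calling (dropped from the threshold table); antigens whose control
    sd is exactly zero are kept but flagged degenerate.
    """
    if isinstance(values, RFUMatrix):
        values = values.values
    control_sample_ids = list(control_sample_ids)
    missing = [s for s in control_sample_ids if s not in values.index]
    if missing:
        raise ValueError(f"control sample(s) not in matrix: {missing}")
    ctrl = values.loc[control_sample_ids]
    n = ctrl.notna().sum(axis=0)
    mean = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    tab = pd.DataFrame({"mean": mean, "sd": sd, "n": n})
    tab = tab[tab["n"] >= 2]
    tab["threshold"] = tab["mean"] + 2.0 * tab["sd"]
    tab["degenerate"] = tab["sd"] == 0.0
    return PositivityThresholds(table=tab, control_group=control_group,
                                control_n=len(control_sample_ids))


def call_positivity(
    values: pd.DataFrame | RFUMatrix,
    thresholds: PositivityThresholds,
    channel: str = "",
) -> PositivityMatrix:
    """Call every (sample, antigen) positive iff RFU > threshold (strict)."""
    if isinstance(values, RFUMatrix):
        channel = channel or values.channel
        values = values.values
    antigens = [a for a in values.columns if a in thresholds.table.index]
    v = values[antigens]
    thr = thresholds.threshold.reindex(antigens)
    calls = v.gt(thr, axis=1)
    calls = calls.astype("boolean").mask(v.isna())
    return PositivityMatrix(calls=calls, thresholds=thresholds, channel=channel)


def categorize_reactivity(positive_count: int) -> str:
    """Map a positive-antigen count onto the symbol-grid category key.

    0 -> absent, 1-29 -> weak, 30-47 -> moderate, 48-63 -> strong,
    64-80 -> very_strong, >80 -> PSA (polyspecific).
    """
    c = int(positive_count)
    if c < 0:
        raise ValueError("positive count cannot be negative")
    if c > PSA_COUNT:
        return "PSA"
    for name, lo, hi in CATEGORY_BINS:
        if lo <= c <= hi:
            return name
    raise AssertionError("unreachable: category bins cover 0..80")


def antigen_ratio(calls: pd.Series) -> float:
    """Positive/negative antigen-count ratio for one sample and channel.

    Returns ``inf`` (flagged undefined) when no antigen is negative; such
    samples are excluded from forest aggregation.
    """
    valid = calls.dropna()
    if valid.empty:
        return float("nan")
    pos = int(valid.sum())
    neg = int(len(valid) - pos)
    if neg == 0:
        return float("inf")
    return pos / neg


@dataclass
class RatioStat:
    """Isotype-minus-subclass mean antigen-ratio difference with CI bounds."""

    mean_difference: float
    ci_low: float
    ci_high: float
    n: int
    subclass: str = ""
    isotype: str = ""


def subclass_forest(
    ratios_isotype: pd.Series,
    ratios_subclass: pd.Series,
    method: str = "t",
    n_boot: int = 2000,
    seed: int = 0,
) -> RatioStat:
    """Forest statistic for one subclass against its isotype.

    The statistic is the mean of per-sample paired differences
    (isotype ratio - subclass ratio); the reported 5% and 95% bounds are the
    endpoints of a two-sided 90% interval (Student-t by default, percentile
    bootstrap optionally).  More negative values mean the subclass accounts
    for a larger share of the isotype's reactivity.
    """
    pair = pd.concat({"iso": ratios_isotype, "sub": ratios_subclass}, axis=1, join="inner")
    pair = pair.replace([np.inf, -np.inf], np.nan).dropna()
    n = len(pair)
    if n < 2:
        raise ValueError("subclass_forest needs >= 2 paired finite samples")
    diff = (pair["iso"] - pair["sub"]).to_numpy(dtype=float)
    m = float(diff.mean())
    if method == "t":
        se = diff.std(ddof=1) / math.sqrt(n)
        half = float(stats.t.ppf(0.95, n - 1)) * se
        lo, hi = m - half, m + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = rng.choice(diff, size=(n_boot, n), replace=True).mean(axis=1)
        lo, hi = (float(x) for x in np.quantile(boots, [0.05, 0.95]))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return RatioStat(mean_difference=m, ci_low=lo, ci_high=hi, n=n)


@dataclass
class GroupComparison:
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # group, n, mean, t, p_raw, p_adj, stars
    control_group: str


def compare_groups(values: pd.Series, groups: pd.Series, control_group: str) -> GroupComparison:
    """One-way ANOVA across groups plus Welch tests of each group vs control.

    Pairwise p-values are Bonferroni-adjusted over the family of
    non-control groups and mapped to stars at 0.05/0.01/0.001/0.0001.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    labels = list(dict.fromkeys(df["group"]))
    if control_group not in labels:
        raise ValueError(f"control group {control_group!r} not present")
    if len(labels) < 2:
        raise ValueError("compare_groups needs at least two groups")
    arrays = [df.loc[df["group"] == g, "value"].to_numpy(dtype=float) for g in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    f, p = stats.f_oneway(*arrays)
    ctrl = df.loc[df["group"] == control_group, "value"].to_numpy(dtype=float)
    rows = []
    others = [g for g in labels if g != control_group]
    for g in others:
        x = df.loc[df["group"] == g, "value"].to_numpy(dtype=float)
        t, praw = stats.ttest_ind(x, ctrl, equal_var=False)
        rows.append({"group": g, "n": len(x), "mean": float(x.mean()),
                     "t": float(t), "p_raw": float(praw)})
    pw = pd.DataFrame(rows)
    pw["p_adj"] = np.minimum(1.0, pw["p_raw"] * len(others))
    pw["stars"] = pw["p_adj"].map(significance_stars)
    return GroupComparison(anova_f=float(f), anova_p=float(p), pairwise=pw,
                           control_group=control_group)


def isotype_positive_proportion(
    calls_igg: PositivityMatrix | pd.DataFrame,
    calls_iga: PositivityMatrix | pd.DataFrame,
    groups: pd.Series,
) -> pd.DataFrame:
    """Paired per-group comparison of IgG vs IgA positive-antigen proportions.

    Wilcoxon signed-rank per group over the per-sample proportions, with
    Bonferroni adjustment over the groups tested.
    """
    g = calls_igg.calls if isinstance(calls_igg, PositivityMatrix) else calls_igg
    a = calls_iga.calls if isinstance(calls_iga, PositivityMatrix) else calls_iga
    common = g.index.intersection(a.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between IgG and IgA call matrices")
    prop_g = g.loc[common].mean(axis=1).astype(float)
    prop_a = a.loc[common].mean(axis=1).astype(float)
    grp = groups.reindex(common)
    rows = []
    for label in dict.fromkeys(grp.dropna()):
        idx = grp.index[grp == label]
        d = (prop_a.loc[idx] - prop_g.loc[idx]).to_numpy(dtype=float)
        if np.allclose(d, 0.0):
            praw = 1.0
        else:
            praw = float(stats.wilcoxon(d, zero_method="wilcox").pvalue)
        rows.append({"group": label, "n": len(idx),
                     "prop_IgG": float(prop_g.loc[idx].mean()),
                     "prop_IgA": float(prop_a.loc[idx].mean()),
                     "mean_diff_IgA_minus_IgG": float(d.mean()), "p_raw": praw})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * len(out))
    out["stars"] = out["p_adj"].map(significance_stars)
    return out


class PositivityModel:
    """Mean+2SD positivity model for one detection channel.

    Parameters
    ----------
    rfu : RFUMatrix or DataFrame
        Normalized sample x antigen RFU values.
    annotations : DataFrame
        Sample annotations with ``sample_id`` and ``group`` columns (and
        optional ``psa_<channel>`` flags from the simulator).
    control_group : str
        Group whose samples anchor the thresholds (healthy controls for
        serum, normal-adjacent for tissue).
    """

    def __init__(self, rfu, annotations: pd.DataFrame, control_group: str):
        if isinstance(rfu, RFUMatrix):
            self.channel = rfu.channel
            self.values = rfu.values
        else:
            self.channel = ""
            self.values = rfu
        self.annotations = annotations.set_index("sample_id") \
            if "sample_id" in annotations.columns else annotations
        self.control_group = control_group
        if control_group not in set(self.annotations["group"]):
            raise ValueError(f"control group {control_group!r} not in annotations")

    def fit(self) -> "PositivityResults":
        ctrl_ids = [s for s in self.values.index
                    if self.annotations.loc[s, "group"] == self.control_group]
        thr = compute_thresholds(self.values, ctrl_ids, control_group=self.control_group)
        calls = call_positivity(self.values, thr, channel=self.channel)
        return PositivityResults(model=self, thresholds=thr, calls=calls)


@dataclass
class PositivityResults:
    """Fitted positivity calls for one channel, with profile statistics."""

    model: PositivityModel
    thresholds: PositivityThresholds
    calls: PositivityMatrix

    @property
    def positive_count(self) -> pd.Series:
        return self.calls.positive_count

    @property
    def categories(self) -> pd.Series:
        return self.positive_count.map(categorize_reactivity)

    @property
    def symbols(self) -> pd.Series:
        return self.categories.map(CATEGORY_SYMBOLS)

    @property
    def antigen_ratios(self) -> pd.Series:
        return self.calls.calls.apply(antigen_ratio, axis=1)

    @property
    def psa_samples(self) -> list[str]:
        return list(self.positive_count.index[self.positive_count > PSA_COUNT])

    def summary(self) -> pd.DataFrame:
        groups = self.model.annotations["group"].reindex(self.calls.calls.index)
        return pd.DataFrame({
            "group": groups,
            "positive_count": self.positive_count,
            "negative_count": self.calls.negative_count,
            "category": self.categories,
            "symbol": self.symbols,
            "antigen_ratio": self.antigen_ratios,
        })


def reactivity_table(results: dict[str, PositivityResults]) -> pd.DataFrame:
    """Symbol grid (samples x channels) of reactivity categories."""
    cols = {ch: res.symbols for ch, res in results.items()}
    return pd.DataFrame(cols)
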