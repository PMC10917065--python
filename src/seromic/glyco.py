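"""Lectin-channel glycoform profiling.

Four lectins report glycan motifs on antigen-bound antibodies: RCA and ECL
(beta-1,4-galactose), SNA (alpha-2,6-sialic acid) and LCA
(alpha-1,6-fucose).  Positivity reuses the identical control mean+2SD
thresholding code path as antibody positivity; per-cohort "total
glycosylation" is summarized as the mean +/- SEM of the pooled
positive-antigen RFUs, and case-versus-pooled-controls differences are
tested per antigen with a Bonferroni correction over the antigens of each
lectin.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .positivity import call_positivity, compute_thresholds
from .preprocess import RFUMatrix

LECTIN_MOTIFS = {
    "RCA": "β1,4-Gal",
    "ECL": "β1,4-Gal",
    "SNA": "α2,6-SA",
    "LCA": "α1,6-Fuc",
}


def lectin_positivity(
    rfu,
    annotations: pd.DataFrame,
    control_group: str,
    min_cohort_fraction: float = 0.0,
) -> dict[str, set[str]]:
    """Cohort-positive antigen sets for one lectin channel.

    An antigen is positive for a cohort when more than
    ``min_cohort_fraction`` of the cohort's samples exceed the control
    mean+2SD threshold (default: any single sample suffices).
    """
    values = rfu.values if isinstance(rfu, RFUMatrix) else rfu
    ann = annotations.set_index("sample_id") if "sample_id" in annotations.columns \
        else annotations
    groups = ann["group"].reindex(values.index)
    ctrl_ids = list(values.index[groups == control_group])
    thr = compute_thresholds(values, ctrl_ids, control_group=control_group)
    calls = call_positivity(values, thr).calls
    out: dict[str, set[str]] = {}
    for label in dict.fromkeys(groups.dropna()):
        sub = calls.loc[groups == label]
        frac = sub.mean(axis=0).astype(float)
        out[label] = set(frac.index[frac > min_cohort_fraction])
    return out


def total_glyco_summary(values: pd.DataFrame, cohort_samples, positive_antigens) -> dict:
    """Mean and SEM over the pooled positive-antigen RFUs of one cohort."""
    antigens = sorted(positive_antigens)
    if not antigens:
        return {"n_positive_antigens": 0, "n_values": 0, "mean": None, "sem": None}
    pool = values.loc[list(cohort_samples), antigens].to_numpy(dtype=float).ravel()
    pool = pool[np.isfinite(pool)]
    n = pool.size
    mean = float(pool.mean())
    sem = 0.0 if n < 2 else float(pool.std(ddof=1) / np.sqrt(n))
    return {"n_positive_antigens": len(antigens), "n_values": int(n),
            "mean": mean, "sem": sem, "flag_n1": n == 1}


def lectin_contrast(
    values: pd.DataFrame,
    groups: pd.Series,
    case: str,
    controls,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-antigen case vs pooled-controls tests, Bonferroni over antigens.

    Returns a per-antigen table with the raw and Bonferroni-adjusted
    Mann-Whitney p-values and a significance flag at ``alpha``.
    """
    controls = list(controls)
    x = values.loc[groups == case].to_numpy(dtype=float)
    y = values.loc[groups.isin(controls)].to_numpy(dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("lectin_contrast needs n >= 3 per side")
    constant = np.ptp(np.concatenate([x, y]), axis=0) == 0
    res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided", method="asymptotic")
    p = np.where(constant | ~np.isfinite(np.asarray(res.pvalue, float)), 1.0,
                 np.asarray(res.pvalue, float))
    m = p.size
    p_adj = np.minimum(1.0, p * m)
    out = pd.DataFrame(
        {
            "case_mean": x.mean(axis=0),
            "control_mean": y.mean(axis=0),
            "p_raw": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=values.columns,
    )
    out.index.name = "antigen_id"
    return out


@dataclass
class LectinProfile:
    lectin: str
    motif: str
    positive_antigens: dict[str, set[str]]
    cohort_summary: pd.DataFrame  # cohort, n_positive, mean, sem
    contrast: pd.DataFrame
    significant_count: int


class LectinProfiler:
    """Glycoform profiling model over a set of lectin channels."""

    def __init__(
        self,
        rfu_by_channel: dict[str, RFUMatrix | pd.DataFrame],
        annotations: pd.DataFrame,
        control_group: str,
        case: str,
        controls,
        lectins: list[str] | None = None,
        min_cohort_fraction: float = 0.0,
        alpha: float = 0.05,
    ):
        self.lectins = lectins or [l for l in LECTIN_MOTIFS if l in rfu_by_channel]
        missing = [l for l in self.lectins if l not in rfu_by_channel]
        if missing:
            raise ValueError(f"lectin channel(s) not in data: {missing}")
        self.rfu = {l: (m.values if isinstance(m, RFUMatrix) else m)
                    for l, m in rfu_by_channel.items() if l in self.lectins}
        self.annotations = annotations.set_index("sample_id") \
            if "sample_id" in annotations.columns else annotations
        self.control_group = control_group
        self.case = case
        self.controls = list(controls)
        self.min_cohort_fraction = min_cohort_fraction
        self.alpha = alpha

    def fit(self) -> "LectinProfileResults":
        profiles: dict[str, LectinProfile] = {}
        for lectin in self.lectins:
            values = self.rfu[lectin]
            groups = self.annotations["group"].reindex(values.index)
            pos = lectin_positivity(values, self.annotations, self.control_group,
                                    self.min_cohort_fraction)
            rows = []
            for label, antigens in pos.items():
                cohort_samples = values.index[groups == label]
                s = total_glyco_summary(values, cohort_samples, antigens)
                rows.append({"cohort": label, **s})
            contrast = lectin_contrast(values, groups, self.case, self.controls,
                                       alpha=self.alpha)
            profiles[lectin] = LectinProfile(
                lectin=lectin,
                motif=LECTIN_MOTIFS.get(lectin, ""),
                positive_antigens=pos,
                cohort_summary=pd.DataFrame(rows),
                contrast=contrast,
                significant_count=int(contrast["significant"].sum()),
            )
        return LectinProfileResults(model=self, profiles=profiles)


@dataclass
class LectinProfileResults:
    model: "LectinProfiler"
    profiles: dict[str, LectinProfile]

    def significant_counts(self) -> pd.Series:
        return pd.Series({l: p.significant_count for l, p in self.profiles.items()},
                         name="significant_count")

    def summary(self) -> pd.DataFrame:
        frames = []
        for lectin, prof in self.profiles.items():
            t = prof.cohort_summary.copy()
            t.insert(0, "lectin", lectin)
            t.insert(1, "motif", prof.motif)
            t["significant_count"] = prof.significant_count
            frames.append(t)
        return pd.concat(frames, ignore_index=True)
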