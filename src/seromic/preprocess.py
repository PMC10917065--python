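"""Spot-level preprocessing: net fluorescence, replicate aggregation into
per-channel RFU matrices with coefficients of variation, and across-array
normalization.

Net intensity is the background-subtracted spot signal
(``foreground_median - local_background``); negative nets are retained —
positivity thresholding downstream decides what counts as signal — and are
only floored when a log transform requires it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .panel import AntigenPanel

log = logging.getLogger(__name__)

SATURATION_LEVEL = 65535.0
CV_WARN_DEFAULT = 0.20
LOG_FLOOR_EPSILON = 1.0


@dataclass
class RFUMatrix:
    """Per-channel sample x antigen relative-fluorescence matrix.

    ``values`` and ``cv`` share the same index (sample ids) and columns
    (antigen ids).  ``cv`` is NaN where fewer than two replicates survived
    or the replicate mean is non-positive.
    """

    values: pd.DataFrame
    cv: pd.DataFrame
    channel: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.cv.index) or not self.values.columns.equals(
            self.cv.columns
        ):
            raise ValueError("values and cv must share index and columns")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def antigens(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class QCReport:
    """Per-spot and per-entry quality flags, resolvable to their source rows."""

    spot_flags: pd.DataFrame  # sample_id, channel, antigen_id, replicate_index, reason
    replicate_flags: pd.DataFrame  # sample_id, channel, antigen_id, reason
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "spot_flags": self.spot_flags.to_dict(orient="records"),
            "replicate_flags": self.replicate_flags.to_dict(orient="records"),
            "summary": self.summary,
        }


def net_intensity(foreground_median, local_background):
    """Background-subtracted spot intensity (may be negative; not clipped)."""
    fg = np.asarray(foreground_median, dtype=float)
    bg = np.asarray(local_background, dtype=float)
    if not (np.all(np.isfinite(fg)) and np.all(np.isfinite(bg))):
        raise ValueError("net_intensity requires finite inputs")
    out = fg - bg
    return float(out) if out.ndim == 0 else out


def aggregate_replicates(
    spots: pd.DataFrame,
    panel: AntigenPanel,
    cv_warn: float = CV_WARN_DEFAULT,
) -> tuple[dict[str, RFUMatrix], QCReport]:
    """Aggregate replicate spots into one RFU matrix per detection channel.

    RFU is the mean net intensity over non-flagged replicates; CV the
    replicate sd/mean (NaN when the mean is non-positive).  Entries with
    fewer than two surviving replicates are flagged; entries where all
    replicates are flagged (or absent) become missing.
    """
    df = spots.copy()
    df["net"] = net_intensity(df["foreground_median"], df["local_background"])
    saturated = df["foreground_median"] >= SATURATION_LEVEL
    negative = df["net"] < 0
    preflagged = df["flag"] != 0
    spot_flag_frames = []
    for mask, reason in [(saturated, "saturated"), (negative, "negative_net"),
                         (preflagged, "scanner_flag")]:
        if mask.any():
            sf = df.loc[mask, ["sample_id", "channel", "antigen_id", "replicate_index"]].copy()
            sf["reason"] = reason
            spot_flag_frames.append(sf)
    # saturated or scanner-flagged spots are excluded from aggregation;
    # negative nets are kept (recorded only)
    df["excluded"] = saturated | preflagged

    keep = df[~df["excluded"]]
    grp = keep.groupby(["sample_id", "channel", "antigen_id"], sort=True)["net"]
    agg = grp.agg(rfu="mean", sd="std", n="size").reset_index()  # std: ddof=1

    # expected grid: every (sample, channel) seen x every panel antigen
    pairs = df[["sample_id", "channel"]].drop_duplicates()
    full = pairs.merge(pd.DataFrame({"antigen_id": panel.antigen_ids}), how="cross")
    agg = full.merge(agg, on=["sample_id", "channel", "antigen_id"], how="left")
    agg["n"] = agg["n"].fillna(0).astype(int)

    rep_flag_frames = []
    missing = agg["n"] < panel.n_replicates
    if missing.any():
        rf = agg.loc[missing, ["sample_id", "channel", "antigen_id"]].copy()
        rf["reason"] = "missing_replicates"
        rep_flag_frames.append(rf)
    low = (agg["n"] < 2) & (agg["n"] > 0)
    if low.any():
        rf = agg.loc[low, ["sample_id", "channel", "antigen_id"]].copy()
        rf["reason"] = "lt2_replicates"
        rep_flag_frames.append(rf)
    agg.loc[agg["n"] == 0, "rfu"] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        cv = agg["sd"] / agg["rfu"]
    cv = cv.where((agg["rfu"] > 0) & (agg["n"] >= 2))
    agg["cv"] = cv
    high_cv = agg["cv"] > cv_warn
    if high_cv.any():
        rf = agg.loc[high_cv, ["sample_id", "channel", "antigen_id"]].copy()
        rf["reason"] = "high_cv"
        rep_flag_frames.append(rf)

    matrices: dict[str, RFUMatrix] = {}
    sample_order = list(dict.fromkeys(spots["sample_id"]))
    for ch, sub in agg.groupby("channel", sort=True):
        vals = sub.pivot(index="sample_id", columns="antigen_id", values="rfu")
        cvs = sub.pivot(index="sample_id", columns="antigen_id", values="cv")
        order = [s for s in sample_order if s in vals.index]
        vals = vals.reindex(index=order, columns=panel.antigen_ids)
        cvs = cvs.reindex(index=order, columns=panel.antigen_ids)
        matrices[ch] = RFUMatrix(values=vals, cv=cvs, channel=str(ch),
                                 provenance={"normalization": "none"})

    empty_spot = pd.DataFrame(columns=["sample_id", "channel", "antigen_id",
                                       "replicate_index", "reason"])
    empty_rep = pd.DataFrame(columns=["sample_id", "channel", "antigen_id", "reason"])
    spot_flags = pd.concat(spot_flag_frames, ignore_index=True) if spot_flag_frames else empty_spot
    rep_flags = pd.concat(rep_flag_frames, ignore_index=True) if rep_flag_frames else empty_rep
    report = QCReport(
        spot_flags=spot_flags,
        replicate_flags=rep_flags,
        summary={
            "n_spots": int(len(df)),
            "n_saturated": int(saturated.sum()),
            "n_negative_net": int(negative.sum()),
            "n_scanner_flagged": int(preflagged.sum()),
            "n_missing_entries": int((agg["n"] == 0).sum()),
            "n_high_cv": int(high_cv.sum()),
            "cv_warn": cv_warn,
            "median_cv_per_channel": {
                str(ch): float(np.nanmedian(sub["cv"])) if sub["cv"].notna().any() else None
                for ch, sub in agg.groupby("channel", sort=True)
            },
        },
    )
    return matrices, report


def normalize(rfu: RFUMatrix, method: str = "median_scale",
              epsilon: float = LOG_FLOOR_EPSILON) -> RFUMatrix:
    """Across-sample normalization of one channel's RFU matrix.

    ``median_scale`` (default) rescales every sample to the global median of
    per-sample medians; rank-preserving within sample.  ``quantile`` is the
    classic quantile normalization (every sample gets the mean sorted
    profile).  ``none`` passes through.
    """
    if rfu.values.empty:
        raise ValueError("cannot normalize an empty matrix")
    prov = dict(rfu.provenance)
    if method == "none":
        prov["normalization"] = "none"
        return RFUMatrix(rfu.values.copy(), rfu.cv.copy(), rfu.channel, prov)
    if method == "median_scale":
        floored = rfu.values.clip(lower=epsilon)
        med = floored.median(axis=1)
        target = float(med.median())
        factors = target / med
        bad = ~np.isfinite(factors) | (med <= 0)
        if bad.any():
            log.warning("median_scale: %d sample(s) with non-positive median, left unscaled",
                        int(bad.sum()))
            factors[bad] = 1.0
        out = rfu.values.mul(factors, axis=0)
        prov.update(normalization="median_scale", target_median=target,
                    flagged_samples=list(rfu.values.index[bad]))
        return RFUMatrix(out, rfu.cv.copy(), rfu.channel, prov)
    if method == "quantile":
        v = rfu.values.to_numpy(dtype=float)
        order = np.argsort(v, axis=1, kind="stable")
        ranks = np.empty_like(order)
        n_s, n_a = v.shape
        ranks[np.arange(n_s)[:, None], order] = np.arange(n_a)
        reference = np.sort(v, axis=1).mean(axis=0)
        out = pd.DataFrame(reference[ranks], index=rfu.values.index,
                           columns=rfu.values.columns)
        prov["normalization"] = "quantile"
        return RFUMatrix(out, rfu.cv.copy(), rfu.channel, prov)
    raise ValueError(f"unknown normalization method {method!r}")
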