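"""End-to-end driver: simulate -> preprocess -> profile -> panels -> glyco ->
cluster -> report.

Every stage persists its outputs under the run directory and can be re-run
from those intermediates alone; long-format CSV is the canonical
interchange between stages (GAL/GPR dialects are accepted at ingestion).
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import gpr_io, report as report_mod
from .cluster import hcluster, log2_scale
from .cohort import CohortDesign, make_cohort
from .config import DataError, RunConfig
from .glyco import LectinProfiler
from .panel import make_panel
from .panels import PanelDiscovery, panels_table
from .positivity import (
    PSA_COUNT,
    PositivityModel,
    compare_groups,
    isotype_positive_proportion,
    reactivity_table,
    subclass_forest,
)
from .preprocess import aggregate_replicates, normalize
from .simulate import EffectSpec, PlantedEffect, simulate_spot_table

log = logging.getLogger(__name__)

ISOTYPE_SUBCLASSES = {"IgG": ["IgG1", "IgG2", "IgG3", "IgG4"], "IgA": ["IgA1", "IgA2"]}


def _annotations_path(run_dir: Path) -> Path:
    return run_dir / "annotations.csv"


def _load_annotations(run_dir: Path) -> pd.DataFrame:
    p = _annotations_path(run_dir)
    if not p.exists():
        raise DataError(f"missing {p}; run the simulate stage or provide annotations")
    ann = pd.read_csv(p)
    for c in ann.columns:
        if c.startswith("psa_"):
            ann[c] = ann[c].astype(bool)
    return ann


def stage_simulate(cfg: RunConfig, run_dir: Path) -> dict:
    run_dir.mkdir(parents=True, exist_ok=True)
    panel = make_panel(cfg.panel.n_ct, cfg.panel.n_ta, cfg.panel.n_replicates, seed=cfg.seed)
    design = CohortDesign(
        groups=[(g.label, g.n, g.specimen) for g in cfg.groups],
        channels=list(cfg.channels),
        psa_fraction=cfg.psa_fraction,
        seed=cfg.seed,
    )
    cohort = make_cohort(design)
    eff = cfg.effects
    effects = EffectSpec(
        planted_effects=[PlantedEffect(e.group, e.channel, e.antigen_id, e.log2_fc,
                                       e.penetrance) for e in eff.planted_effects],
        baseline_log_mean=eff.baseline_log_mean,
        baseline_log_sd=eff.baseline_log_sd,
        replicate_log_sd=eff.replicate_log_sd,
        antigen_log_sd=eff.antigen_log_sd,
        background_mean=eff.background_mean,
        background_sd=eff.background_sd,
        background_estimation_sd=eff.background_estimation_sd,
        psa_elevation=eff.psa_elevation,
        psa_n_range=tuple(eff.psa_n_range),
    )
    spots = simulate_spot_table(panel, cohort, effects, seed=cfg.seed)
    gpr_io.write_gal(panel, run_dir / "layout.gal")
    cohort.to_csv(_annotations_path(run_dir), index=False)
    gpr_io.write_spots_csv(spots, run_dir / "spots.csv")
    return {"n_antigens": panel.n_antigens, "n_spots": panel.n_spots,
            "n_samples": len(cohort), "n_spot_rows": len(spots)}


def stage_preprocess(cfg: RunConfig, run_dir: Path) -> dict:
    panel = gpr_io.read_gal(run_dir / "layout.gal")
    ann = _load_annotations(run_dir)
    spots = gpr_io.read_spot_tables(run_dir / "spots.csv", panel, ann)
    matrices, qc = aggregate_replicates(spots, panel, cv_warn=cfg.cv_warn)
    for ch, m in matrices.items():
        norm = normalize(m, cfg.normalization)
        norm.values.to_csv(run_dir / f"rfu_{ch}.csv")
        norm.cv.to_csv(run_dir / f"cv_{ch}.csv")
    qc_payload = qc.to_dict()
    # keep the JSON bounded: detailed flags are capped, counts live in summary
    qc_payload["spot_flags"] = qc_payload["spot_flags"][:1000]
    qc_payload["replicate_flags"] = qc_payload["replicate_flags"][:1000]
    (run_dir / "qc.json").write_text(json.dumps(qc_payload, indent=2, sort_keys=True) + "\n")
    return {"summary": qc.summary, "channels": sorted(matrices)}


def _load_rfu(run_dir: Path, channel: str) -> pd.DataFrame:
    p = run_dir / f"rfu_{channel}.csv"
    if not p.exists():
        raise DataError(f"missing {p}; run the preprocess stage first")
    return pd.read_csv(p, index_col=0)


def _present_channels(cfg: RunConfig, run_dir: Path) -> list[str]:
    return [ch for ch in cfg.channels if (run_dir / f"rfu_{ch}.csv").exists()]


def stage_profile(cfg: RunConfig, run_dir: Path) -> dict:
    ann = _load_annotations(run_dir)
    channels = _present_channels(cfg, run_dir)
    payload: dict = {"reactivity": {}, "forest": [], "group_comparisons": {},
                     "isotype_proportions": {}}
    for specimen in dict.fromkeys(ann["specimen"]):
        control = cfg.control_groups.get(specimen)
        sub_ann = ann[ann["specimen"] == specimen]
        if control is None or control not in set(sub_ann["group"]):
            log.warning("profile: no control group for specimen %r; skipped", specimen)
            continue
        results = {}
        for ch in channels:
            values = _load_rfu(run_dir, ch).loc[
                lambda v: v.index.isin(sub_ann["sample_id"])]
            res = PositivityModel(values, sub_ann, control).fit()
            results[ch] = res
            res.thresholds.table.to_csv(run_dir / f"thresholds_{specimen}_{ch}.csv")
            res.calls.calls.to_csv(run_dir / f"calls_{specimen}_{ch}.csv")
        grid = reactivity_table(results)
        grid.to_csv(run_dir / f"reactivity_{specimen}.csv")
        payload["reactivity"][specimen] = {
            "n_samples": len(grid),
            "psa_pairs": int(sum(len(r.psa_samples) for r in results.values())),
        }
        groups = sub_ann.set_index("sample_id")["group"]
        # isotype-vs-subclass forest statistics per group
        forest_rows = []
        for iso, subs in ISOTYPE_SUBCLASSES.items():
            if iso not in results:
                continue
            iso_res = results[iso]
            iso_ratio = iso_res.antigen_ratios
            if cfg.exclude_psa:
                iso_ratio = iso_ratio.drop(index=iso_res.psa_samples)
            for sc in subs:
                if sc not in results:
                    continue
                sc_res = results[sc]
                sc_ratio = sc_res.antigen_ratios
                if cfg.exclude_psa:
                    sc_ratio = sc_ratio.drop(index=sc_res.psa_samples, errors="ignore")
                for label in dict.fromkeys(groups):
                    ids = groups.index[groups == label]
                    try:
                        stat = subclass_forest(iso_ratio.reindex(ids),
                                               sc_ratio.reindex(ids))
                    except ValueError:
                        continue
                    forest_rows.append({
                        "specimen": specimen, "group": label, "isotype": iso,
                        "subclass": sc, "mean_difference": stat.mean_difference,
                        "ci_low": stat.ci_low, "ci_high": stat.ci_high, "n": stat.n,
                    })
        if forest_rows:
            pd.DataFrame(forest_rows).to_csv(run_dir / f"forest_{specimen}.csv", index=False)
        payload["forest"].extend(forest_rows)
        # per-channel mean-RFU group comparisons against the control group
        for ch in channels:
            values = _load_rfu(run_dir, ch).loc[
                lambda v: v.index.isin(sub_ann["sample_id"])]
            per_sample = values.mean(axis=1)
            try:
                cmp_res = compare_groups(per_sample, groups.reindex(per_sample.index),
                                         control)
            except ValueError:
                continue
            payload["group_comparisons"][f"{specimen}_{ch}"] = {
                "anova_f": cmp_res.anova_f, "anova_p": cmp_res.anova_p,
                "pairwise": cmp_res.pairwise.to_dict(orient="records"),
            }
        if "IgG" in results and "IgA" in results:
            prop = isotype_positive_proportion(results["IgG"].calls, results["IgA"].calls,
                                               groups)
            prop.to_csv(run_dir / f"isotype_proportion_{specimen}.csv", index=False)
            payload["isotype_proportions"][specimen] = prop.to_dict(orient="records")
    if payload["group_comparisons"]:
        rows = []
        for key, d in payload["group_comparisons"].items():
            for pw in d["pairwise"]:
                rows.append({"channel": key, "anova_f": d["anova_f"],
                             "anova_p": d["anova_p"], **pw})
        pd.DataFrame(rows).to_csv(run_dir / "group_comparisons.csv", index=False)
    return payload


def _psa_samples(run_dir: Path, specimen: str, channel: str) -> list[str]:
    p = run_dir / f"calls_{specimen}_{channel}.csv"
    if not p.exists():
        return []
    calls = pd.read_csv(p, index_col=0)
    counts = calls.fillna(False).astype(bool).sum(axis=1)
    return list(counts.index[counts > PSA_COUNT])


def stage_panels(cfg: RunConfig, run_dir: Path) -> dict:
    ann = _load_annotations(run_dir)
    serum = ann[ann["specimen"] == "serum"]
    if serum.empty:
        return {"skipped": "no serum samples"}
    payload: dict = {}
    for ch in [c for c in ("IgG", "IgA") if c in _present_channels(cfg, run_dir)]:
        values = _load_rfu(run_dir, ch).loc[lambda v: v.index.isin(serum["sample_id"])]
        excl = _psa_samples(run_dir, "serum", ch) if cfg.exclude_psa else []
        model = PanelDiscovery(
            values, serum, cfg.case, cfg.controls, fdr=cfg.fdr,
            size_range=cfg.panel_sizes, top_m=cfg.top_m, rule=cfg.combination_rule,
            exclude_samples=excl, max_panels=cfg.max_panels, seed=cfg.seed,
        )
        try:
            res = model.fit()
        except ValueError as exc:
            payload[ch] = {"skipped": str(exc)}
            continue
        tab = panels_table(res.panels)
        tab.to_csv(run_dir / f"panels_{ch}.csv", index=False)
        res.marker_stats.to_csv(run_dir / f"marker_stats_{ch}.csv")
        payload[ch] = {
            "n_candidates": len(res.candidates),
            "fallback_used": res.fallback_used,
            "n_panels": len(res.panels),
            "top": tab.head(5).to_dict(orient="records"),
        }
    return payload


def stage_glyco(cfg: RunConfig, run_dir: Path) -> dict:
    ann = _load_annotations(run_dir)
    serum = ann[ann["specimen"] == "serum"]
    lectins = [l for l in cfg.lectins if (run_dir / f"rfu_{l}.csv").exists()]
    if serum.empty or not lectins:
        return {"skipped": "no serum lectin channels"}
    rfu = {l: _load_rfu(run_dir, l).loc[lambda v: v.index.isin(serum["sample_id"])]
           for l in lectins}
    control = cfg.control_groups.get("serum")
    res = LectinProfiler(rfu, serum, control, cfg.case, cfg.controls,
                         lectins=lectins).fit()
    res.summary().to_csv(run_dir / "glyco_summary.csv", index=False)
    for l, prof in res.profiles.items():
        prof.contrast.to_csv(run_dir / f"glyco_{l}.csv")
    return {
        "significant_counts": {l: p.significant_count for l, p in res.profiles.items()},
        "n_positive": {l: {c: len(s) for c, s in p.positive_antigens.items()}
                       for l, p in res.profiles.items()},
    }


def stage_cluster(cfg: RunConfig, run_dir: Path) -> dict:
    ann = _load_annotations(run_dir)
    serum = ann[ann["specimen"] == "serum"]
    channels = _present_channels(cfg, run_dir)
    case_ids = serum.loc[serum["group"] == cfg.case, "sample_id"]
    if len(case_ids) == 0 or len(channels) < 2:
        return {"skipped": "need >= 2 channels and case samples"}
    rows = {}
    for ch in channels:
        values = _load_rfu(run_dir, ch)
        rows[ch] = values.loc[values.index.isin(case_ids)].mean(axis=0)
    feat = pd.DataFrame(rows).T  # features x antigens
    scaled = log2_scale(feat, epsilon=cfg.cluster.epsilon)
    scaled.to_csv(run_dir / "scaled_matrix.csv")
    fc = hcluster(scaled, distance=cfg.cluster.distance, linkage=cfg.cluster.linkage)
    (run_dir / "features.nwk").write_text(fc.to_newick() + "\n")
    ac = hcluster(scaled.T, distance=cfg.cluster.distance, linkage=cfg.cluster.linkage)
    (run_dir / "antigens.nwk").write_text(ac.to_newick() + "\n")
    return {
        "feature_leaf_order": [fc.labels[i] for i in fc.leaf_order],
        "n_antigen_leaves": len(ac.labels),
        "distance": cfg.cluster.distance,
        "linkage": cfg.cluster.linkage,
    }


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "profile": stage_profile,
    "panels": stage_panels,
    "glyco": stage_glyco,
    "cluster": stage_cluster,
}


def run_pipeline(cfg: RunConfig, run_dir: str | Path) -> dict:
    """Execute every stage in order and write the consolidated report."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    for name, fn in STAGES.items():
        t0 = time.perf_counter()
        try:
            outputs[name] = fn(cfg, run_dir)
        except Exception as exc:
            raise DataError(
                f"stage {name!r} failed: {exc}; fix the inputs or re-run earlier stages"
            ) from exc
        log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
    payload = report_mod.run_report(outputs, cfg.model_dump(mode="json"), cfg.seed, run_dir)
    if cfg.make_plots:
        _make_plots(cfg, run_dir, outputs)
    return payload


def _make_plots(cfg: RunConfig, run_dir: Path, outputs: dict) -> None:
    try:
        if (run_dir / "scaled_matrix.csv").exists():
            scaled = pd.read_csv(run_dir / "scaled_matrix.csv", index_col=0)
            fc = hcluster(scaled, distance=cfg.cluster.distance,
                          linkage=cfg.cluster.linkage)
            report_mod.plot_heatmap(scaled, fc, run_dir / "heatmap.png")
        forest = (outputs.get("profile") or {}).get("forest") or []
        if forest:
            report_mod.plot_forest(forest, run_dir / "forest.png")
        counts = (outputs.get("glyco") or {}).get("significant_counts")
        if counts:
            report_mod.plot_lectin_counts(counts, run_dir / "lectin_counts.png")
    except Exception:  # plotting must never fail the run
        log.exception("plotting failed")
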