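"""Run report: one JSON + markdown bundle gathering every stage's outputs,
validated against a packaged schema, plus optional plots."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

from pydantic import BaseModel


class ReportSchema(BaseModel):
    """Packaged schema the report payload must validate against."""

    config: dict
    seed: int
    stages_present: list[str]
    stages_missing: list[str]
    qc: Optional[dict] = None
    reactivity: Optional[dict] = None
    forest: Optional[list] = None
    group_comparisons: Optional[dict] = None
    panels: Optional[dict] = None
    glyco: Optional[dict] = None
    cluster: Optional[dict] = None


EXPECTED_STAGES = ["simulate", "preprocess", "profile", "panels", "glyco", "cluster"]


def run_report(stage_outputs: dict[str, Any], config: dict, seed: int,
               out_dir: str | Path) -> dict:
    """Assemble, validate and persist the run report.

    Missing stages are reported as explicit gaps rather than failing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    present = [s for s in EXPECTED_STAGES if s in stage_outputs]
    missing = [s for s in EXPECTED_STAGES if s not in stage_outputs]
    payload = ReportSchema(
        config=config,
        seed=seed,
        stages_present=present,
        stages_missing=missing,
        qc=stage_outputs.get("preprocess"),
        reactivity=(stage_outputs.get("profile") or {}).get("reactivity"),
        forest=(stage_outputs.get("profile") or {}).get("forest"),
        group_comparisons=(stage_outputs.get("profile") or {}).get("group_comparisons"),
        panels=stage_outputs.get("panels"),
        glyco=stage_outputs.get("glyco"),
        cluster=stage_outputs.get("cluster"),
    ).model_dump()
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    (out / "report.md").write_text(_markdown(payload))
    return payload


def _markdown(payload: dict) -> str:
    lines = ["# seromic run report", ""]
    lines.append(f"Seed: {payload['seed']}")
    lines.append(f"Stages completed: {', '.join(payload['stages_present']) or 'none'}")
    if payload["stages_missing"]:
        lines.append(f"Stages missing: {', '.join(payload['stages_missing'])}")
    if payload.get("qc"):
        lines += ["", "## QC", "```", json.dumps(payload["qc"].get("summary", {}),
                                                 indent=2, sort_keys=True), "```"]
    panels = payload.get("panels") or {}
    for ch, tab in panels.items():
        lines += ["", f"## Top panels ({ch})"]
        if isinstance(tab, dict) and tab.get("top"):
            hdr = list(tab["top"][0])
            lines.append("| " + " | ".join(hdr) + " |")
            lines.append("|" + "---|" * len(hdr))
            for row in tab["top"]:
                lines.append("| " + " | ".join(str(row[h]) for h in hdr) + " |")
    glyco = payload.get("glyco") or {}
    if glyco.get("significant_counts"):
        lines += ["", "## Lectin significant-antigen counts"]
        for l, c in glyco["significant_counts"].items():
            lines.append(f"- {l}: {c}")
    cluster = payload.get("cluster") or {}
    if cluster.get("feature_leaf_order"):
        lines += ["", "## Feature dendrogram leaf order",
                  ", ".join(cluster["feature_leaf_order"])]
    return "\n".join(lines) + "\n"


def plot_heatmap(scaled_matrix, cluster_result, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = cluster_result.leaf_order
    m = scaled_matrix.iloc[order]
    fig, ax = plt.subplots(figsize=(10, max(3, 0.4 * len(m))))
    im = ax.imshow(m.to_numpy(dtype=float), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(m)), m.index)
    ax.set_xlabel("antigens")
    fig.colorbar(im, ax=ax, label="log2 RFU / SD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_forest(forest_rows: list[dict], path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.5 * len(forest_rows))))
    for i, row in enumerate(forest_rows):
        ax.plot([row["ci_low"], row["ci_high"]], [i, i], "k-")
        ax.plot(row["mean_difference"], i, "ks")
    ax.axvline(0.0, color="grey", ls="--", lw=0.8)
    ax.set_yticks(range(len(forest_rows)), [r["subclass"] for r in forest_rows])
    ax.set_xlabel("mean isotype ratio − subclass ratio (5%–95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_lectin_counts(counts: dict[str, int], path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(list(counts), list(counts.values()))
    ax.set_ylabel("Bonferroni-significant antigens")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
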