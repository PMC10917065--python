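"""Cohort design: sample groups, detection channels and polyspecificity flags."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ISOTYPE_CHANNELS = ["IgG", "IgA"]
SUBCLASS_CHANNELS = ["IgG1", "IgG2", "IgG3", "IgG4", "IgA1", "IgA2"]
LECTIN_CHANNELS = ["RCA", "SNA", "LCA", "ECL"]
DEFAULT_CHANNELS = ISOTYPE_CHANNELS + SUBCLASS_CHANNELS + LECTIN_CHANNELS

#: serum cohorts of the default study design (case, two disease controls, healthy)
DEFAULT_SERUM_GROUPS = [
    ("PDAC", 30, "serum"),
    ("CP", 16, "serum"),
    ("DYS", 13, "serum"),
    ("LTBI", 30, "serum"),
]
#: matched tissue triplets
DEFAULT_TISSUE_GROUPS = [
    ("tumor", 8, "tissue"),
    ("normal_adjacent", 8, "tissue"),
    ("CP_tissue", 8, "tissue"),
]


@dataclass
class CohortDesign:
    """Groups, channels and the polyspecific-sample rate of a simulated study."""

    groups: list[tuple[str, int, str]] = field(default_factory=lambda: list(DEFAULT_SERUM_GROUPS))
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    psa_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g[0] for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        for label, n, specimen in self.groups:
            if n < 0:
                raise ValueError(f"group {label!r} has negative size")
            if specimen not in ("serum", "tissue"):
                raise ValueError(f"group {label!r}: specimen must be 'serum' or 'tissue'")
        if not 0.0 <= self.psa_fraction <= 1.0:
            raise ValueError("psa_fraction must lie in [0, 1]")


def make_cohort(design: CohortDesign) -> pd.DataFrame:
    """Expand a :class:`CohortDesign` into per-sample annotation records.

    Returns a DataFrame with one row per sample (``sample_id``, ``group``,
    ``specimen``) plus one boolean column ``psa_<channel>`` per detection
    channel, drawn Bernoulli(``psa_fraction``) from the design seed.  The
    design seed is stored in ``.attrs['seed']`` so downstream simulation is
    reproducible from the annotations alone.
    """
    rng = np.random.default_rng([design.seed, 0x0C07])
    recs = []
    for label, n, specimen in design.groups:
        for i in range(n):
            recs.append({"sample_id": f"{label}_{i + 1:03d}", "group": label, "specimen": specimen})
    ann = pd.DataFrame(recs, columns=["sample_id", "group", "specimen"])
    for ch in design.channels:
        ann[f"psa_{ch}"] = rng.random(len(ann)) < design.psa_fraction
    ann.attrs["seed"] = design.seed
    ann.attrs["channels"] = list(design.channels)
    return ann


def channels_of(annotations: pd.DataFrame) -> list[str]:
    """Detection channels recorded in an annotation table."""
    stored = annotations.attrs.get("channels")
    if stored:
        return list(stored)
    return [c[4:] for c in annotations.columns if c.startswith("psa_")]
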