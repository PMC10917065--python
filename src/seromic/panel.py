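"""Antigen panel definition and array geometry.

The default panel mirrors a commercial cancer-testis (CT) antigen array:
213 CT plus 49 tumor-associated (TA) antigen features, each spotted in
triplicate, with the replicate spots placed in distinct print blocks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPOT_COLUMNS = ["antigen_id", "antigen_class", "replicate_index", "block", "row", "column"]

DEFAULT_N_CT = 213
DEFAULT_N_TA = 49
DEFAULT_N_REPLICATES = 3


@dataclass
class AntigenPanel:
    """Identity and grid coordinates of every antigen spot on the array.

    Parameters
    ----------
    spots : DataFrame
        One row per spot with columns ``antigen_id``, ``antigen_class``
        (``CT`` or ``TA``), ``replicate_index`` (0-based), ``block``,
        ``row``, ``column`` (1-based grid coordinates).
    n_replicates : int
        Number of replicate spots per antigen.
    """

    spots: pd.DataFrame
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValueError(f"spot table missing columns: {missing}")
        coords = self.spots[["block", "row", "column"]]
        if coords.duplicated().any():
            dup = coords[coords.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate spot coordinate (block,row,column)={tuple(dup)}")
        counts = self.spots.groupby("antigen_id", sort=False).size()
        bad = counts[counts != self.n_replicates]
        if len(bad):
            raise ValueError(
                f"{len(bad)} antigen(s) do not have exactly {self.n_replicates} spots, "
                f"e.g. {bad.index[0]!r} has {int(bad.iloc[0])}"
            )

    @property
    def antigen_ids(self) -> list[str]:
        return list(dict.fromkeys(self.spots["antigen_id"]))

    @property
    def n_antigens(self) -> int:
        return len(self.antigen_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def antigen_classes(self) -> pd.Series:
        return self.spots.drop_duplicates("antigen_id").set_index("antigen_id")["antigen_class"]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AntigenPanel):
            return NotImplemented
        if self.n_replicates != other.n_replicates:
            return False
        a = self.spots[SPOT_COLUMNS].reset_index(drop=True)
        b = other.spots[SPOT_COLUMNS].reset_index(drop=True)
        return a.equals(b)


def make_panel(
    n_ct: int = DEFAULT_N_CT,
    n_ta: int = DEFAULT_N_TA,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
) -> AntigenPanel:
    """Construct a synthetic antigen panel laid out on a print grid.

    Antigens are named ``CT001..`` / ``TA001..`` and placed row-major on a
    near-square grid; replicate *r* of every antigen lives in block *r + 1*
    so replicates never share a block. The seed permutes antigen placement
    within the grid (the same permutation in every block, as a printing
    robot would).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be a positive integer")
    if n_ct < 0 or n_ta < 0 or n_ct + n_ta < 1:
        raise ValueError("panel must contain at least one antigen")
    ids = [f"CT{i + 1:03d}" for i in range(n_ct)] + [f"TA{i + 1:03d}" for i in range(n_ta)]
    classes = ["CT"] * n_ct + ["TA"] * n_ta
    n = len(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    width = max(1, math.ceil(math.sqrt(n)))
    rows, cols = np.divmod(np.arange(n), width)
    recs = []
    for rep in range(n_replicates):
        for pos, k in enumerate(order):
            recs.append(
                (ids[k], classes[k], rep, rep + 1, int(rows[pos]) + 1, int(cols[pos]) + 1)
            )
    spots = pd.DataFrame(recs, columns=SPOT_COLUMNS)
    spots = spots.sort_values(["antigen_id", "replicate_index"], kind="stable").reset_index(drop=True)
    return AntigenPanel(spots=spots, n_replicates=n_replicates)
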