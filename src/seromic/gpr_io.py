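"""Reading and writing array-layout (GAL-dialect) and spot-level (GPR-dialect)
text files, plus the long-format CSV used as canonical interchange.

Only the tab-separated dialects are supported: an ATF-style header followed
by a column-header line containing at least Block/Row/Column/ID/Name (GAL)
or Block/Row/Column/ID plus foreground/background medians (GPR).  Unknown
columns are ignored with a logged warning.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .panel import SPOT_COLUMNS, AntigenPanel
from .simulate import SPOT_TABLE_COLUMNS

log = logging.getLogger(__name__)

_GAL_COLUMNS = ["Block", "Row", "Column", "ID", "Name"]
_GPR_FG = "F1 Median"
_GPR_BG = "B1 Median"


class FormatError(ValueError):
    """Malformed layout or spot file."""


class ReconciliationError(ValueError):
    """Spot data that cannot be matched to the panel or annotations."""


def _read_atf(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    """Parse an ATF-style file: ``Key=Value`` header lines, then a TSV table."""
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    header_row = None
    for i, line in enumerate(lines):
        fields = line.rstrip("\n").split("\t")
        stripped = [f.strip().strip('"') for f in fields]
        if "Block" in stripped and "Column" in stripped:
            header_row = i
            break
        for f in stripped:
            if "=" in f:
                k, _, v = f.partition("=")
                meta[k.strip()] = v.strip()
    if header_row is None:
        raise FormatError(f"{path}: no Block/Column header line found")
    table = pd.read_csv(path, sep="\t", skiprows=header_row, dtype={"ID": str, "Name": str})
    table.columns = [c.strip().strip('"') for c in table.columns]
    return meta, table


def write_gal(panel: AntigenPanel, path: str | Path) -> None:
    p = Path(path)
    body = panel.spots[["block", "row", "column", "antigen_id", "antigen_class"]].copy()
    body.columns = _GAL_COLUMNS
    with p.open("w") as fh:
        fh.write("ATF\t1.0\n2\t5\n")
        fh.write('"Type=ArrayList V1.0"\n')
        fh.write(f'"BlockCount={int(panel.spots["block"].max())}"\n')
        body.to_csv(fh, sep="\t", index=False)


def read_gal(path: str | Path) -> AntigenPanel:
    """Read a GAL-dialect layout into an :class:`AntigenPanel`.

    Replicate count is inferred per antigen id; the ``Name`` column is taken
    as the antigen class when it is ``CT``/``TA``, otherwise the class is
    inferred from the id prefix (default ``TA``).
    """
    _, table = _read_atf(path)
    missing = [c for c in _GAL_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing GAL columns {missing}")
    extra = [c for c in table.columns if c not in _GAL_COLUMNS]
    if extra:
        log.warning("%s: ignoring unknown GAL columns %s", path, extra)
    spots = pd.DataFrame(
        {
            "antigen_id": table["ID"].astype(str),
            "antigen_class": [
                n if n in ("CT", "TA") else ("CT" if str(i).startswith("CT") else "TA")
                for n, i in zip(table["Name"].astype(str), table["ID"].astype(str))
            ],
            "block": table["Block"].astype(int),
            "row": table["Row"].astype(int),
            "column": table["Column"].astype(int),
        }
    )
    if spots[["block", "row", "column"]].duplicated().any():
        raise FormatError(f"{path}: clashing spot coordinates")
    counts = spots.groupby("antigen_id", sort=False).size()
    n_rep = int(counts.iloc[0])
    if (counts != n_rep).any():
        raise FormatError(f"{path}: unequal replicate counts across antigens")
    spots = spots.sort_values(["antigen_id", "block"], kind="stable").reset_index(drop=True)
    spots["replicate_index"] = spots.groupby("antigen_id", sort=False).cumcount()
    try:
        return AntigenPanel(spots=spots[SPOT_COLUMNS], n_replicates=n_rep)
    except ValueError as exc:  # pragma: no cover - AntigenPanel re-validates
        raise FormatError(str(exc)) from exc


def write_gpr(spots: pd.DataFrame, path: str | Path) -> None:
    """Write the spot rows of a single (sample, channel) as a GPR-dialect TSV."""
    samples = spots["sample_id"].unique()
    channels = spots["channel"].unique()
    if len(samples) != 1 or len(channels) != 1:
        raise ValueError("write_gpr expects rows of exactly one (sample, channel)")
    body = spots[["block", "row", "column", "antigen_id", "foreground_median",
                  "local_background", "flag"]].copy()
    body.columns = ["Block", "Row", "Column", "ID", _GPR_FG, _GPR_BG, "Flags"]
    body.insert(4, "Name", spots["antigen_id"].to_numpy())
    with Path(path).open("w") as fh:
        fh.write("ATF\t1.0\n4\t8\n")
        fh.write('"Type=Results V1.0"\n')
        fh.write(f'"Sample={samples[0]}"\n')
        fh.write(f'"Channel={channels[0]}"\n')
        body.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def write_gpr_set(spot_table: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for (samp, ch), grp in spot_table.groupby(["sample_id", "channel"], sort=True):
        p = out / f"{samp}__{ch}.gpr"
        write_gpr(grp, p)
        paths.append(p)
    return paths


def read_gpr(path: str | Path) -> pd.DataFrame:
    meta, table = _read_atf(path)
    if "Sample" not in meta or "Channel" not in meta:
        raise FormatError(f"{path}: GPR header lacks Sample=/Channel= metadata")
    needed = ["Block", "Row", "Column", "ID", _GPR_FG, _GPR_BG]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing GPR columns {missing}")
    out = pd.DataFrame(
        {
            "sample_id": meta["Sample"],
            "channel": meta["Channel"],
            "antigen_id": table["ID"].astype(str),
            "block": table["Block"].astype(int),
            "row": table["Row"].astype(int),
            "column": table["Column"].astype(int),
            "foreground_median": table[_GPR_FG].astype(float),
            "local_background": table[_GPR_BG].astype(float),
            "flag": table["Flags"].astype(int) if "Flags" in table.columns else 0,
        }
    )
    return out


def read_spot_tables(
    paths: list[str | Path] | str | Path,
    panel: AntigenPanel,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Read and merge GPR files and/or long CSVs, validating against the panel.

    Raises :class:`ReconciliationError` if a file names a sample absent from
    the annotations or antigens absent from the panel.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() == ".gpr":
            frames.append(read_gpr(p))
        else:
            df = pd.read_csv(p)
            needed = ["sample_id", "channel", "antigen_id", "foreground_median", "local_background"]
            missing = [c for c in needed if c not in df.columns]
            if missing:
                raise FormatError(f"{p}: long CSV missing columns {missing}")
            if "flag" not in df.columns:
                df["flag"] = 0
            frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    known_samples = set(annotations["sample_id"])
    bad_samples = sorted(set(merged["sample_id"]) - known_samples)
    if bad_samples:
        raise ReconciliationError(f"unknown sample(s) in spot data: {bad_samples}")
    bad_ant = sorted(set(merged["antigen_id"]) - set(panel.antigen_ids))
    if bad_ant:
        raise ReconciliationError(f"antigen id(s) absent from panel: {bad_ant}")
    if "replicate_index" not in merged.columns:
        merged["replicate_index"] = merged.groupby(
            ["sample_id", "channel", "antigen_id"], sort=False
        ).cumcount()
    for col in SPOT_TABLE_COLUMNS:
        if col not in merged.columns:
            merged[col] = 0
    return merged[SPOT_TABLE_COLUMNS]


def write_spots_csv(spot_table: pd.DataFrame, path: str | Path) -> None:
    spot_table.to_csv(path, index=False, float_format="%.6f")
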