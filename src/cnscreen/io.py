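"""Readers and writers for the pipeline's tab-separated formats.

All files are UTF-8 TSV with a header row.  Grid coordinates are 1-based on
disk and converted to the package's 0-based convention on read.  Missing
values are written as the literal token ``NA``; curated zeros (colonies
judged plated-but-dead) are written as rate 0 with a separate boolean
column so "no data" and "dead colony" stay distinguishable.

Colony table schema:
    plate, row, col, strain, carbon, nitrogen, replicate, time_s, area_px
    (optional trailing column: curated_zero as 0/1)

Matrix schema: first column ``strain``, remaining columns condition labels
(``carbon:nitrogen`` lowercase, two-digit replicate suffix for the six
glucose:ammonium replicates, e.g. ``glucose:ammonium01``).

Threshold schema: condition, direction {fast, slow}, fdr_level, z_threshold.
Gene-set files: two columns (term, gene), no header requirement enforced
beyond the column count.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    Condition,
    ConditionError,
    HitTable,
    PlateLayout,
    PlateSet,
    RateMatrix,
    ThresholdTable,
    WILDTYPE_STRAIN,
    ZScoreMatrix,
)

COLONY_COLUMNS = ("plate", "row", "col", "strain", "carbon", "nitrogen",
                  "replicate", "time_s", "area_px")


class FormatError(ValueError):
    """File does not match the documented schema."""


class ParseError(ValueError):
    """A cell failed to parse; the message cites the 1-based line number."""


class DuplicateRecordError(ValueError):
    """Two records share (plate, row, col, condition, time)."""


class EmptyInputError(ValueError):
    """The file contains a header but no data rows (or nothing at all)."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _to_numeric(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & df[column].notna() & (df[column].astype(str).str.strip() != "NA")
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        line = int(df.index[bad][0]) + 2
        raise ParseError(f"{path}: non-numeric {column} value "
                         f"{df[column][bad].iloc[0]!r} at line {line}")
    return converted


def read_colony_table(path: str | Path) -> list[PlateSet]:
    """Read a colony time-course table into one PlateSet per (plate, condition).

    Plate shapes are inferred from the largest row/column index present for
    each plate; positions without observations get a ``None`` strain entry
    in the layout unless another condition of the same plate names them.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, COLONY_COLUMNS, path)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    for col in ("plate", "row", "col", "replicate", "time_s", "area_px"):
        df[col] = _to_numeric(df, col, path)
    key = ["plate", "row", "col", "carbon", "nitrogen", "replicate", "time_s"]
    dup = df.duplicated(subset=key)
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise DuplicateRecordError(f"{path}: duplicate (plate,row,col,time) record at line {line}")
    has_curated = "curated_zero" in df.columns
    if has_curated:
        df["curated_zero"] = _to_numeric(df, "curated_zero", path).fillna(0).astype(int)

    # shared layouts: one per plate, across all conditions in the file
    shapes = {int(p): (int(g["row"].max()), int(g["col"].max()))
              for p, g in df.groupby("plate")}
    layouts: dict[int, PlateLayout] = {}
    for p, (nr, nc) in shapes.items():
        strains = np.full((nr, nc), None, dtype=object)
        layouts[p] = PlateLayout(p, strains, np.zeros((nr, nc), dtype=bool))
    for (p, r, c), g in df.groupby(["plate", "row", "col"]):
        lay = layouts[int(p)]
        strain = g["strain"].iloc[0]
        conflicting = g["strain"].nunique() > 1
        if conflicting:
            raise FormatError(f"{path}: position plate {int(p)} ({int(r)},{int(c)}) "
                              f"carries multiple strain ids")
        lay.strains[int(r) - 1, int(c) - 1] = strain
        lay.wildtype[int(r) - 1, int(c) - 1] = strain == WILDTYPE_STRAIN

    plate_sets: list[PlateSet] = []
    for (p, carbon, nitrogen, rep), g in df.groupby(
            ["plate", "carbon", "nitrogen", "replicate"], sort=True):
        try:
            cond = Condition(str(carbon), str(nitrogen), int(rep))
        except ConditionError as e:
            raise FormatError(f"{path}: {e}") from e
        obs = pd.DataFrame({
            "row": g["row"].astype(int) - 1,
            "col": g["col"].astype(int) - 1,
            "time_s": g["time_s"].astype(float),
            "area_px": g["area_px"].astype(float),
        }).reset_index(drop=True)
        lay = layouts[int(p)]
        curated = np.zeros(lay.shape, dtype=bool)
        if has_curated:
            flagged = g[g["curated_zero"] > 0]
            for r, c in zip(flagged["row"].astype(int), flagged["col"].astype(int)):
                curated[r - 1, c - 1] = True
        plate_sets.append(PlateSet(lay, cond, obs, curated))
    return plate_sets


def write_colony_table(plate_sets: Iterable[PlateSet], path: str | Path) -> None:
    """Write PlateSets back to the colony-table TSV schema (1-based grid)."""
    frames = []
    for ps in plate_sets:
        obs = ps.observations
        frame = pd.DataFrame({
            "plate": ps.layout.plate_index,
            "row": obs["row"].astype(int) + 1,
            "col": obs["col"].astype(int) + 1,
            "strain": [ps.layout.strains[r, c] for r, c in zip(obs["row"], obs["col"])],
            "carbon": ps.condition.carbon,
            "nitrogen": ps.condition.nitrogen,
            "replicate": ps.condition.replicate_tag,
            "time_s": obs["time_s"].to_numpy(),
            "area_px": obs["area_px"].to_numpy(),
            "curated_zero": [int(ps.curated_zero[r, c]) for r, c in zip(obs["row"], obs["col"])],
        })
        # curated-zero positions have no usable series but must appear so the
        # flag survives the round trip; emit a single zero-area record.
        flagged = np.argwhere(ps.curated_zero)
        if len(flagged):
            extra = pd.DataFrame({
                "plate": ps.layout.plate_index,
                "row": flagged[:, 0] + 1,
                "col": flagged[:, 1] + 1,
                "strain": [ps.layout.strains[r, c] for r, c in flagged],
                "carbon": ps.condition.carbon,
                "nitrogen": ps.condition.nitrogen,
                "replicate": ps.condition.replicate_tag,
                "time_s": 0.0,
                "area_px": 0.0,
                "curated_zero": 1,
            })
            frame = pd.concat([frame, extra], ignore_index=True)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False)


def _read_matrix_frame(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if df.empty or df.shape[1] < 2:
        raise EmptyInputError(f"{path}: empty or single-column matrix file")
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "strain"
    for label in df.columns:
        try:
            Condition.parse(label)
        except ConditionError as e:
            raise FormatError(f"{path}: unknown condition label {label!r}") from e
    return df.astype(float)


def read_rate_matrix(path: str | Path) -> RateMatrix:
    return RateMatrix(_read_matrix_frame(Path(path)))


def read_zscore_matrix(path: str | Path) -> ZScoreMatrix:
    return ZScoreMatrix(_read_matrix_frame(Path(path)))


def read_threshold_table(path: str | Path) -> ThresholdTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if df.empty:
        raise EmptyInputError(f"{path}: no threshold rows")
    _require_columns(df, ThresholdTable.COLUMNS, path)
    for label in df["condition"].unique():
        try:
            Condition.parse(label)
        except ConditionError as e:
            raise FormatError(f"{path}: unknown condition label {label!r}") from e
    df["fdr_level"] = _to_numeric(df, "fdr_level", path)
    df["z_threshold"] = _to_numeric(df, "z_threshold", path)
    return ThresholdTable(df)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Two-column (term, gene) TSV -> term -> gene-set map."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: gene-set files need two columns (term, gene)")
    if df.empty:
        raise EmptyInputError(f"{path}: no gene-set rows")
    term_col, gene_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for term, g in df.groupby(term_col):
        out[str(term)] = set(g[gene_col].astype(str))
    return out


def read_supplementary_matrix(path: str | Path, kind: str):
    """Dispatching reader for re-saved supplementary tables.

    ``kind`` is one of ``rates``, ``zscores``, ``thresholds``, ``gene_lists``.
    """
    readers = {
        "rates": read_rate_matrix,
        "zscores": read_zscore_matrix,
        "thresholds": read_threshold_table,
        "gene_lists": read_gene_sets,
    }
    if kind not in readers:
        raise ValueError(f"unknown supplementary kind: {kind!r}")
    return readers[kind](path)


def _write_matrix(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = "strain"
    out.to_csv(path, sep="\t", na_rep="NA")


def write_rate_matrix(matrix: RateMatrix, path: str | Path) -> None:
    """Strains as rows, condition labels as columns, missing cells as NA."""
    _write_matrix(matrix.table, path)


def write_zscore_matrix(matrix: ZScoreMatrix, path: str | Path) -> None:
    _write_matrix(matrix.table, path)


def write_threshold_table(thresholds: ThresholdTable, path: str | Path) -> None:
    thresholds.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_hit_table(hits: HitTable, path: str | Path) -> None:
    rows = []
    for label in hits.conditions:
        for direction, genes in (("fast", hits.fast.get(label, [])),
                                 ("slow", hits.slow.get(label, []))):
            for gene in genes:
                rows.append((label, direction, gene))
    pd.DataFrame(rows, columns=["condition", "direction", "gene"]).to_csv(
        path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> HitTable:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    fast: dict[str, list[str]] = {}
    slow: dict[str, list[str]] = {}
    for (label, direction), g in df.groupby(["condition", "direction"]):
        target = fast if direction == "fast" else slow
        target[str(label)] = list(g["gene"])
    return HitTable(fast, slow)
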