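"""Domain types shared across the screening pipeline.

The screen grows an arrayed deletion collection (16 plates of 16 x 24
colonies) on minimal media built from every pairwise combination of four
carbon sources and seven nitrogen sources.  The reference condition,
glucose:ammonium, is grown as six replicate plate sets.  These types carry
the data between stages: colony observations, plate layouts, per-position
rate grids, strain x condition matrices and the derived score tables.

Grid coordinates are 0-based internally; all file formats carry 1-based
row/column numbers (see :mod:`cnscreen.io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CARBON_SOURCES: tuple[str, ...] = ("glucose", "galactose", "ribose", "glycerol")
NITROGEN_SOURCES: tuple[str, ...] = (
    "ammonium",
    "proline",
    "glutamate",
    "glutamine",
    "arginine",
    "urea",
    "allantoin",
)

#: Default plate-array geometry of the screen.
N_PLATES = 16
N_ROWS = 16
N_COLS = 24
#: Wild-type replicate positions across the whole 16-plate array.
N_WILDTYPE = 701
#: Number of glucose:ammonium replicate plate sets merged into the reference.
N_GA_REPLICATES = 6

WILDTYPE_STRAIN = "WT"

_LABEL_RE = re.compile(r"^([a-z]+):([a-z]+?)(\d{2})?$")


class ConditionError(ValueError):
    """Unknown carbon/nitrogen source or unparseable condition label."""


@dataclass(frozen=True, order=True)
class Condition:
    """One metabolic environment: a carbon source paired with a nitrogen source.

    ``replicate_tag`` distinguishes the six glucose:ammonium replicate plate
    sets (1..6); it is 0 for single-instance conditions.
    """

    carbon: str
    nitrogen: str
    replicate_tag: int = 0

    def __post_init__(self) -> None:
        if self.carbon not in CARBON_SOURCES:
            raise ConditionError(f"unknown carbon source: {self.carbon!r}")
        if self.nitrogen not in NITROGEN_SOURCES:
            raise ConditionError(f"unknown nitrogen source: {self.nitrogen!r}")
        if self.replicate_tag < 0:
            raise ConditionError("replicate_tag must be >= 0")

    @property
    def label(self) -> str:
        """Serialized form, e.g. ``glucose:proline`` or ``glucose:ammonium01``."""
        tag = f"{self.replicate_tag:02d}" if self.replicate_tag else ""
        return f"{self.carbon}:{self.nitrogen}{tag}"

    @property
    def pair(self) -> "Condition":
        """The condition with the replicate tag stripped."""
        return Condition(self.carbon, self.nitrogen)

    @property
    def is_reference(self) -> bool:
        return self.carbon == "glucose" and self.nitrogen == "ammonium"

    @property
    def is_glycerol(self) -> bool:
        return self.carbon == "glycerol"

    @classmethod
    def parse(cls, label: str) -> "Condition":
        m = _LABEL_RE.match(label.strip().lower())
        if m is None:
            raise ConditionError(f"unparseable condition label: {label!r}")
        carbon, nitrogen, tag = m.groups()
        return cls(carbon, nitrogen, int(tag) if tag else 0)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def all_conditions() -> list[Condition]:
    """The 28 distinct (carbon, nitrogen) pairs, reference first."""
    conds = [Condition(c, n) for c in CARBON_SOURCES for n in NITROGEN_SOURCES]
    conds.sort(key=lambda c: (not c.is_reference, CARBON_SOURCES.index(c.carbon),
                              NITROGEN_SOURCES.index(c.nitrogen)))
    return conds


def condition_instances() -> list[Condition]:
    """All 33 plate-set instances grown in the screen.

    Six replicate instances of glucose:ammonium (tags 01..06) plus the 27
    other carbon:nitrogen pairs.
    """
    out = [Condition("glucose", "ammonium", k) for k in range(1, N_GA_REPLICATES + 1)]
    out += [c for c in all_conditions() if not c.is_reference]
    return out


@dataclass
class PlateLayout:
    """Strain assignment of one plate: a dense grid of strain ids.

    ``strains`` is an object array of shape (n_rows, n_cols); ``wildtype``
    is the matching boolean mask of wild-type replicate positions.
    """

    plate_index: int
    strains: np.ndarray
    wildtype: np.ndarray

    def __post_init__(self) -> None:
        self.strains = np.asarray(self.strains, dtype=object)
        self.wildtype = np.asarray(self.wildtype, dtype=bool)
        if self.strains.shape != self.wildtype.shape:
            raise ValueError("strains and wildtype masks differ in shape")
        if self.plate_index < 1:
            raise ValueError("plate_index is 1-based")

    @property
    def shape(self) -> tuple[int, int]:
        return self.strains.shape

    @property
    def n_wildtype(self) -> int:
        return int(self.wildtype.sum())


@dataclass
class PlateSet:
    """Colony observations for one plate grown in one condition instance.

    ``observations`` holds one row per scan per colony with 0-based
    ``row``/``col``, ``time_s`` and ``area_px`` columns.  ``curated_zero``
    flags positions manually judged non-viable; these are forced to growth
    rate 0 downstream regardless of their (missing) series.
    """

    layout: PlateLayout
    condition: Condition
    observations: pd.DataFrame
    curated_zero: np.ndarray | None = None

    def __post_init__(self) -> None:
        need = {"row", "col", "time_s", "area_px"}
        missing = need - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        if self.curated_zero is None:
            self.curated_zero = np.zeros(self.layout.shape, dtype=bool)
        self.curated_zero = np.asarray(self.curated_zero, dtype=bool)
        if self.curated_zero.shape != self.layout.shape:
            raise ValueError("curated_zero mask does not match layout shape")
        obs = self.observations
        n_rows, n_cols = self.layout.shape
        if len(obs) and ((obs["row"].max() >= n_rows) or (obs["col"].max() >= n_cols)
                         or (obs["row"].min() < 0) or (obs["col"].min() < 0)):
            raise ValueError("observations outside layout positions")
        if (obs["area_px"] < 0).any():
            raise ValueError("negative colony area")

    def series(self) -> "pd.core.groupby.DataFrameGroupBy":
        """Observations grouped per colony position, time-sorted."""
        return self.observations.sort_values("time_s").groupby(["row", "col"], sort=True)


@dataclass
class RatePlate:
    """Per-position growth rates of one plate (pixels/second, NaN = missing)."""

    plate_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, values: np.ndarray) -> "RatePlate":
        return RatePlate(self.plate_index, np.asarray(values, dtype=float))


@dataclass
class RateMatrix:
    """Strains x condition-instances growth-rate matrix (NaN = missing).

    ``table`` is indexed by strain id with condition labels as columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.astype(float)
        vals = self.table.to_numpy()
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("growth rates must be >= 0 or missing")
        # validates the labels
        self.conditions  # noqa: B018

    @property
    def strains(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> list[Condition]:
        return [Condition.parse(c) for c in self.table.columns]


@dataclass
class ZScoreMatrix:
    """Strain-level modified z-scores per condition instance.

    ``plate_sd`` carries the per-(plate, condition-instance) residual SD that
    enters the z denominator; indexed by plate, columns are instance labels.
    ``wt_position_z`` keeps the per-position wild-type z values (before the
    strain-level collapse) that the null model is fitted from.
    """

    table: pd.DataFrame
    plate_sd: pd.DataFrame | None = None
    wt_position_z: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> list[Condition]:
        return [Condition.parse(c) for c in self.table.columns]


@dataclass
class ThresholdTable:
    """Condition-specific z thresholds per direction and FDR level.

    Long-form ``table`` with columns condition, direction, fdr_level,
    z_threshold.  Slow thresholds are <= 0, fast >= 0; +-inf sentinels mean
    "no rejection at this level".
    """

    table: pd.DataFrame

    COLUMNS = ("condition", "direction", "fdr_level", "z_threshold")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"threshold table missing columns: {sorted(missing)}")
        bad = ~self.table["direction"].isin(["fast", "slow"])
        if bad.any():
            raise ValueError("direction must be 'fast' or 'slow'")

    def lookup(self, condition: str | Condition, direction: str,
               fdr_level: float) -> float:
        label = condition.label if isinstance(condition, Condition) else condition
        t = self.table
        sel = t[(t["condition"] == label) & (t["direction"] == direction)
                & (np.isclose(t["fdr_level"], fdr_level))]
        if sel.empty:
            raise KeyError(f"no threshold for {label}/{direction}@{fdr_level}")
        return float(sel["z_threshold"].iloc[0])

    @property
    def fdr_levels(self) -> list[float]:
        return sorted(self.table["fdr_level"].unique())


@dataclass
class HitTable:
    """Per condition-instance lists of fast- and slow-growing deletions."""

    fast: dict[str, list[str]]
    slow: dict[str, list[str]]

    def __post_init__(self) -> None:
        for label in self.fast:
            overlap = set(self.fast[label]) & set(self.slow.get(label, []))
            if overlap:
                raise ValueError(f"genes both fast and slow in {label}: {sorted(overlap)[:3]}")

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.fast) | set(self.slow))

    def counts(self) -> pd.DataFrame:
        rows = [(label, len(self.fast.get(label, [])), len(self.slow.get(label, [])))
                for label in self.conditions]
        return pd.DataFrame(rows, columns=["condition", "n_fast", "n_slow"]).set_index("condition")
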