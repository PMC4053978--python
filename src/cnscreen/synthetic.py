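"""Synthetic screening experiments with known ground truth.

Emulates the screen's generative structure: a 16-plate array of 16 x 24
pinned colonies (one full wild-type plate, 701 wild-type positions in all)
grown across the 4 carbon x 7 nitrogen condition grid, with six replicate
plate sets of the glucose:ammonium reference.  Expected colony growth rate
is multiplicative — base rate x carbon effect x nitrogen effect x
carbon-nitrogen interaction x strain fitness x planted gene-environment
effect — after which a smooth additive spatial bias and multiplicative
log-normal observation noise are applied.  Colony area grows linearly from
the pin size, scanned at 0/5/10/24 h (plus 48 h on glycerol).

Planted gene-environment effects are the recoverable ground truth every
downstream stage is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CARBON_SOURCES,
    Condition,
    N_COLS,
    N_GA_REPLICATES,
    N_PLATES,
    N_ROWS,
    N_WILDTYPE,
    NITROGEN_SOURCES,
    PlateLayout,
    PlateSet,
    WILDTYPE_STRAIN,
)

HOUR = 3600.0
#: Scan times (seconds); glycerol conditions get one extra 48 h scan.
SCAN_TIMES_S = (0.0, 5 * HOUR, 10 * HOUR, 24 * HOUR)
GLYCEROL_EXTRA_SCAN_S = 48 * HOUR

DEFAULT_CARBON_MULT = {"glucose": 1.0, "galactose": 0.80, "ribose": 0.35, "glycerol": 0.15}
DEFAULT_NITROGEN_MULT = {"ammonium": 1.0, "glutamine": 0.97, "glutamate": 0.90,
                         "arginine": 0.85, "proline": 0.80, "allantoin": 0.70, "urea": 0.60}
#: Pairwise carbon x nitrogen interactions (1 = independent contributions).
#: Three non-reference cells are exactly 1, mirroring a grid where a few
#: source pairs genuinely combine independently.
DEFAULT_INTERACTION_MULT = {
    ("galactose", "proline"): 1.10, ("galactose", "glutamate"): 1.15,
    ("galactose", "glutamine"): 0.90, ("galactose", "arginine"): 1.10,
    ("galactose", "urea"): 0.85, ("galactose", "allantoin"): 1.00,
    ("ribose", "proline"): 1.20, ("ribose", "glutamate"): 1.40,
    ("ribose", "glutamine"): 0.85, ("ribose", "arginine"): 1.15,
    ("ribose", "urea"): 1.00, ("ribose", "allantoin"): 1.20,
    ("glycerol", "proline"): 1.15, ("glycerol", "glutamate"): 1.50,
    ("glycerol", "glutamine"): 0.90, ("glycerol", "arginine"): 1.00,
    ("glycerol", "urea"): 1.20, ("glycerol", "allantoin"): 1.25,
}


class SyntheticConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SyntheticConfig:
    """Parameters of the generator; defaults reproduce the screen's design.

    Geometry defaults to the real array (16 plates of 16 x 24, 701 wild-type
    positions, 4,772 mutants, six glucose:ammonium replicate plate sets, all
    28 conditions).  ``conditions`` may name a subset of (carbon, nitrogen)
    pairs to scale an experiment down; the reference pair is always included.
    """

    n_plates: int = N_PLATES
    n_rows: int = N_ROWS
    n_cols: int = N_COLS
    n_wildtype: int | None = None          # None -> 701 at full geometry, else derived
    n_strains: int = 4772
    n_ga_replicates: int = N_GA_REPLICATES
    conditions: list[tuple[str, str]] | None = None

    base_rate: float = 3.0e-3              # px/s, wild-type in glucose:ammonium
    initial_area: float = 20.0             # px, pin size
    carbon_mult: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CARBON_MULT))
    nitrogen_mult: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NITROGEN_MULT))
    interaction_mult: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_INTERACTION_MULT))
    strain_fitness_sd: float = 0.05        # log-scale SD of the healthy bulk;
                                           # most non-essential deletions grow within a
                                           # few percent of wild type in benign media
    sick_fraction: float = 0.12            # left tail of constitutively sick strains
    sick_log_mean: float = -0.35           # their median fitness multiplier (~0.70)
    sick_log_sd: float = 0.25

    n_planted_slow: int = 120
    n_planted_fast: int = 30
    slow_effect: float = 0.5               # multiplier for planted sensitivities
    fast_effect: float = 1.25              # faster-than-expected effects are modest
    ge_effect: dict[tuple[str, str], float] | None = None  # explicit plants override counts

    spatial_amplitude: float = 1.5e-4      # px/s, additive quadratic bias surface
    noise_sd: float = 0.05                 # log-normal multiplicative area noise
    missing_prob: float = 0.01             # probability a colony yields no series
    curated_zero_frac: float = 0.5         # fraction of failures flagged dead-not-missing

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SyntheticConfigError("noise_sd must be >= 0")
        if not (0 <= self.missing_prob < 1):
            raise SyntheticConfigError("missing_prob must be in [0, 1)")
        if self.n_strains < 1:
            raise SyntheticConfigError("need at least one mutant strain")
        if self.n_plates < 2:
            raise SyntheticConfigError("need the wild-type plate plus mutant plates")
        for m in (self.base_rate, self.slow_effect, self.fast_effect,
                  *self.carbon_mult.values(), *self.nitrogen_mult.values(),
                  *self.interaction_mult.values()):
            if m <= 0:
                raise SyntheticConfigError("all rate multipliers must be > 0")

    def condition_pairs(self) -> list[Condition]:
        if self.conditions is None:
            pairs = [Condition(c, n) for c in CARBON_SOURCES for n in NITROGEN_SOURCES]
        else:
            pairs = [Condition(c, n) for c, n in self.conditions]
            ref = Condition("glucose", "ammonium")
            if ref not in pairs:
                pairs = [ref] + pairs
        return pairs

    def instances(self) -> list[Condition]:
        """Condition instances grown: GA replicates first, then the rest."""
        pairs = self.condition_pairs()
        out = [Condition("glucose", "ammonium", k)
               for k in range(1, self.n_ga_replicates + 1)]
        out += [c for c in pairs if not c.is_reference]
        return out


@dataclass
class SyntheticTruth:
    """Fully realized ground truth of one simulated experiment."""

    seed: int
    config: SyntheticConfig
    strain_fitness: dict[str, float]
    ge_effect: dict[tuple[str, str], float]
    spatial_field: dict[tuple[str, int], np.ndarray]

    def expected_rate(self, strain: str, condition: Condition) -> float:
        """Multiplicative expectation before spatial bias and noise."""
        cfg = self.config
        inter = cfg.interaction_mult.get((condition.carbon, condition.nitrogen), 1.0)
        ge = self.ge_effect.get((strain, condition.pair.label), 1.0)
        return (cfg.base_rate * cfg.carbon_mult[condition.carbon]
                * cfg.nitrogen_mult[condition.nitrogen] * inter
                * self.strain_fitness[strain] * ge)


@dataclass
class SyntheticExperiment:
    plate_sets: list[PlateSet]
    truth: SyntheticTruth

    @property
    def layouts(self) -> dict[int, PlateLayout]:
        return {ps.layout.plate_index: ps.layout for ps in self.plate_sets}


def design_layouts(n_plates: int = N_PLATES, n_rows: int = N_ROWS,
                   n_cols: int = N_COLS, n_wildtype: int | None = None,
                   n_strains: int = 4772) -> list[PlateLayout]:
    """Build the plate array: one full wild-type plate plus scattered replicates.

    Plate 1 is entirely wild-type.  The remaining wild-type replicates are
    spread over every other plate on a generalized diagonal that touches
    every row (and most columns), topped to the requested total — 701 for
    the full geometry.
    """
    area = n_rows * n_cols
    if n_wildtype is None:
        if (n_plates, n_rows, n_cols) == (N_PLATES, N_ROWS, N_COLS):
            n_wildtype = N_WILDTYPE
        else:
            n_wildtype = area + (n_plates - 1) * (n_rows + 5)
    scattered = n_wildtype - area
    if scattered < n_plates - 1:
        raise SyntheticConfigError(
            f"n_wildtype={n_wildtype} too small for a full wild-type plate "
            f"plus one replicate per remaining plate")
    quota, extra = divmod(scattered, n_plates - 1)

    mutants = [f"mut{i:04d}" for i in range(1, n_strains + 1)]
    layouts = []
    wt_plate = PlateLayout(1, np.full((n_rows, n_cols), WILDTYPE_STRAIN, dtype=object),
                           np.ones((n_rows, n_cols), dtype=bool))
    layouts.append(wt_plate)
    cursor = 0
    for k in range(2, n_plates + 1):
        q = quota + (1 if (k - 2) < extra else 0)
        wt_mask = np.zeros((n_rows, n_cols), dtype=bool)
        placed = 0
        i = 0
        while placed < q:
            r = i % n_rows
            c = (7 * k + 5 * i) % n_cols
            if not wt_mask[r, c]:
                wt_mask[r, c] = True
                placed += 1
            i += 1
        strains = np.full((n_rows, n_cols), None, dtype=object)
        strains[wt_mask] = WILDTYPE_STRAIN
        for r in range(n_rows):
            for c in range(n_cols):
                if strains[r, c] is None:
                    strains[r, c] = mutants[cursor % n_strains]
                    cursor += 1
        layouts.append(PlateLayout(k, strains, wt_mask))
    total = sum(lay.n_wildtype for lay in layouts)
    assert total == n_wildtype, (total, n_wildtype)
    return layouts


def _quadratic_surface(rng: np.random.Generator, n_rows: int, n_cols: int,
                       amplitude: float) -> np.ndarray:
    """Smooth low-order polynomial bias, scaled to the requested amplitude."""
    y = (np.arange(n_rows)[:, None] - (n_rows - 1) / 2) / max(n_rows - 1, 1)
    x = (np.arange(n_cols)[None, :] - (n_cols - 1) / 2) / max(n_cols - 1, 1)
    coef = rng.uniform(-1, 1, size=5)
    surf = coef[0] * y + coef[1] * x + coef[2] * y * x + coef[3] * y**2 + coef[4] * x**2
    surf -= surf.mean()
    peak = np.abs(surf).max()
    if peak > 0:
        surf *= amplitude / peak
    return surf


def simulate_experiment(config: SyntheticConfig | None = None,
                        seed: int = 0) -> SyntheticExperiment:
    """Generate a full synthetic screen; identical seeds give identical output."""
    cfg = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(seed)
    layouts = design_layouts(cfg.n_plates, cfg.n_rows, cfg.n_cols,
                             cfg.n_wildtype, cfg.n_strains)
    mutants = [f"mut{i:04d}" for i in range(1, cfg.n_strains + 1)]

    # left-skewed single-mutant fitness: a tight healthy bulk plus a tail of
    # constitutively sick strains (sick in every condition, so the effect
    # cancels in the gene-environment z-scores)
    fitness = {WILDTYPE_STRAIN: 1.0}
    draws = rng.lognormal(mean=0.0, sigma=cfg.strain_fitness_sd, size=cfg.n_strains)
    if cfg.sick_fraction > 0:
        sick = rng.random(cfg.n_strains) < cfg.sick_fraction
        draws[sick] = rng.lognormal(mean=cfg.sick_log_mean, sigma=cfg.sick_log_sd,
                                    size=int(sick.sum()))
    fitness.update(dict(zip(mutants, draws)))

    if cfg.ge_effect is not None:
        ge = {(s, Condition.parse(lbl).pair.label): m
              for (s, lbl), m in cfg.ge_effect.items()}
    else:
        plantable = [c.label for c in cfg.condition_pairs()
                     if not c.is_reference and not c.is_glycerol]
        ge = {}
        n_slow, n_fast = cfg.n_planted_slow, cfg.n_planted_fast
        if plantable and (n_slow + n_fast) > 0:
            combos = [(s, lbl) for s in mutants for lbl in plantable]
            take = rng.choice(len(combos), size=min(n_slow + n_fast, len(combos)),
                              replace=False)
            for j, idx in enumerate(take):
                s, lbl = combos[idx]
                ge[(s, lbl)] = cfg.slow_effect if j < min(n_slow, len(take)) else cfg.fast_effect

    instances = cfg.instances()
    spatial: dict[tuple[str, int], np.ndarray] = {}
    for cond in instances:
        for lay in layouts:
            spatial[(cond.label, lay.plate_index)] = _quadratic_surface(
                rng, cfg.n_rows, cfg.n_cols, cfg.spatial_amplitude)

    truth = SyntheticTruth(seed, cfg, fitness, ge, spatial)

    plate_sets: list[PlateSet] = []
    for cond in instances:
        times = np.array(SCAN_TIMES_S + ((GLYCEROL_EXTRA_SCAN_S,) if cond.is_glycerol else ()))
        for lay in layouts:
            rates = np.empty(lay.shape)
            for r in range(lay.shape[0]):
                for c in range(lay.shape[1]):
                    rates[r, c] = truth.expected_rate(lay.strains[r, c], cond)
            rates = np.maximum(rates + spatial[(cond.label, lay.plate_index)], 1e-9)

            fail = rng.random(lay.shape) < cfg.missing_prob
            curated = fail & (rng.random(lay.shape) < cfg.curated_zero_frac)
            dropped = fail & ~curated

            areas = cfg.initial_area + rates[:, :, None] * times[None, None, :]
            if cfg.noise_sd > 0:
                noise = rng.lognormal(mean=0.0, sigma=cfg.noise_sd, size=areas.shape)
                areas = areas * noise

            keep = ~fail
            rr, cc = np.nonzero(keep)
            obs = pd.DataFrame({
                "row": np.repeat(rr, len(times)),
                "col": np.repeat(cc, len(times)),
                "time_s": np.tile(times, len(rr)),
                "area_px": areas[rr, cc, :].ravel(),
            })
            del dropped  # dropped colonies simply have no observations
            plate_sets.append(PlateSet(lay, cond, obs, curated))
    return SyntheticExperiment(plate_sets, truth)


def truth_table(experiment: SyntheticExperiment) -> pd.DataFrame:
    """Exact list of planted gene-environment effects.

    Columns: strain, condition (pair label), direction (slow if the planted
    multiplier < 1 else fast), effect (the multiplier).  Depends only on the
    carried truth, so it is invariant to any reordering of the plate sets.
    """
    rows = [(s, lbl, "slow" if m < 1 else "fast", m)
            for (s, lbl), m in sorted(experiment.truth.ge_effect.items())]
    return pd.DataFrame(rows, columns=["strain", "condition", "direction", "effect"])


def small_config(**overrides) -> SyntheticConfig:
    """A scaled-down configuration for fast exercises of the full pipeline.

    4 plates of 8 x 12 (one all wild-type), 300 mutants, six reference
    replicates, and a complete 4-carbon x 3-nitrogen sub-grid (a full cross
    keeps the wild-type interaction model identifiable).  Everything else
    keeps the full-scale defaults.
    """
    base = dict(
        n_plates=4, n_rows=8, n_cols=12, n_strains=300,
        conditions=[(c, n) for c in CARBON_SOURCES
                    for n in ("ammonium", "proline", "urea")],
        n_planted_slow=12, n_planted_fast=4,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def null_calibration_config(**overrides) -> SyntheticConfig:
    """An isogenic, effect-free array for null calibration of the hit caller.

    All strains share wild-type fitness and no gene-environment effects are
    planted, so every colony is statistically exchangeable and any called
    hit is a false discovery — the simulated analogue of screening an
    all-wild-type collection, which is exactly the exchangeability the 701
    wild-type replicate null relies on.  Observation noise and the spatial
    bias field stay on; colony dropout is off so random deaths do not
    masquerade as slow hits.
    """
    base = dict(
        n_plates=8, n_rows=12, n_cols=16, n_strains=1300,
        conditions=[(c, n) for c in CARBON_SOURCES
                    for n in ("ammonium", "proline", "urea")],
        n_planted_slow=0, n_planted_fast=0,
        strain_fitness_sd=0.0, sick_fraction=0.0, missing_prob=0.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)
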