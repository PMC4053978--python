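"""Colony area time courses -> growth rates.

The growth rate of a colony is the slope of the ordinary least-squares
linear fit of area (pixels) against time (seconds), with an intercept
(pinned colonies start at a nonzero area).  Colonies with fewer than two
finite observations get a missing rate (NaN); fitted negative slopes are
defined to be 0.  Clamping happens at the rate level, before any
normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import Condition, PlateSet, RatePlate, RateMatrix


class TimeOrderError(ValueError):
    """Timestamps within one colony must be strictly increasing."""


class LayoutMismatchError(ValueError):
    """Plate sets disagree on the strain layout of a plate."""


def fit_growth_rate(times_s, areas_px) -> float:
    """OLS slope of area on time; NaN if < 2 finite points; clamped at 0.

    Equivalent to the closed form  sum((t-t.mean())*(a-a.mean())) /
    sum((t-t.mean())**2).
    """
    t = np.asarray(times_s, dtype=float)
    a = np.asarray(areas_px, dtype=float)
    if t.ndim != 1 or t.shape != a.shape:
        raise ValueError("times and areas must be 1-D and equal length")
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise TimeOrderError("timestamps must be strictly increasing")
    finite = np.isfinite(t) & np.isfinite(a)
    if finite.sum() < 2:
        return float("nan")
    t, a = t[finite], a[finite]
    tc = t - t.mean()
    slope = float(tc @ (a - a.mean()) / (tc @ tc))
    return max(slope, 0.0)


def rate_plate(plate_set: PlateSet) -> RatePlate:
    """Per-position growth rates for one PlateSet.

    Positions with no observations are missing unless flagged curated-zero,
    which forces rate 0 (colony judged plated but non-viable).
    """
    values = np.full(plate_set.layout.shape, np.nan)
    obs = plate_set.observations
    if len(obs):
        srt = obs.sort_values(["row", "col", "time_s"])
        rows = srt["row"].to_numpy(int)
        cols = srt["col"].to_numpy(int)
        t = srt["time_s"].to_numpy(float)
        a = srt["area_px"].to_numpy(float)
        colony = rows * plate_set.layout.shape[1] + cols
        starts = np.flatnonzero(np.r_[True, np.diff(colony) != 0])
        sizes = np.diff(np.r_[starts, len(colony)])
        if len(set(sizes)) == 1 and sizes[0] >= 2 and \
                np.all(t.reshape(-1, sizes[0]) == t[:sizes[0]]):
            # common scan grid across the plate: one vectorized OLS
            tg = t[:sizes[0]]
            am = a.reshape(-1, sizes[0])
            if np.isfinite(tg).all() and np.isfinite(am).all() and np.all(np.diff(tg) > 0):
                tc = tg - tg.mean()
                slopes = (am - am.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
                values[rows[starts], cols[starts]] = np.maximum(slopes, 0.0)
            else:
                for s, n in zip(starts, sizes):
                    values[rows[s], cols[s]] = fit_growth_rate(t[s:s + n], a[s:s + n])
        else:
            for s, n in zip(starts, sizes):
                values[rows[s], cols[s]] = fit_growth_rate(t[s:s + n], a[s:s + n])
    values[plate_set.curated_zero] = 0.0
    return RatePlate(plate_set.layout.plate_index, values)


def rate_plates(plate_sets: list[PlateSet]) -> dict[str, dict[int, RatePlate]]:
    """Rates organized as condition-instance label -> plate index -> RatePlate.

    Raises LayoutMismatchError if two plate sets disagree on a plate's
    strain grid.
    """
    seen_layouts: dict[int, np.ndarray] = {}
    out: dict[str, dict[int, RatePlate]] = {}
    for ps in plate_sets:
        p = ps.layout.plate_index
        if p in seen_layouts:
            if seen_layouts[p].shape != ps.layout.strains.shape or \
                    not (seen_layouts[p] == ps.layout.strains).all():
                raise LayoutMismatchError(f"conflicting layouts for plate {p}")
        else:
            seen_layouts[p] = ps.layout.strains
        out.setdefault(ps.condition.label, {})[p] = rate_plate(ps)
    return out


def build_rate_matrix(plate_sets: list[PlateSet]) -> RateMatrix:
    """Assemble a strains x condition-instances rate matrix.

    Strains occupying several positions keep position identity through the
    normalization stages; here (an I/O-facing summary) replicate positions
    of one strain are averaged per condition instance.
    """
    grids = rate_plates(plate_sets)
    layouts = {ps.layout.plate_index: ps.layout for ps in plate_sets}
    labels = sorted(grids, key=lambda lbl: Condition.parse(lbl))
    strains = sorted({s for lay in layouts.values() for s in lay.strains.ravel()
                      if s is not None})
    sums = pd.DataFrame(0.0, index=strains, columns=labels)
    counts = pd.DataFrame(0, index=strains, columns=labels)
    for label, per_plate in grids.items():
        for p, rp in per_plate.items():
            lay = layouts[p]
            flat_strains = lay.strains.ravel()
            flat_rates = rp.values.ravel()
            ok = np.isfinite(flat_rates) & (flat_strains != None)  # noqa: E711
            agg = pd.Series(flat_rates[ok]).groupby(pd.Series(flat_strains[ok])).agg(["sum", "count"])
            sums.loc[agg.index, label] += agg["sum"].to_numpy()
            counts.loc[agg.index, label] += agg["count"].to_numpy()
    with np.errstate(invalid="ignore"):
        table = sums / counts.replace(0, np.nan)
    return RateMatrix(table)
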