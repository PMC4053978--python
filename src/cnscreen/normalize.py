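"""Reference construction, LOWESS plate normalization and spatial smoothing.

The glucose:ammonium reference is built per array plate from six replicate
plate sets: the replicate with the fewest missing values anchors the other
five, which are LOWESS-rescaled to it before all six are averaged.  Every
experimental plate is then LOWESS-normalized against its reference plate,
which removes the wholesale rate difference between the condition and the
reference so that residuals reflect strain-specific deviation.  A spatial
filter subtracts smooth within-plate bias (row/column gradients from, for
example, uneven pinning or media thickness).

The LOWESS step multiplies each rate by the smoothed (target/plate) ratio
regressed on the plate's own rate — a rate-dependent rescaling toward the
target that leaves identical plates untouched and recovers any constant
scale factor exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .datatypes import RatePlate

DEFAULT_LOWESS_FRAC = 0.5
#: Gaussian spatial-filter scale in grid units; smooths over neighborhoods
#: larger than one colony but smaller than plate-scale gradients.
DEFAULT_GAUSSIAN_SIGMA = 2.0
MIN_JOINT_POSITIONS = 10


class InsufficientOverlapError(ValueError):
    """Fewer than 10 jointly finite positions between plate and target."""


class ReplicateArityError(ValueError):
    """The reference requires exactly six glucose:ammonium replicates."""


@dataclass
class ReferenceModel:
    """Per-plate glucose:ammonium reference rates and replicate variability.

    ``ga_ref``: plate index -> reference RatePlate (positionwise mean of the
    six mutually normalized replicates).  ``strain_sd``: plate index ->
    positionwise sample SD of the six replicates' residuals about the
    reference.  ``anchor_id``: which replicate (0-based) served as the
    anchor for each plate.
    """

    ga_ref: dict[int, RatePlate]
    anchor_id: dict[int, int]
    strain_sd: dict[int, np.ndarray]
    lowess_frac: float = DEFAULT_LOWESS_FRAC

    @property
    def plate_indices(self) -> list[int]:
        return sorted(self.ga_ref)


def lowess_normalize(plate: RatePlate, target: RatePlate,
                     frac: float = DEFAULT_LOWESS_FRAC) -> RatePlate:
    """Rescale ``plate`` toward ``target`` by a LOWESS-smoothed ratio.

    The (target/plate) ratio is regressed on the plate's own rate over
    jointly finite, nonzero positions (window = ``frac`` of those points,
    locally linear, one robustifying iteration) and each finite plate rate
    is multiplied by the smoothed ratio at that rate.  Zero rates pass
    through unchanged (dead colonies stay dead); positions missing in
    ``plate`` stay missing.
    """
    if plate.shape != target.shape:
        raise ValueError("plate and target do not share a layout")
    pv, tv = plate.values, target.values
    joint = np.isfinite(pv) & np.isfinite(tv) & (pv > 0)
    if joint.sum() < MIN_JOINT_POSITIONS:
        raise InsufficientOverlapError(
            f"only {int(joint.sum())} jointly finite positions (need "
            f">= {MIN_JOINT_POSITIONS})")
    x = pv[joint]
    ratio = tv[joint] / x

    out = pv.copy()
    evaluate = np.isfinite(pv) & (pv > 0)
    smoothed = _sm_lowess(ratio, x, frac=frac, it=1, xvals=pv[evaluate])
    out[evaluate] = pv[evaluate] * smoothed
    return plate.copy_with(out)


def build_reference(ga_replicates: dict[int, list[RatePlate]],
                    frac: float = DEFAULT_LOWESS_FRAC) -> ReferenceModel:
    """Merge six glucose:ammonium replicate plates per array plate.

    Per plate index: the replicate with the fewest missing positions is held
    out as the anchor, the other five are LOWESS-normalized to it, and the
    six are averaged positionwise (missing values excluded).  The
    positionwise sample SD of the six residuals about that mean is the
    strain-wise SD entering the z-score denominator.
    """
    ga_ref: dict[int, RatePlate] = {}
    anchor_id: dict[int, int] = {}
    strain_sd: dict[int, np.ndarray] = {}
    for p, reps in ga_replicates.items():
        if len(reps) != 6:
            raise ReplicateArityError(
                f"plate {p}: got {len(reps)} glucose:ammonium replicates, need 6")
        missing = [int(np.isnan(r.values).sum()) for r in reps]
        anchor = int(np.argmin(missing))
        normalized = [r if i == anchor else lowess_normalize(r, reps[anchor], frac)
                      for i, r in enumerate(reps)]
        stack = np.stack([r.values for r in normalized])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN positions
            ref = np.nanmean(stack, axis=0)
            resid = stack - ref[None, :, :]
            sd = np.nanstd(resid, axis=0, ddof=1)
        ga_ref[p] = RatePlate(p, ref)
        anchor_id[p] = anchor
        strain_sd[p] = sd
    return ReferenceModel(ga_ref, anchor_id, strain_sd, frac)


def normalize_condition(plate: RatePlate, reference: ReferenceModel) -> RatePlate:
    """LOWESS-normalize one experimental plate against its reference plate."""
    if plate.plate_index not in reference.ga_ref:
        raise KeyError(f"plate {plate.plate_index} absent from reference model")
    if not np.isfinite(plate.values).any():
        return plate.copy_with(plate.values.copy())
    return lowess_normalize(plate, reference.ga_ref[plate.plate_index],
                            reference.lowess_frac)


def spatial_smooth(plate: RatePlate, sigma: float = DEFAULT_GAUSSIAN_SIGMA,
                   extreme_frac: float = 0.05) -> RatePlate:
    """Subtract the smooth spatial bias of a plate.

    Extreme values (the top and bottom ``extreme_frac`` of the finite
    distribution) and missing positions are temporarily replaced by the
    plate mean so that missing positions can be infilled from a Gaussian
    filter without being corrupted by outliers.  The extreme values are
    then restored (the replacement is only temporary), the infilled plate
    is Gaussian-smoothed, and the zero-mean residual between that smoothed
    plate and its mean is subtracted from the input.  Originally missing
    positions remain missing, and the plate mean is preserved.
    """
    v = plate.values
    finite = np.isfinite(v)
    if not finite.any():
        warnings.warn("spatial_smooth: all-missing plate returned unchanged")
        return plate.copy_with(v.copy())
    mean = v[finite].mean()
    lo, hi = np.nanquantile(v, [extreme_frac, 1 - extreme_frac])
    trimmed = v.copy()
    trimmed[~finite | (v < lo) | (v > hi)] = mean

    # first pass only supplies infill values for the missing positions
    first_pass = gaussian_filter(trimmed, sigma=sigma, truncate=3.0, mode="reflect")
    infilled = v.copy()
    infilled[~finite] = first_pass[~finite]
    smoothed = gaussian_filter(infilled, sigma=sigma, truncate=3.0, mode="reflect")
    residual = smoothed - smoothed.mean()
    out = v - residual
    out[~finite] = np.nan
    return plate.copy_with(out)
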