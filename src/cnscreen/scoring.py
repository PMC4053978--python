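"""Modified z-scores, wild-type null model, FDR thresholds and hit tables.

For each plate under each condition the residual between the normalized
rate and the glucose:ammonium reference is standardized by the combined
variability sqrt(sd_strain^2 + sd_plate^2): the strain-wise SD comes from
the six reference replicates at that position, the plate-wise SD is the SD
of the residuals across the plate under that condition (general growth
variation on the plate).  A z-score is negative when the strain grew slower
in the test condition than its reference behaviour predicts.

The 701 wild-type replicate positions provide a per-condition empirical
null: a normal distribution fitted by moments to the wild-type z-scores.
One-sided p-values against that null feed a Benjamini-Hochberg step-up per
(condition, direction) family, which converts a desired FDR into
condition-specific z thresholds and fast/slow hit lists.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    Condition,
    HitTable,
    PlateLayout,
    RatePlate,
    ThresholdTable,
    ZScoreMatrix,
)
from .normalize import ReferenceModel

DEFAULT_FDR = 0.20
FDR_LEVELS = (0.10, 0.20)
MIN_WILDTYPE_NULL = 100


class UndefinedZError(ValueError):
    """Zero combined variance at one or more positions."""


class InsufficientNullError(ValueError):
    """Too few wild-type values to fit a condition's null."""


def compute_zscores(normalized: dict[str, dict[int, RatePlate]],
                    reference: ReferenceModel,
                    layouts: dict[int, PlateLayout],
                    collapse: str = "z") -> ZScoreMatrix:
    """Z-scores from normalized (and spatially smoothed) rate plates.

    ``normalized`` maps condition-instance label -> plate index -> RatePlate.
    Strains occupying several positions are collapsed by averaging their
    per-position z-scores (``collapse="z"``) or their rates before scoring
    (``collapse="rate"``).  Wild-type positions are kept per-position in
    ``wt_position_z`` for the null fit; the returned table holds mutant
    strains only.
    """
    if collapse not in ("z", "rate"):
        raise ValueError("collapse must be 'z' or 'rate'")
    per_label: dict[str, pd.Series] = {}
    plate_sd_rows: dict[str, dict[int, float]] = {}
    wt_z: dict[str, np.ndarray] = {}
    for label, per_plate in normalized.items():
        strain_vals: dict[str, list[float]] = {}
        wt_vals: list[np.ndarray] = []
        sd_row: dict[int, float] = {}
        for p, rp in per_plate.items():
            ref = reference.ga_ref[p].values
            resid = rp.values - ref
            finite = np.isfinite(resid)
            if finite.sum() >= 2:
                sd_plate = float(np.std(resid[finite], ddof=1))
            else:
                sd_plate = np.nan
            sd_row[p] = sd_plate
            denom = np.sqrt(reference.strain_sd[p] ** 2 + sd_plate ** 2)
            bad = finite & (denom == 0)
            if bad.any():
                positions = [(p, int(r) + 1, int(c) + 1) for r, c in np.argwhere(bad)]
                raise UndefinedZError(
                    f"zero combined variance at (plate,row,col): {positions[:10]}")
            with np.errstate(invalid="ignore"):
                z = resid / denom
            lay = layouts[p]
            wt_vals.append(z[lay.wildtype & np.isfinite(z)])
            mut = ~lay.wildtype
            for r, c in zip(*np.nonzero(mut)):
                strain_vals.setdefault(lay.strains[r, c], [])
                if np.isfinite(z[r, c]):
                    strain_vals[lay.strains[r, c]].append(
                        (resid[r, c], denom[r, c]) if collapse == "rate" else z[r, c])
        if collapse == "rate":
            collapsed = {s: (np.mean([t[0] for t in v]) / np.mean([t[1] for t in v]))
                         if v else np.nan for s, v in strain_vals.items()}
        else:
            collapsed = {s: float(np.mean(v)) if v else np.nan
                         for s, v in strain_vals.items()}
        per_label[label] = pd.Series(collapsed)
        plate_sd_rows[label] = sd_row
        wt_z[label] = np.concatenate(wt_vals) if wt_vals else np.array([])

    labels = sorted(per_label, key=lambda lbl: Condition.parse(lbl))
    table = pd.DataFrame({lbl: per_label[lbl] for lbl in labels}).sort_index()
    plate_sd = pd.DataFrame({lbl: pd.Series(plate_sd_rows[lbl]) for lbl in labels})
    return ZScoreMatrix(table, plate_sd, wt_z)


def fit_null(zmatrix: ZScoreMatrix,
             min_wildtype: int = MIN_WILDTYPE_NULL) -> pd.DataFrame:
    """Per-condition mean/SD of wild-type z-scores (the replicate null).

    Returns a frame indexed by condition label with columns mean, sd, n.
    Uses only the wild-type position z-scores, so it is invariant to every
    mutant value.
    """
    rows = {}
    for label in zmatrix.table.columns:
        vals = np.asarray(zmatrix.wt_position_z.get(label, []), dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < min_wildtype:
            raise InsufficientNullError(
                f"{label}: {len(vals)} wild-type z values (need >= {min_wildtype})")
        sd = float(np.std(vals, ddof=1))
        if sd <= 1e-12 * max(1.0, abs(float(np.mean(vals)))):
            raise InsufficientNullError(f"{label}: wild-type z SD must be > 0")
        rows[label] = {"mean": float(np.mean(vals)), "sd": sd, "n": len(vals)}
    return pd.DataFrame(rows).T[["mean", "sd", "n"]]


def bh_thresholds(zmatrix: ZScoreMatrix, null: pd.DataFrame,
                  fdr: float | Sequence[float] = DEFAULT_FDR) -> ThresholdTable:
    """Condition-specific fast/slow z thresholds at the requested FDR level(s).

    One-sided p-values from the fitted wild-type normal (lower tail for
    slow, upper tail for fast), Benjamini-Hochberg step-up applied within
    each (condition, direction) family; the threshold is the least extreme
    z among rejected tests, or an infinite sentinel when nothing is
    rejected.
    """
    levels = [fdr] if np.isscalar(fdr) else list(fdr)
    for level in levels:
        if not 0 < level < 1:
            raise ValueError(f"fdr level {level} outside (0, 1)")
    rows = []
    for label in zmatrix.table.columns:
        if label not in null.index:
            raise KeyError(f"no null model for condition {label}")
        mu, sd = null.loc[label, "mean"], null.loc[label, "sd"]
        z = zmatrix.table[label].dropna()
        p_slow = stats.norm.cdf(z, loc=mu, scale=sd)
        p_fast = stats.norm.sf(z, loc=mu, scale=sd)
        for level in levels:
            for direction, pvals in (("slow", p_slow), ("fast", p_fast)):
                if len(z):
                    reject = multipletests(pvals, alpha=level, method="fdr_bh")[0]
                else:
                    reject = np.zeros(0, dtype=bool)
                if reject.any():
                    zr = z.to_numpy()[reject]
                    thr = float(zr.max()) if direction == "slow" else float(zr.min())
                else:
                    thr = -np.inf if direction == "slow" else np.inf
                rows.append((label, direction, level, thr))
    return ThresholdTable(pd.DataFrame(rows, columns=list(ThresholdTable.COLUMNS)))


def call_hits(zmatrix: ZScoreMatrix, thresholds: ThresholdTable,
              fdr_level: float = DEFAULT_FDR) -> HitTable:
    """Fast/slow gene lists per condition at one FDR level.

    Slow list: genes with z <= the slow threshold; fast list: z >= the fast
    threshold.  Monotone: making a z more extreme never removes a hit.
    """
    fast: dict[str, list[str]] = {}
    slow: dict[str, list[str]] = {}
    for label in zmatrix.table.columns:
        z = zmatrix.table[label].dropna()
        slow_thr = thresholds.lookup(label, "slow", fdr_level)
        fast_thr = thresholds.lookup(label, "fast", fdr_level)
        slow[label] = sorted(z.index[z <= slow_thr])
        fast[label] = sorted(z.index[z >= fast_thr])
    return HitTable(fast, slow)


def hit_count_summary(hits: HitTable) -> pd.DataFrame:
    """Per (carbon, nitrogen) pair fast/slow counts, replicate-averaged.

    Replicate instances of one condition pair (the six glucose:ammonium
    plate sets) are averaged, which is why a reference count can be
    fractional.
    """
    per_pair: dict[str, dict[str, list[int]]] = {}
    for label in hits.conditions:
        pair = Condition.parse(label).pair.label
        rec = per_pair.setdefault(pair, {"fast": [], "slow": []})
        rec["fast"].append(len(hits.fast.get(label, [])))
        rec["slow"].append(len(hits.slow.get(label, [])))
    rows = [(pair, float(np.mean(rec["fast"])), float(np.mean(rec["slow"])))
            for pair, rec in sorted(per_pair.items())]
    return pd.DataFrame(rows, columns=["condition", "n_fast", "n_slow"]).set_index("condition")


def count_effects_per_gene(hits: HitTable,
                           exclude: Iterable[str] = ()) -> pd.DataFrame:
    """Number of distinct condition pairs in which each gene is a hit.

    Replicate instances collapse to their condition pair before counting;
    pairs named in ``exclude`` (e.g. ``glucose:ammonium``) are dropped.
    Returns a frame indexed by gene with columns n_slow, n_fast.
    """
    excluded = {Condition.parse(lbl).pair.label for lbl in exclude}
    slow_pairs: dict[str, set[str]] = {}
    fast_pairs: dict[str, set[str]] = {}
    for label in hits.conditions:
        pair = Condition.parse(label).pair.label
        if pair in excluded:
            continue
        for gene in hits.slow.get(label, []):
            slow_pairs.setdefault(gene, set()).add(pair)
        for gene in hits.fast.get(label, []):
            fast_pairs.setdefault(gene, set()).add(pair)
    genes = sorted(set(slow_pairs) | set(fast_pairs))
    return pd.DataFrame({
        "n_slow": [len(slow_pairs.get(g, ())) for g in genes],
        "n_fast": [len(fast_pairs.get(g, ())) for g in genes],
    }, index=pd.Index(genes, name="gene"))


def randomized_effect_counts(hits: HitTable, genes: Sequence[str],
                             exclude: Iterable[str] = (), n_rand: int = 1000,
                             seed: int = 0) -> pd.DataFrame:
    """Null distribution of per-gene effect counts under random assignment.

    Preserves each condition's hit count while assigning hits to genes
    uniformly at random (the control used when judging whether genes
    accumulate effects across conditions more often than an FDR-matched
    random scatter would produce).  Returns the mean number of genes with
    >= k slow effects for k = 1..max, over ``n_rand`` randomizations.
    """
    rng = np.random.default_rng(seed)
    excluded = {Condition.parse(lbl).pair.label for lbl in exclude}
    counts_per_pair: dict[str, int] = {}
    for label in hits.conditions:
        pair = Condition.parse(label).pair.label
        if pair in excluded:
            continue
        counts_per_pair[pair] = max(counts_per_pair.get(pair, 0),
                                    len(hits.slow.get(label, [])))
    genes = list(genes)
    max_k = max(len(counts_per_pair), 1)
    tallies = np.zeros(max_k)
    for _ in range(n_rand):
        per_gene = np.zeros(len(genes), dtype=int)
        for pair, n in counts_per_pair.items():
            chosen = rng.choice(len(genes), size=min(n, len(genes)), replace=False)
            per_gene[chosen] += 1
        for k in range(1, max_k + 1):
            tallies[k - 1] += (per_gene >= k).sum()
    tallies /= n_rand
    return pd.DataFrame({"k": np.arange(1, max_k + 1), "mean_genes_ge_k": tallies})


def sensitive_genes(hits: HitTable, carbon: str = "galactose",
                    min_conditions: int = 4, direction: str = "slow") -> set[str]:
    """Genes with a significant defect in >= ``min_conditions`` distinct
    conditions sharing one carbon source (galactose sensitivity: >= 4 of 7)."""
    per_gene: dict[str, set[str]] = {}
    lists = hits.slow if direction == "slow" else hits.fast
    for label, genes in lists.items():
        cond = Condition.parse(label)
        if cond.carbon != carbon:
            continue
        for gene in genes:
            per_gene.setdefault(gene, set()).add(cond.pair.label)
    return {g for g, pairs in per_gene.items() if len(pairs) >= min_conditions}
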