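"""End-to-end orchestration of the screening pipeline.

Stages run in the order the data flow demands: growth rates -> reference
construction -> per-condition LOWESS normalization -> spatial smoothing ->
z-scores -> wild-type null and BH thresholds -> hit calling -> wild-type
interaction model -> source-signature NMF -> condition clustering.  Every
artifact is a TSV reproducible from the config plus a single top-level
seed, which fans out to per-stage seeds through a fixed derivation; a JSON
manifest records versions, seeds and parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import growth, io, normalize, profiles, scoring, signatures, wtmodel
from .datatypes import Condition, RateMatrix
from .synthetic import SyntheticConfig, simulate_experiment, truth_table

log = logging.getLogger("cnscreen")
if not log.handlers:  # line-oriented stage/level/message logging
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(name)s\t%(levelname)s\t%(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run.

    Exactly one of ``synthetic`` (a generator configuration) or
    ``colony_table`` (a TSV path) supplies the input.
    """

    synthetic: SyntheticConfig | None = None
    colony_table: str | None = None
    seed: int = 0
    lowess_frac: float = normalize.DEFAULT_LOWESS_FRAC
    gaussian_sigma: float = normalize.DEFAULT_GAUSSIAN_SIGMA
    fdr: float = scoring.DEFAULT_FDR
    nmf_iterations: int = signatures.DEFAULT_ITERATIONS
    nmf_cutoff: float = signatures.DEFAULT_CUTOFF
    alpha: float = wtmodel.DEFAULT_ALPHA
    top_n: int = profiles.DEFAULT_TOP_N
    min_overlap: int = profiles.DEFAULT_MIN_OVERLAP
    min_wildtype_null: int = scoring.MIN_WILDTYPE_NULL
    smooth_before_zscores: bool = True

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.colony_table is None):
            raise ValueError("config needs exactly one of synthetic / colony_table")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr outside (0, 1)")
        if not 0 < self.lowess_frac <= 1:
            raise ValueError("lowess_frac outside (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        syn = raw.pop("synthetic", None)
        if syn is not None:
            if "conditions" in syn and syn["conditions"] is not None:
                syn["conditions"] = [tuple(x) for x in syn["conditions"]]
            if "interaction_mult" in syn:
                syn["interaction_mult"] = {tuple(k.split(":")): v
                                           for k, v in syn["interaction_mult"].items()}
            syn = SyntheticConfig(**syn)
        return cls(synthetic=syn, **raw)


def derive_seeds(seed: int) -> dict[str, int]:
    """Fan one top-level seed out to per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    names = ("synthetic", "nmf", "controls")
    children = ss.spawn(len(names))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(names, children)}


@dataclass
class PipelineResult:
    out_dir: Path
    rate_matrix: RateMatrix
    reference: normalize.ReferenceModel
    zscores: scoring.ZScoreMatrix
    null: pd.DataFrame
    thresholds: object
    hits: object
    wt_fit: wtmodel.WtModelFit | None
    model_comparison: pd.DataFrame | None
    decomposition: signatures.SignatureDecomposition | None
    members: dict[str, list[str]] = field(default_factory=dict)
    truth: pd.DataFrame | None = None


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return inner
    return wrap


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute every stage and write the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)

    # -- input ------------------------------------------------------------
    truth = None
    if config.synthetic is not None:
        experiment = _stage("simulate")(simulate_experiment)(
            config.synthetic, seeds["synthetic"])
        plate_sets = experiment.plate_sets
        truth = truth_table(experiment)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    else:
        plate_sets = _stage("read")(io.read_colony_table)(config.colony_table)

    layouts = {ps.layout.plate_index: ps.layout for ps in plate_sets}

    # -- rates ------------------------------------------------------------
    grids = _stage("rates")(growth.rate_plates)(plate_sets)
    rate_matrix = _stage("rates")(growth.build_rate_matrix)(plate_sets)
    io.write_rate_matrix(rate_matrix, out / "rates.tsv")

    # -- reference --------------------------------------------------------
    ga_labels = sorted(lbl for lbl in grids
                       if Condition.parse(lbl).is_reference and Condition.parse(lbl).replicate_tag)
    if len(ga_labels) != 6:
        raise PipelineError(f"stage 'reference' failed: found {len(ga_labels)} "
                            "glucose:ammonium replicate instances, need 6")
    ga_replicates = {p: [grids[lbl][p] for lbl in ga_labels] for p in layouts}
    reference = _stage("reference")(normalize.build_reference)(
        ga_replicates, config.lowess_frac)

    # -- normalize + smooth ------------------------------------------------
    scored_labels = [lbl for lbl in grids if not Condition.parse(lbl).is_glycerol]
    log.info("stage normalize+smooth: %d condition instances", len(scored_labels))
    norm_grids: dict[str, dict[int, normalize.RatePlate]] = {}
    for lbl in scored_labels:
        per_plate = {}
        for p, rp in grids[lbl].items():
            try:
                np_plate = normalize.normalize_condition(rp, reference)
                if config.smooth_before_zscores:
                    np_plate = normalize.spatial_smooth(np_plate, config.gaussian_sigma)
            except Exception as e:
                raise PipelineError(
                    f"stage 'normalize' failed on {lbl} plate {p}: {e}") from e
            per_plate[p] = np_plate
        norm_grids[lbl] = per_plate

    # -- scores, null, thresholds, hits -----------------------------------
    zscores = _stage("score")(scoring.compute_zscores)(norm_grids, reference, layouts)
    io.write_zscore_matrix(zscores, out / "zscores.tsv")
    null = _stage("score")(scoring.fit_null)(zscores, config.min_wildtype_null)
    null.to_csv(out / "null.tsv", sep="\t", index_label="condition")
    thresholds = _stage("thresholds")(scoring.bh_thresholds)(
        zscores, null, scoring.FDR_LEVELS)
    io.write_threshold_table(thresholds, out / "thresholds.tsv")
    hits = _stage("hits")(scoring.call_hits)(zscores, thresholds, config.fdr)
    io.write_hit_table(hits, out / "hits.tsv")
    summary = scoring.hit_count_summary(hits)
    summary.to_csv(out / "hit_counts.tsv", sep="\t")

    # -- wild-type model ---------------------------------------------------
    wt_rates = wildtype_rates_from_grids(grids, layouts)
    wt_fit = model_cmp = None
    try:
        wt_fit = wtmodel.fit_wt_model(wt_rates, config.alpha)
        wt_fit.term_table().to_csv(out / "wt_model.tsv", sep="\t", index=False)
        model_cmp = wtmodel.compare_model_families(wt_rates)
        model_cmp.to_csv(out / "wt_model_comparison.tsv", sep="\t")
    except wtmodel.MissingCellError as e:
        log.warning("wtmodel\tskipped: %s", e)

    # -- signatures --------------------------------------------------------
    decomposition = None
    members: dict[str, list[str]] = {}
    try:
        data = signatures.binarize_effects(zscores, thresholds, fdr_level=0.20)
        coef = signatures.build_coefficients(list(data.columns))
        decomposition = _stage("signatures")(signatures.decompose)(
            data, coef, config.nmf_iterations, seeds["nmf"], config.nmf_cutoff)
        members = signatures.signature_members(decomposition)
        decomposition.signatures.to_csv(out / "signatures.tsv", sep="\t",
                                        index_label="gene")
        pd.DataFrame([(src, g) for src, genes in members.items() for g in genes],
                     columns=["source", "gene"]).to_csv(
            out / "signature_members.tsv", sep="\t", index=False)
        pd.DataFrame({"iteration": range(len(decomposition.reconstruction_error)),
                      "frobenius_error": decomposition.reconstruction_error}).to_csv(
            out / "nmf_error.tsv", sep="\t", index=False)
    except signatures.EmptyDataError as e:
        log.warning("signatures\tskipped: %s", e)

    # -- profiles ----------------------------------------------------------
    top_n = min(config.top_n, zscores.table.shape[0])
    clustering = _stage("profiles")(profiles.cluster_conditions)(zscores, top_n)
    pd.DataFrame({"condition": clustering.conditions}).to_csv(
        out / "clustered_conditions.tsv", sep="\t", index=False)

    _write_report(out, config, hits, members, wt_fit)
    _write_manifest(out, config, seeds)
    return PipelineResult(out, rate_matrix, reference, zscores, null, thresholds,
                          hits, wt_fit, model_cmp, decomposition, members, truth)


def wildtype_rates_from_grids(grids, layouts) -> dict[str, np.ndarray]:
    """Replicate-level wild-type rates per condition instance label."""
    out: dict[str, np.ndarray] = {}
    for lbl, per_plate in grids.items():
        vals: list[float] = []
        for p, rp in per_plate.items():
            v = rp.values[layouts[p].wildtype]
            vals.extend(v[np.isfinite(v)])
        out[lbl] = np.asarray(vals)
    return out


def wildtype_rates_from_plates(plate_sets) -> dict[str, np.ndarray]:
    """Replicate-level wild-type rates per condition instance from plate sets."""
    out: dict[str, list[float]] = {}
    for ps in plate_sets:
        rp = growth.rate_plate(ps)
        vals = rp.values[ps.layout.wildtype]
        out.setdefault(ps.condition.label, []).extend(vals[np.isfinite(vals)])
    return {lbl: np.asarray(v) for lbl, v in out.items()}


def _write_report(out: Path, config: PipelineConfig, hits, members, wt_fit) -> None:
    lines = ["cnscreen pipeline report", "========================", ""]
    lines.append("Per-condition hit counts (fast/slow, replicate-averaged):")
    for pair, row in scoring.hit_count_summary(hits).iterrows():
        lines.append(f"  {pair}: {row['n_fast']:g}/{row['n_slow']:g}")
    gal = scoring.sensitive_genes(hits, "galactose", min_conditions=4)
    lines.append("")
    lines.append(f"Galactose-sensitive genes (slow in >=4 galactose conditions): {len(gal)}")
    if members:
        overlap = signatures.membership_overlap(members, "galactose", "ribose")
        lines.append(f"Galactose/ribose signature overlap: {len(overlap)} genes")
        lines.append("Signature sizes: "
                     + ", ".join(f"{s}={len(g)}" for s, g in sorted(members.items())))
    if wt_fit is not None:
        ns = wt_fit.nonsignificant_interactions()
        lines.append(f"Interaction terms not significant at alpha={config.alpha:g}: "
                     f"{len(ns)} ({', '.join(':'.join(t) for t in ns) or 'none'})")
    (out / "report.txt").write_text("\n".join(lines) + "\n")


def _write_manifest(out: Path, config: PipelineConfig, seeds: dict[str, int]) -> None:
    import cnscreen
    import scipy
    import statsmodels

    cfg = asdict(config)
    if cfg.get("synthetic") and cfg["synthetic"].get("interaction_mult"):
        cfg["synthetic"]["interaction_mult"] = {
            ":".join(k): v for k, v in cfg["synthetic"]["interaction_mult"].items()}
        if cfg["synthetic"].get("ge_effect"):
            cfg["synthetic"]["ge_effect"] = {
                "|".join(k): v for k, v in cfg["synthetic"]["ge_effect"].items()}
    manifest = {
        "versions": {"cnscreen": cnscreen.__version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "scipy": scipy.__version__,
                     "statsmodels": statsmodels.__version__},
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": cfg,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                  default=str) + "\n")
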