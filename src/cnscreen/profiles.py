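"""Profile-similarity analyses over the z-score matrix.

Guilt-by-association: genes whose sensitivity profiles across the condition
grid correlate strongly tend to share function, so ranked gene pairs can be
scored against a co-annotation standard (precision-recall).  The same
z-score matrix supports hierarchical clustering of conditions, set-overlap
tests against earlier screens, sign tests for coherent directional shifts
of annotated gene sets, comparison to an external genetic-interaction
profile compendium, and scoring of the liquid-culture confirmation assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .datatypes import Condition, ZScoreMatrix

DEFAULT_MIN_OVERLAP = 10
DEFAULT_TOP_N = 500
DEFAULT_NORMALIZATION_PASSES = 10
DEFAULT_TOP_QUERY_FRAC = 0.10
SATURATION_FRAC = 0.95


class EmptyStandardError(ValueError):
    """The co-annotation standard yields no evaluable gene pairs."""


class SharedUniverseError(ValueError):
    """Too few shared genes between the two profile compendia."""


class UndefinedScoreError(ValueError):
    """Wild-type liquid growth rate of zero makes the ratio undefined."""


def profile_similarity(zmatrix: ZScoreMatrix | pd.DataFrame,
                       min_overlap: int = DEFAULT_MIN_OVERLAP) -> pd.DataFrame:
    """Gene x gene Pearson correlation over jointly finite conditions.

    Pairs sharing fewer than ``min_overlap`` conditions are left undefined
    (NaN) — with only ~21 scored conditions, shorter overlaps give unstable
    correlations.
    """
    table = zmatrix.table if isinstance(zmatrix, ZScoreMatrix) else zmatrix
    if table.shape[1] < 2:
        raise ValueError("need at least two conditions for profile similarity")
    sim = table.T.corr(min_periods=min_overlap)
    np.fill_diagonal(sim.values, 1.0)
    return sim


@dataclass
class PRCurve:
    """Ranked gene pairs with cumulative precision; ``background`` is the
    co-annotation rate over all evaluable pairs (= precision at full recall)."""

    table: pd.DataFrame
    background: float

    def precision_at(self, rank: int) -> float:
        if rank < 1 or rank > len(self.table):
            raise IndexError(f"rank {rank} outside 1..{len(self.table)}")
        return float(self.table["precision"].iloc[rank - 1])


def co_annotation_matrix(genes: list[str],
                         term_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Boolean gene x gene co-annotation indicator (shared term)."""
    terms = list(term_sets)
    incidence = np.zeros((len(genes), len(terms)), dtype=bool)
    index = {g: i for i, g in enumerate(genes)}
    for j, t in enumerate(terms):
        for g in term_sets[t]:
            if g in index:
                incidence[index[g], j] = True
    co = incidence @ incidence.T
    return pd.DataFrame(co > 0, index=genes, columns=genes)


def precision_recall(similarity: pd.DataFrame, term_sets: dict[str, set[str]],
                     gene_subset: list[str] | None = None,
                     min_pairs: int = 1) -> PRCurve:
    """Precision at each recall rank of gene pairs ordered by similarity.

    Evaluable pairs are unordered pairs of distinct genes that are present
    in the similarity matrix, annotated to at least one term, and have a
    defined similarity; ties are broken by the lexicographic pair
    identifier for determinism.
    """
    annotated = set().union(*term_sets.values()) if term_sets else set()
    genes = [g for g in similarity.index if g in annotated]
    if gene_subset is not None:
        keep = set(gene_subset)
        genes = [g for g in genes if g in keep]
    if len(genes) < 2:
        raise EmptyStandardError("fewer than two annotated genes with profiles")
    co = co_annotation_matrix(genes, term_sets).to_numpy()
    sim = similarity.loc[genes, genes].to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    s = sim[iu]
    defined = np.isfinite(s)
    if defined.sum() < min_pairs:
        raise EmptyStandardError("no evaluable gene pairs")
    pairs = pd.DataFrame({
        "gene_a": np.asarray(genes, dtype=object)[iu[0]][defined],
        "gene_b": np.asarray(genes, dtype=object)[iu[1]][defined],
        "similarity": s[defined],
        "co_annotated": co[iu][defined],
    })
    pairs = pairs.sort_values(["similarity", "gene_a", "gene_b"],
                              ascending=[False, True, True], kind="mergesort")
    pairs = pairs.reset_index(drop=True)
    hits = pairs["co_annotated"].to_numpy().cumsum()
    ranks = np.arange(1, len(pairs) + 1)
    pairs["rank"] = ranks
    pairs["precision"] = hits / ranks
    background = float(pairs["co_annotated"].mean())
    return PRCurve(pairs, background)


@dataclass
class ConditionClustering:
    condition_linkage: np.ndarray
    gene_linkage: np.ndarray
    conditions: list[str]
    genes: list[str]


def cluster_conditions(zmatrix: ZScoreMatrix | pd.DataFrame,
                       top_n: int = DEFAULT_TOP_N,
                       method: str = "average") -> ConditionClustering:
    """Two-way hierarchical clustering on correlation distance.

    Genes are ranked by profile variance and the ``top_n`` most variable
    retained; conditions (and those genes) are clustered agglomeratively on
    1 - Pearson correlation.
    """
    table = zmatrix.table if isinstance(zmatrix, ZScoreMatrix) else zmatrix
    if top_n > table.shape[0]:
        raise ValueError(f"top_n={top_n} exceeds gene count {table.shape[0]}")
    variance = table.var(axis=1, skipna=True)
    genes = list(variance.sort_values(ascending=False, kind="mergesort").index[:top_n])
    sub = table.loc[genes]

    def _corr_linkage(frame: pd.DataFrame) -> np.ndarray:
        corr = frame.T.corr(min_periods=2).to_numpy()
        dist = 1.0 - corr
        dist[~np.isfinite(dist)] = 2.0
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2
        return linkage(squareform(dist, checks=False), method=method)

    cond_link = _corr_linkage(sub.T)   # rows = conditions
    gene_link = _corr_linkage(sub)     # rows = genes
    return ConditionClustering(cond_link, gene_link, list(sub.columns), genes)


def hypergeometric_overlap(set_a: set[str], set_b: set[str],
                           universe_size: int) -> tuple[int, float]:
    """Observed overlap and upper-tail hypergeometric p-value."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("a set exceeds the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, p


def enrichment(gene_list: set[str], term_sets: dict[str, set[str]],
               background: set[str],
               correction: str = "bonferroni") -> pd.DataFrame:
    """Per-term hypergeometric enrichment with Bonferroni correction.

    Each term's p-value is multiplied by the number of terms tested and
    capped at 1.
    """
    if not background:
        raise ValueError("empty background")
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    query = set(gene_list) & set(background)
    n_terms = len(term_sets)
    rows = []
    for term, members in term_sets.items():
        term_bg = set(members) & set(background)
        k, p = hypergeometric_overlap(query, term_bg, len(background))
        rows.append((term, k, len(term_bg), p, min(1.0, p * n_terms)))
    return pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p",
                                       "p_corrected"]).set_index("term")


@dataclass
class SignTestResult:
    medians: pd.Series
    n_match: int
    n_total: int
    p: float


def gene_set_sign_test(zmatrix: ZScoreMatrix | pd.DataFrame, gene_set: set[str],
                       group_a: list[str], group_b: list[str]) -> SignTestResult:
    """Binomial sign test for a coherent directional split.

    Per-condition median z over ``gene_set``; a condition matches the
    hypothesized pattern when its median is negative in ``group_a`` and
    positive in ``group_b``.  p is the upper binomial tail with success
    probability 1/2 over all conditions with a defined median.
    """
    table = zmatrix.table if isinstance(zmatrix, ZScoreMatrix) else zmatrix
    if not gene_set:
        raise ValueError("empty gene set")
    if set(group_a) & set(group_b):
        raise ValueError("condition groups must be disjoint")
    genes = [g for g in gene_set if g in table.index]
    labels = list(group_a) + list(group_b)
    medians = table.loc[genes, labels].median(axis=0, skipna=True)
    if medians.isna().all():
        raise ValueError("all-missing medians")
    defined = medians.dropna()
    n_match = int(sum(defined[c] < 0 for c in group_a if c in defined.index)
                  + sum(defined[c] > 0 for c in group_b if c in defined.index))
    n_total = len(defined)
    p = float(stats.binom.sf(n_match - 1, n_total, 0.5))
    return SignTestResult(medians, n_match, n_total, p)


def bidirectional_unit_normalize(matrix: pd.DataFrame,
                                 n_passes: int = DEFAULT_NORMALIZATION_PASSES) -> pd.DataFrame:
    """Alternately rescale columns then rows toward unit Euclidean length.

    Missing values are set to 0 first.  Exact simultaneous unit row and
    column norms only exist for square matrices (the squared norms share
    one total), so the alternation ends on the row side: the profile
    vectors that enter the inner product have length exactly 1, while the
    column (per-gene) rescaling balances gene contributions.
    """
    m = matrix.fillna(0.0).to_numpy(dtype=float).copy()
    for _ in range(n_passes):
        cn = np.linalg.norm(m, axis=0, keepdims=True)
        m = np.divide(m, cn, out=np.zeros_like(m), where=cn > 0)
        rn = np.linalg.norm(m, axis=1, keepdims=True)
        m = np.divide(m, rn, out=np.zeros_like(m), where=rn > 0)
    return pd.DataFrame(m, index=matrix.index, columns=matrix.columns)


@dataclass
class CrossProfileResult:
    similarity: pd.DataFrame            # condition x query inner products
    top_queries: dict[str, list[str]] = field(default_factory=dict)


def cross_profile_similarity(env_profiles: pd.DataFrame,
                             query_profiles: pd.DataFrame,
                             min_shared_genes: int = 100,
                             n_passes: int = DEFAULT_NORMALIZATION_PASSES,
                             top_frac: float = DEFAULT_TOP_QUERY_FRAC) -> CrossProfileResult:
    """Compare environmental profiles to an external perturbation compendium.

    Both matrices (conditions x genes and queries x genes) are restricted to
    the shared gene universe, independently normalized so row and column
    vectors have Euclidean length approximately 1 (missing set to 0), and
    compared by inner product.  The top ``top_frac`` of queries per
    condition are returned for downstream enrichment.
    """
    shared = [g for g in env_profiles.columns if g in set(query_profiles.columns)]
    if len(shared) < min_shared_genes:
        raise SharedUniverseError(
            f"{len(shared)} shared genes (need >= {min_shared_genes})")
    env = bidirectional_unit_normalize(env_profiles[shared], n_passes)
    qry = bidirectional_unit_normalize(query_profiles[shared], n_passes)
    sim = pd.DataFrame(env.to_numpy() @ qry.to_numpy().T,
                       index=env.index, columns=qry.index)
    n_top = max(1, math.ceil(top_frac * sim.shape[1]))
    top = {cond: list(sim.loc[cond].sort_values(ascending=False, kind="mergesort")
                      .index[:n_top])
           for cond in sim.index}
    return CrossProfileResult(sim, top)


@dataclass
class LiquidAssay:
    """Optical-density time courses of the liquid confirmation assay.

    ``wells``: one row per reading with columns strain, condition, well,
    time_h, od.
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"strain", "condition", "well", "time_h", "od"}
        missing = need - set(self.wells.columns)
        if missing:
            raise ValueError(f"liquid assay missing columns: {sorted(missing)}")
        if (self.wells["od"] < 0).any():
            raise ValueError("optical density must be >= 0")


def liquid_growth_rate(times_h, ods) -> float:
    """Maximum OD divided by the time to saturation.

    Saturation is the first timestamp at which OD reaches 95 percent of its
    maximum (the saturation instant itself is not sharply defined on noisy
    series).
    """
    t = np.asarray(times_h, dtype=float)
    od = np.asarray(ods, dtype=float)
    order = np.argsort(t)
    t, od = t[order], od[order]
    peak = od.max()
    if peak <= 0:
        return 0.0
    t_sat = t[np.argmax(od >= SATURATION_FRAC * peak)]
    if t_sat <= 0:
        return float("nan")
    return float(peak / t_sat)


def liquid_adjusted_score(mutant: LiquidAssay, wildtype: LiquidAssay,
                          reference_condition: str = "glucose:ammonium") -> pd.DataFrame:
    """Condition-specific liquid scores, doubly normalized.

    Per (strain, condition): mean mutant rate over replicate wells divided
    by the mean wild-type rate in that condition, then divided by the same
    ratio in the reference condition.  A score of 1 means the mutant behaves
    like wild-type once its reference-condition behaviour is accounted for.
    """
    def rates(assay: LiquidAssay) -> pd.Series:
        out = {}
        for key, g in assay.wells.groupby(["strain", "condition", "well"]):
            out[key] = liquid_growth_rate(g["time_h"].to_numpy(), g["od"].to_numpy())
        s = pd.Series(out)
        return s.groupby(level=[0, 1]).mean()

    mut = rates(mutant)
    wt = rates(wildtype).groupby(level=1).mean()
    if (wt <= 0).any():
        bad = list(wt.index[wt <= 0])
        raise UndefinedScoreError(f"zero wild-type rate in condition(s) {bad}")
    raw = mut / mut.index.get_level_values(1).map(wt)
    raw.index = mut.index
    scores = {}
    for strain in raw.index.get_level_values(0).unique():
        sub = raw.loc[strain]
        if reference_condition not in sub.index:
            raise ValueError(f"strain {strain} lacks reference-condition measurements")
        ref = sub[reference_condition]
        if ref <= 0 or not np.isfinite(ref):
            raise UndefinedScoreError(f"strain {strain}: reference score undefined")
        scores[strain] = sub / ref
    return pd.DataFrame(scores).T.sort_index()
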