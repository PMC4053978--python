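"""Nutrient-source signature decomposition by fixed-coefficient NMF.

A gene that is sensitive whenever, say, galactose is the carbon source —
regardless of the nitrogen partner — should be attributed to galactose
itself.  The binarized gene x condition effect matrix (Data) is decomposed
as Data ~= Signatures x Coefficients, where Coefficients is the known
source composition of each condition (a 1 in its carbon row and a 1 in its
nitrogen row) and is held fixed; only the non-negative gene x source
Signatures matrix is fitted, with the standard multiplicative update

    W <- W * (V H^T) / (W H H^T + eps)

run for a fixed number of iterations from a seeded uniform random start.
Fixing the coefficients gives every source column equal weight and guards
against over-fitting the sparse, unbalanced data matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import Condition, ThresholdTable, ZScoreMatrix

DEFAULT_ITERATIONS = 20
DEFAULT_CUTOFF = 0.4
EPSILON = 1e-9
#: The ten sources of the non-glycerol grid: three carbons plus seven nitrogens.
SOURCES = ("glucose", "galactose", "ribose",
           "ammonium", "proline", "glutamate", "glutamine", "arginine",
           "urea", "allantoin")


class EmptyDataError(ValueError):
    """No gene has any significant effect after binarization."""


class CoefficientIndependenceError(ValueError):
    """Duplicate condition columns would make signatures unidentifiable."""


@dataclass
class SignatureDecomposition:
    data: pd.DataFrame              # G x C binary (0/1 floats)
    coefficients: pd.DataFrame      # S x C binary, fixed
    signatures: pd.DataFrame        # G x S non-negative
    reconstruction_error: np.ndarray  # Frobenius norm per iteration (incl. start)
    iterations: int
    seed: int
    membership_cutoff: float = DEFAULT_CUTOFF


def binarize_effects(zmatrix: ZScoreMatrix, thresholds: ThresholdTable,
                     fdr_level: float = 0.20,
                     direction: str = "slow") -> pd.DataFrame:
    """Binary gene x condition matrix of significant effects.

    A cell is 1 iff the gene's z-score passes the condition's threshold at
    the given FDR in the chosen direction (``slow`` by default — signatures
    are read as per-source sensitivity lists; ``both`` accepts either
    direction).  Glycerol columns are removed, all glucose:ammonium
    replicate columns except ``glucose:ammonium01`` are removed, and
    all-zero gene rows are dropped.
    """
    if direction not in ("slow", "fast", "both"):
        raise ValueError("direction must be 'slow', 'fast' or 'both'")
    keep: list[str] = []
    for label in zmatrix.table.columns:
        cond = Condition.parse(label)
        if cond.is_glycerol:
            continue
        if cond.is_reference and label != "glucose:ammonium01":
            continue
        keep.append(label)
    data = pd.DataFrame(0.0, index=zmatrix.table.index, columns=keep)
    for label in keep:
        z = zmatrix.table[label]
        hit = pd.Series(False, index=z.index)
        if direction in ("slow", "both"):
            hit |= z <= thresholds.lookup(label, "slow", fdr_level)
        if direction in ("fast", "both"):
            hit |= z >= thresholds.lookup(label, "fast", fdr_level)
        data[label] = hit.astype(float)
    data = data.loc[data.sum(axis=1) > 0]
    if data.empty:
        raise EmptyDataError("no gene has a significant effect in any condition")
    return data


def build_coefficients(conditions: list[str]) -> pd.DataFrame:
    """Fixed S x C source-composition matrix: each condition column carries a
    1 in its carbon row and a 1 in its nitrogen row."""
    coef = pd.DataFrame(0.0, index=list(SOURCES), columns=list(conditions))
    for label in conditions:
        cond = Condition.parse(label)
        if cond.is_glycerol:
            raise ValueError(f"glycerol condition {label} not part of the decomposition")
        coef.loc[cond.carbon, label] = 1.0
        coef.loc[cond.nitrogen, label] = 1.0
    dup = coef.T.duplicated()
    if dup.any():
        raise CoefficientIndependenceError(
            f"duplicate condition columns: {list(coef.columns[dup])}")
    return coef


def coefficient_rank(coefficients: pd.DataFrame) -> int:
    """Numeric rank of the source-composition matrix (9 for the full
    bipartite carbon x nitrogen design: 3 + 7 - 1)."""
    return int(np.linalg.matrix_rank(coefficients.to_numpy()))


def decompose(data: pd.DataFrame, coefficients: pd.DataFrame,
              iterations: int = DEFAULT_ITERATIONS, seed: int = 0,
              cutoff: float = DEFAULT_CUTOFF) -> SignatureDecomposition:
    """Fit the signatures by multiplicative updates with coefficients fixed."""
    if list(data.columns) != list(coefficients.columns):
        raise ValueError("data and coefficient columns disagree")
    V = data.to_numpy(dtype=float)
    H = coefficients.to_numpy(dtype=float)
    h_before = H.tobytes()
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.0, 1.0, size=(V.shape[0], H.shape[0]))

    HHt = H @ H.T
    VHt = V @ H.T
    errors = [float(np.linalg.norm(V - W @ H))]
    for _ in range(iterations):
        W *= VHt / (W @ HHt + EPSILON)
        assert (W >= 0).all()
        errors.append(float(np.linalg.norm(V - W @ H)))
    assert H.tobytes() == h_before  # coefficients are never updated
    signatures = pd.DataFrame(W, index=data.index, columns=coefficients.index)
    return SignatureDecomposition(data, coefficients, signatures,
                                  np.array(errors), iterations, seed, cutoff)


def signature_members(decomposition: SignatureDecomposition,
                      cutoff: float | None = None) -> dict[str, list[str]]:
    """Per-source gene lists: genes whose raw signature value exceeds the
    membership cutoff (0.4 by default, no rescaling)."""
    cut = decomposition.membership_cutoff if cutoff is None else cutoff
    out: dict[str, list[str]] = {}
    sig = decomposition.signatures
    for source in sig.columns:
        out[source] = sorted(sig.index[sig[source] > cut])
    return out


def membership_overlap(members: dict[str, list[str]], source_a: str,
                       source_b: str) -> set[str]:
    """Genes shared by two source signatures (e.g. galactose and ribose)."""
    return set(members.get(source_a, [])) & set(members.get(source_b, []))
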