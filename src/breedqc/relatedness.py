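"""Allele-sharing distance, duplicate detection, genomic relationships, PCA.

The identity-by-state (IBS) distance between two diploid samples is the
allele-count Hamming distance normalised by the pairwise-complete locus count:

    d(i, j) = sum_l |g_il - g_jl| / (2 * L_ij)

over loci l where both samples have calls, so d = 1 - (proportion of alleles
identical by state).  Duplicate candidates are pairs with d at or below a
threshold (0.05 by default, the convention for clonal crops with ~1% assay
error), grouped into connected components so that chained field/crossing-block
copies land in one group.

The additive genomic relationship matrix follows VanRaden's first method:
A = WW' / (2 * sum_l p_l (1 - p_l)) with W the dosage matrix centred at 2p
and missing cells imputed to the marker mean (0 after centring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from breedqc.genotype_io import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric allele-sharing dissimilarities in [0, 1] with zero diagonal.

    ``n_loci_used[i, j]`` counts loci non-missing in both members of the pair;
    a pair with no shared loci has NaN distance (excluded from duplicate
    detection with a warning).
    """

    ids: list[str]
    values: np.ndarray
    n_loci_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance grid shape inconsistent with ids")
        finite = np.isfinite(V)
        if not np.allclose(V[finite], V.T[finite], atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(V), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        if (V[finite] < -1e-12).any() or (V[finite] > 1 + 1e-12).any():
            raise ValueError("distances must lie in [0, 1]")
        self.values = V

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class DuplicateReport:
    """Putative duplicate groups at distance threshold ``threshold``."""

    threshold: float
    components: list[list[str]]  # each sorted, size >= 2
    pair_distances: dict[tuple[str, str], float]
    representatives: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_distances)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "components": self.components,
            "pairs": [
                {"a": a, "b": b, "distance": d}
                for (a, b), d in sorted(self.pair_distances.items())
            ],
            "representatives": self.representatives,
        }


@dataclass
class RelationshipMatrix:
    """Additive genomic relationship matrix (VanRaden method 1)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship grid shape inconsistent with ids")
        if not np.allclose(V, V.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")
        self.values = V


def ibs_distance(G: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise 1-IBS distance with pairwise deletion of missing calls."""
    d = G.dosages.astype(np.float64)
    obs = d != MISSING
    dz = np.where(obs, d, 0.0)
    n = G.n_samples
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    obs_f = obs.astype(np.float64)
    for i in range(n):
        both = obs_f[i] * obs_f  # n x L indicator of pairwise-complete loci
        L = both.sum(axis=1)
        diff = np.abs(dz[i] - dz) * both
        with np.errstate(divide="ignore", invalid="ignore"):
            row = np.where(L > 0, diff.sum(axis=1) / (2.0 * L), np.nan)
        values[i] = row
        counts[i] = L.astype(np.int64)
    np.fill_diagonal(values, 0.0)
    if np.isnan(values).any():
        warnings.warn(
            "some sample pairs share no genotyped loci; their distance is "
            "undefined (NaN) and excluded from duplicate detection",
            stacklevel=2,
        )
    return DistanceMatrix(ids=G.sample_ids, values=values, n_loci_used=counts)


def find_duplicates(D: DistanceMatrix, threshold: float = 0.05) -> DuplicateReport:
    """Group samples whose pairwise distance is <= ``threshold``.

    Builds a graph with an edge per flagged pair and reports connected
    components of size >= 2; the lexicographically smallest id in each group
    is nominated as the representative for a deduplicated sample set.
    """
    g = nx.Graph()
    g.add_nodes_from(D.ids)
    pair_distances: dict[tuple[str, str], float] = {}
    V = D.values
    for i in range(D.n):
        for j in range(i + 1, D.n):
            dij = V[i, j]
            if np.isfinite(dij) and dij <= threshold:
                a, b = sorted((D.ids[i], D.ids[j]))
                g.add_edge(a, b)
                pair_distances[(a, b)] = float(dij)
    components = sorted(
        (sorted(c) for c in nx.connected_components(g) if len(c) >= 2),
        key=lambda c: c[0],
    )
    return DuplicateReport(
        threshold=threshold,
        components=components,
        pair_distances=pair_distances,
        representatives=[c[0] for c in components],
    )


def grm(G: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden method-1 additive relationship matrix.

    Monomorphic markers are excluded; missing dosages are imputed to the
    marker mean (zero after centring), which keeps A positive semi-definite.
    """
    d = G.dosages.astype(np.float64)
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        keep = n_obs > 0
        d, obs, n_obs = d[:, keep], obs[:, keep], n_obs[keep]
    p = np.where(obs, d, 0.0).sum(axis=0) / (2.0 * n_obs)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic; relationship undefined")
    d, obs, p = d[:, poly], obs[:, poly], p[poly]
    W = np.where(obs, d, 2.0 * p) - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    A = (W @ W.T) / denom
    return RelationshipMatrix(ids=G.sample_ids, values=A)


def pca(A: RelationshipMatrix | np.ndarray, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of a symmetric (relationship) matrix.

    Returns ``(scores, eigenvalues)``: scores are eigenvectors scaled by the
    square root of their (non-negative-clipped) eigenvalues, columns sorted
    by decreasing eigenvalue.  Sign convention: in each component the
    largest-magnitude loading is positive.
    """
    V = A.values if isinstance(A, RelationshipMatrix) else np.asarray(A, dtype=float)
    if not np.isfinite(V).all():
        raise ValueError("relationship matrix contains non-finite entries")
    evals, evecs = np.linalg.eigh(V)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(n_components, len(evals))
    evals, evecs = evals[:k], evecs[:, :k]
    for c in range(k):
        j = np.argmax(np.abs(evecs[:, c]))
        if evecs[j, c] < 0:
            evecs[:, c] = -evecs[:, c]
    scores = evecs * np.sqrt(np.clip(evals, 0.0, None))
    return scores, evals


def pca_dosages(G: GenotypeMatrix, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """PCA on mean-centred dosages directly (alternative to the GRM route).

    Missing cells are imputed to the marker mean before centring.  Returns
    ``(scores, eigenvalues)`` with the same conventions as :func:`pca`.
    """
    d = G.dosages.astype(np.float64)
    obs = d != MISSING
    mean = np.where(obs, d, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    X = np.where(obs, d, mean) - mean
    return pca(X @ X.T / max(X.shape[1], 1), n_components)
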