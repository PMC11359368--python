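"""Population structure: Ward clustering, optimal K, admixture EM, concordance.

Hierarchical clustering uses Ward's minimum-variance criterion in the variant
that squares the input dissimilarities inside the algorithm (R's ``Ward.D2``,
SciPy's ``ward``).  The number of clusters is chosen by three standard
diagnostics — the elbow on the within-cluster sum of squares, the mean
silhouette, and the gap statistic with uniform reference sets drawn over the
principal-component-aligned bounding box — plus a majority consensus.

The admixture model is the STRUCTURE/ADMIXTURE likelihood for unlinked
biallelic loci: dosage g_il ~ Binomial(2, p_il) with p_il = sum_k q_ik f_kl,
where q_i are individual ancestry proportions and f_k ancestral allele
frequencies.  It is maximised by expectation-maximisation with closed-form
updates; K is selected by entry-holdout cross-validation on the held-out
binomial deviance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from breedqc.genotype_io import MISSING, GenotypeMatrix
from breedqc.relatedness import DistanceMatrix, DuplicateReport
from breedqc._util import derive_seed

_F_EPS = 1e-6


@dataclass
class ClusterResult:
    """A Ward merge tree plus flat cuts for K = 1..k_max."""

    ids: list[str]
    linkage: np.ndarray  # SciPy linkage matrix
    labels_for_k: dict[int, np.ndarray]  # K -> integer labels (1..K)

    def labels(self, k: int) -> np.ndarray:
        return self.labels_for_k[k]


@dataclass
class OptimalKResult:
    """Per-method optimal K and the majority consensus."""

    elbow: int
    silhouette: int
    gap: int
    consensus: int
    diagnostics: dict[int, dict[str, float]]  # k -> {W, silhouette, gap, s}


@dataclass
class AdmixtureFit:
    """Fitted admixture model: ancestry proportions Q, frequencies F."""

    K: int
    Q: np.ndarray  # n x K, rows sum to 1
    F: np.ndarray  # K x L in [eps, 1-eps]
    loglik_trace: np.ndarray
    converged: bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


@dataclass
class ConcordanceReport:
    """Agreement between two clusterings of a shared sample set."""

    n_common: int
    dissimilarity_pct: float
    adjusted_rand: float
    mismatched_ids: list[str] = field(default_factory=list)
    duplicate_set_overlap: dict[str, list[tuple[str, str]]] | None = None


# ---------------------------------------------------------------------------
# Hierarchical clustering & optimal K
# ---------------------------------------------------------------------------


def ward_cluster(D: DistanceMatrix, k_max: int = 10) -> ClusterResult:
    """Agglomerative Ward.D2 clustering of a dissimilarity matrix."""
    if D.n < 2:
        raise ValueError("need at least 2 samples to cluster")
    condensed = squareform(D.values, checks=False)
    Z = linkage(condensed, method="ward")
    labels_for_k = {
        k: fcluster(Z, t=k, criterion="maxclust")
        for k in range(1, min(k_max, D.n) + 1)
    }
    return ClusterResult(ids=list(D.ids), linkage=Z, labels_for_k=labels_for_k)


def embed_distances(D: DistanceMatrix, n_components: int | None = None) -> np.ndarray:
    """Classical MDS embedding of a distance matrix (Torgerson scaling).

    Double-centres the squared distances and keeps the components with
    positive eigenvalues, so Euclidean distances in the embedding approximate
    the input dissimilarities.
    """
    V = D.values
    n = D.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (V**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-9 * abs(evals[0]))
    X = evecs[:, pos] * np.sqrt(evals[pos])
    if n_components is not None:
        X = X[:, :n_components]
    return X


def _ward_labels(X: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def optimal_k(
    X: np.ndarray | DistanceMatrix,
    k_max: int = 10,
    B: int = 100,
    seed: int = 0,
) -> OptimalKResult:
    """Choose the number of clusters by elbow, silhouette, and gap statistic.

    ``X`` is an n x p embedding (a :class:`DistanceMatrix` is embedded by
    classical MDS first).  Clusters at each k come from Ward clustering.

    - elbow: argmax of the second difference of the within-cluster sum of
      squares W_k (the sharpest bend);
    - silhouette: argmax of the mean silhouette (k >= 2);
    - gap: smallest k with Gap(k) >= Gap(k+1) - s_{k+1}, where the B
      reference sets are uniform over the PCA-aligned bounding box of X;
    - consensus: majority over the three, ties broken toward the smallest K.
    """
    if isinstance(X, DistanceMatrix):
        X = embed_distances(X)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k_max = min(k_max, n - 1) if n > 2 else 1
    if n < 3 or np.allclose(X, X[0]):
        return OptimalKResult(1, 1, 1, 1, {1: {"W": 0.0, "silhouette": np.nan,
                                               "gap": np.nan, "s": np.nan}})
    ks = list(range(1, k_max + 1))
    labels = {k: (np.ones(n, dtype=int) if k == 1 else _ward_labels(X, k)) for k in ks}
    W = {k: _wss(X, labels[k]) for k in ks}
    sil = {}
    for k in ks:
        if k >= 2 and len(np.unique(labels[k])) >= 2:
            sil[k] = float(silhouette_score(X, labels[k]))
        else:
            sil[k] = np.nan

    # gap statistic with PCA-rotated uniform reference
    rng = np.random.default_rng(seed)
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)
    log_wstar = np.zeros((B, len(ks)))
    for b in range(B):
        Zb = rng.uniform(lo, hi, size=Xp.shape) @ Vt
        for idx, k in enumerate(ks):
            lab = np.ones(n, dtype=int) if k == 1 else _ward_labels(Zb, k)
            log_wstar[b, idx] = np.log(max(_wss(Zb, lab), 1e-300))
    gap = {k: float(log_wstar[:, i].mean() - np.log(max(W[k], 1e-300)))
           for i, k in enumerate(ks)}
    s = {k: float(log_wstar[:, i].std(ddof=0) * np.sqrt(1.0 + 1.0 / B))
         for i, k in enumerate(ks)}

    # elbow: sharpest decrease-slowdown of W_k
    if len(ks) >= 3:
        second_diff = {k: W[k - 1] - 2 * W[k] + W[k + 1] for k in ks[1:-1]}
        k_elbow = max(second_diff, key=lambda k: (second_diff[k], -k))
    else:
        k_elbow = ks[-1]
    valid_sil = {k: v for k, v in sil.items() if np.isfinite(v)}
    k_sil = min(valid_sil, key=lambda k: (-valid_sil[k], k)) if valid_sil else 1
    k_gap = ks[-1]
    for i, k in enumerate(ks[:-1]):
        if gap[k] >= gap[ks[i + 1]] - s[ks[i + 1]]:
            k_gap = k
            break

    votes = [k_elbow, k_sil, k_gap]
    counts = {k: votes.count(k) for k in set(votes)}
    best = max(counts.values())
    consensus = min(k for k, c in counts.items() if c == best)
    diagnostics = {
        k: {"W": W[k], "silhouette": sil[k], "gap": gap[k], "s": s[k]} for k in ks
    }
    return OptimalKResult(k_elbow, k_sil, k_gap, consensus, diagnostics)


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------


def _admixture_loglik(g: np.ndarray, obs: np.ndarray, P: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = g * np.log(P) + (2.0 - g) * np.log(1.0 - P)
    return float(ll[obs].sum())


def admixture_em(
    G: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> AdmixtureFit:
    """Fit the K-ancestral-population admixture model by EM.

    Maximises sum_{i,l} [g_il ln p_il + (2 - g_il) ln(1 - p_il)] with
    p_il = sum_k q_ik f_kl (the binomial-coefficient constant is omitted).
    Missing cells are skipped.  The log-likelihood is non-decreasing across
    iterations; iteration stops when the gain drops below ``tol``.
    """
    d = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G)
    if K < 1:
        raise ValueError("K must be >= 1")
    obs = d != MISSING
    g = np.where(obs, d, 0).astype(np.float64)
    n, L = g.shape
    L_i = obs.sum(axis=1).astype(np.float64)  # non-missing loci per sample
    if (L_i == 0).any():
        raise ValueError("sample with no genotyped loci")

    rng = np.random.default_rng(seed)
    # init: F perturbed around pooled frequencies, Q near-uniform
    with np.errstate(invalid="ignore"):
        pbar = np.where(obs, g, 0.0).sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1))
    F = np.clip(pbar + rng.normal(0.0, 0.1, size=(K, L)), _F_EPS, 1 - _F_EPS)
    Q = rng.dirichlet(np.full(K, 10.0), size=n)

    trace = []
    converged = False
    for _ in range(max_iter):
        P = np.clip(Q @ F, _F_EPS, 1 - _F_EPS)
        trace.append(_admixture_loglik(g, obs, P))
        X = np.where(obs, g / P, 0.0)  # counted-allele weight
        Y = np.where(obs, (2.0 - g) / (1.0 - P), 0.0)  # other-allele weight
        # E+M in one pass: responsibilities factor through these products
        AQ = X @ F.T  # n x K: sum_l f_kl g_il / p_il
        BQ = Y @ (1.0 - F).T
        Q_new = Q * (AQ + BQ) / (2.0 * L_i[:, None])
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        num_f = F * (Q.T @ X)  # K x L
        den_f = (1.0 - F) * (Q.T @ Y)
        with np.errstate(invalid="ignore"):
            F_new = num_f / (num_f + den_f)
        F_new = np.clip(np.nan_to_num(F_new, nan=0.5), _F_EPS, 1 - _F_EPS)
        Q, F = Q_new, F_new
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            converged = True
            break
    P = np.clip(Q @ F, _F_EPS, 1 - _F_EPS)
    trace.append(_admixture_loglik(g, obs, P))
    return AdmixtureFit(
        K=K, Q=Q, F=F, loglik_trace=np.asarray(trace), converged=converged
    )


def admixture_cv(
    G: GenotypeMatrix | np.ndarray,
    k_range: range | list[int] = range(1, 11),
    folds: int = 10,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> dict[int, float]:
    """Entry-holdout cross-validation error per K.

    Non-missing cells are partitioned into ``folds`` disjoint folds.  For
    each fold the held-out cells are masked during fitting, then scored by
    the binomial deviance of the observed dosage against 2 * p-hat; the CV
    error for K is the mean per-cell deviance over folds.  The selected K is
    the argmin.
    """
    d = (G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G)).copy()
    obs_idx = np.argwhere(d != MISSING)
    if len(obs_idx) < folds:
        raise ValueError("fewer non-missing cells than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(obs_idx))
    fold_of = np.empty(len(obs_idx), dtype=int)
    fold_of[perm] = np.arange(len(obs_idx)) % folds

    errors: dict[int, list[float]] = {k: [] for k in k_range}
    for f in range(folds):
        held = obs_idx[fold_of == f]
        if len(held) == 0:
            raise ValueError(f"fold {f} holds zero cells")
        masked = d.copy()
        masked[held[:, 0], held[:, 1]] = MISSING
        for k in k_range:
            fit = admixture_em(
                masked, K=k, seed=derive_seed(seed, 31 * f + k),
                tol=tol, max_iter=max_iter,
            )
            P = np.clip(fit.Q @ fit.F, _F_EPS, 1 - _F_EPS)
            gh = d[held[:, 0], held[:, 1]].astype(np.float64)
            ph = P[held[:, 0], held[:, 1]]
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = np.where(gh > 0, gh * np.log(gh / (2 * ph)), 0.0)
                t2 = np.where(gh < 2, (2 - gh) * np.log((2 - gh) / (2 * (1 - ph))), 0.0)
            errors[k].append(float(2.0 * (t1 + t2).mean()))
    return {k: float(np.mean(v)) for k, v in errors.items()}


def select_k(cv_error: dict[int, float]) -> int:
    """Argmin of the cross-validation error (smallest K on ties)."""
    best = min(cv_error.values())
    return min(k for k, v in cv_error.items() if v == best)


def assign_membership(Q: np.ndarray, threshold: float = 0.80) -> list[str | int]:
    """Assign each sample to its majority ancestry, or "admixed".

    A sample is assigned to cluster argmax_k Q_ik (1-based) when its maximum
    ancestry proportion is >= ``threshold`` (inclusive); otherwise it is
    labelled ``"admixed"``.  Ties in the argmax break toward the lowest index.
    """
    Q = np.asarray(Q, dtype=float)
    labels: list[str | int] = []
    for row in Q:
        k = int(np.argmax(row))  # np.argmax takes the first (lowest) index on ties
        labels.append(k + 1 if row[k] >= threshold else "admixed")
    return labels


# ---------------------------------------------------------------------------
# Cross-panel concordance
# ---------------------------------------------------------------------------


def compare_partitions(
    labels_a: dict[str, object],
    labels_b: dict[str, object],
    duplicates_a: DuplicateReport | None = None,
    duplicates_b: DuplicateReport | None = None,
) -> ConcordanceReport:
    """Concordance of two clusterings over their shared samples.

    Cluster labels are arbitrary in each panel, so panel-B labels are mapped
    onto panel-A labels by maximum-agreement (Hungarian) matching on the
    contingency table; ``dissimilarity_pct`` is the percentage of shared
    samples whose mapped labels still disagree.  The adjusted Rand index is
    computed on the same restricted pair.
    """
    common = sorted(set(labels_a) & set(labels_b))
    if not common:
        raise ValueError("the two labelings share no samples")
    a = [labels_a[s] for s in common]
    b = [labels_b[s] for s in common]
    cats_a = sorted({str(x) for x in a})
    cats_b = sorted({str(x) for x in b})
    ia = {c: i for i, c in enumerate(cats_a)}
    ib = {c: i for i, c in enumerate(cats_b)}
    table = np.zeros((len(cats_a), len(cats_b)), dtype=int)
    for x, y in zip(a, b):
        table[ia[str(x)], ib[str(y)]] += 1
    # pad to square so every cluster can be matched (or left unmatched)
    dim = max(table.shape)
    padded = np.zeros((dim, dim), dtype=int)
    padded[: table.shape[0], : table.shape[1]] = table
    rows, cols = linear_sum_assignment(-padded)
    agreement = int(padded[rows, cols].sum())
    n = len(common)
    mism_pct = 100.0 * (n - agreement) / n

    mapping = {c: r for r, c in zip(rows, cols) if c < len(cats_b)}
    mismatched = [
        s
        for s, x, y in zip(common, a, b)
        if mapping.get(ib[str(y)], -1) != ia[str(x)]
    ]
    ari = float(adjusted_rand_score([str(x) for x in a], [str(y) for y in b]))

    overlap = None
    if duplicates_a is not None and duplicates_b is not None:
        pa = set(duplicates_a.pair_distances)
        pb = set(duplicates_b.pair_distances)
        overlap = {
            "shared": sorted(pa & pb),
            "panel_a_only": sorted(pa - pb),
            "panel_b_only": sorted(pb - pa),
        }
    return ConcordanceReport(
        n_common=n,
        dissimilarity_pct=mism_pct,
        adjusted_rand=ari,
        mismatched_ids=mismatched,
        duplicate_set_overlap=overlap,
    )
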