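"""Genomic relationships from pool allele frequencies and group clustering.

The genomic relationship matrix uses the allele-frequency adaptation of the
Yang et al. SNP-based estimator: the 0/1/2 genotype classes are replaced by
twice the reference allele frequency of the pool, x_ij = 2 * af_ij in
[0, 2].  With per-locus mean frequency p_j (computed over the analysed
populations),

    G_ik = (1/m) * sum_j (x_ij - 2 p_j)(x_kj - 2 p_j) / (2 p_j (1 - p_j))   (i != k)
    G_ii = 1 + (1/m) * sum_j (x_ij^2 - (1 + 2 p_j) x_ij + 2 p_j^2) / (2 p_j (1 - p_j))

Monomorphic loci (p_j (1 - p_j) below tolerance) are excluded with m reduced
accordingly.

Populations are assigned to genetic groups by partitioning around medoids on
the dissimilarity d_ik = max(G) - G_ik (zero diagonal), with the number of
clusters chosen by maximum average silhouette width over k = 2..10 (the
`pamk` convention).  The largest cluster of a reference clustering defines
Group A and the second Group B; re-clustered subsets are mapped onto these
labels by majority overlap, and any additional clusters are 'unassigned'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

_MONO_TOL = 1e-9


class RelationshipError(ValueError):
    pass


@dataclass
class GenomicRelationshipMatrix:
    populations: list[str]
    G: np.ndarray
    n_loci_used: int = 0

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        n = len(self.populations)
        if self.G.shape != (n, n):
            raise ValueError("G must be square and match the population list")
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("G must be symmetric")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite")


@dataclass
class GroupAssignment:
    labels: dict[str, str]  # population -> 'A' | 'B' | 'unassigned'
    k: int = 2
    silhouette: float = np.nan
    low_confidence: bool = False
    medoids: list[str] = field(default_factory=list)

    def members(self, label: str) -> list[str]:
        return [p for p, g in self.labels.items() if g == label]


def compute_grm(af: np.ndarray, populations: list[str] | None = None) -> GenomicRelationshipMatrix:
    """Yang-type GRM from a complete populations x loci AF matrix."""
    from poolgs.genotyping import AlleleFrequencyMatrix

    if isinstance(af, AlleleFrequencyMatrix):
        populations = list(af.populations)
        af = af.af
    af = np.asarray(af, dtype=float)
    if af.ndim != 2 or af.shape[0] < 2:
        raise RelationshipError("need a 2-D AF matrix with at least 2 populations")
    if np.isnan(af).any():
        raise RelationshipError("GRM requires a complete (imputed) AF matrix")
    if populations is None:
        populations = [f"POP{i + 1}" for i in range(af.shape[0])]
    x = 2.0 * af
    p = af.mean(axis=0)
    het = 2.0 * p * (1.0 - p)
    keep = het > _MONO_TOL
    m = int(keep.sum())
    if m == 0:
        raise RelationshipError("no informative (polymorphic) loci for the GRM")
    xk = x[:, keep]
    pk = p[keep]
    hetk = het[keep]
    z = (xk - 2.0 * pk) / np.sqrt(hetk)
    G = (z @ z.T) / m
    diag = 1.0 + np.mean((xk ** 2 - (1.0 + 2.0 * pk) * xk + 2.0 * pk ** 2) / hetk, axis=1)
    np.fill_diagonal(G, diag)
    return GenomicRelationshipMatrix(populations=populations, G=G, n_loci_used=m)


def grm_to_dissimilarity(grm: GenomicRelationshipMatrix) -> np.ndarray:
    """max-shift transform of G into a dissimilarity with zero diagonal."""
    d = np.max(grm.G) - grm.G
    np.fill_diagonal(d, 0.0)
    return d


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.empty(n)
        gains.fill(-np.inf)
        for c in range(n):
            if c in medoids:
                continue
            gains[c] = np.sum(np.maximum(nearest - d[:, c], 0.0))
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, d[:, best])
    return medoids


def pam(d: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, list[int]]:
    """Partitioning around medoids (BUILD + SWAP); deterministic.

    Returns (labels, medoid indices); labels are cluster indices 0..k-1 in
    medoid order.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if not (1 <= k <= n):
        raise RelationshipError(f"k={k} out of range for n={n}")
    medoids = _pam_build(d, k)

    def total_cost(meds):
        return float(d[:, meds].min(axis=1).sum())

    cost = total_cost(medoids)
    for _ in range(max_iter):
        best_swap = None
        best_cost = cost
        for mi, m_ in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                cand = list(medoids)
                cand[mi] = h
                c = total_cost(cand)
                if c < best_cost - 1e-12:
                    best_cost = c
                    best_swap = (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        cost = best_cost
    labels = np.argmin(d[:, medoids], axis=1)
    return labels, medoids


def cluster_groups(
    grm: GenomicRelationshipMatrix,
    min_group_size: int = 50,
    reference: GroupAssignment | None = None,
    k_max: int = 10,
    fixed_k: int | None = None,
    seed: int = 0,
) -> GroupAssignment:
    """Assign populations to Groups A/B by PAM with silhouette-chosen k.

    Without a ``reference`` the largest cluster becomes Group A and the
    second largest Group B (defining the reference clustering); with one,
    clusters are mapped to A/B by majority overlap with the reference
    labels.  Remaining clusters are 'unassigned'.  ``min_group_size`` is
    recorded for callers enforcing the group-exclusion rule.
    """
    d = grm_to_dissimilarity(grm)
    n = d.shape[0]
    if n < 3:
        raise RelationshipError("need at least 3 populations to cluster")
    if fixed_k is not None:
        labels, medoids = pam(d, fixed_k)
        sil = silhouette_score(d, labels, metric="precomputed") if fixed_k > 1 else np.nan
        best = (fixed_k, labels, medoids, sil)
    else:
        best = None
        for k in range(2, min(k_max, n - 1) + 1):
            labels, medoids = pam(d, k)
            if len(np.unique(labels)) < 2:
                continue
            sil = silhouette_score(d, labels, metric="precomputed")
            if best is None or sil > best[3] + 1e-12:
                best = (k, labels, medoids, sil)
        if best is None or best[3] <= 0:
            logger.warning("degenerate silhouette profile; falling back to k=2")
            labels, medoids = pam(d, 2)
            sil = silhouette_score(d, labels, metric="precomputed")
            best = (2, labels, medoids, sil)
    k, labels, medoids, sil = best

    sizes = [(int(np.sum(labels == c)), c) for c in range(k)]
    order = sorted(sizes, key=lambda t: (-t[0], t[1]))
    label_map: dict[int, str] = {}
    if reference is None:
        label_map[order[0][1]] = "A"
        if k > 1:
            label_map[order[1][1]] = "B"
    else:
        counts = {}
        for c in range(k):
            members = [grm.populations[i] for i in np.flatnonzero(labels == c)]
            counts[c] = {
                "A": sum(reference.labels.get(p) == "A" for p in members),
                "B": sum(reference.labels.get(p) == "B" for p in members),
            }
        cluster_a = max(range(k), key=lambda c: (counts[c]["A"], -c))
        label_map[cluster_a] = "A"
        rest = [c for c in range(k) if c != cluster_a]
        if rest:
            cluster_b = max(rest, key=lambda c: (counts[c]["B"], -c))
            label_map[cluster_b] = "B"
    out = {
        p: label_map.get(int(c), "unassigned")
        for p, c in zip(grm.populations, labels)
    }
    return GroupAssignment(
        labels=out,
        k=k,
        silhouette=float(sil),
        low_confidence=bool(sil < 0.25),
        medoids=[grm.populations[m] for m in medoids],
    )
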