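"""Clade delineation by spectral clustering of a phylogeny's graph Laplacian.

Tips are clustered into "modalities" — groups sharing Laplacian-spectral
branching structure — from which nonoverlapping candidate clades are built,
filtered by a minimum size, and flagged for paraphyly.

The Laplacian is built on the dense patristic-distance graph over tips only
(tips define clade membership), and k-means runs on the eigenvectors of the
k largest eigenvalues, where the separation structure of distance-weighted
Laplacians concentrates. Both choices are isolated here so alternatives can
be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .core import Phylogeny

#: default number of spectral modalities (40 / 60 as sensitivity settings)
DEFAULT_K = 50

#: minimum clade size retained downstream
DEFAULT_MIN_SIZE = 50


def patristic_matrix(phy: Phylogeny) -> np.ndarray:
    """Symmetric matrix of tip-to-tip path lengths (Ma), tip order = ``phy.tip_labels``.

    O(n^2) via MRCA depths: for each internal node, pairs of tips drawn from
    different child subtrees coalesce exactly there.
    """
    n = phy.n_tips
    pos = {int(v): i for i, v in enumerate(phy.tip_indices)}
    D = np.zeros((n, n))
    tips_below: dict[int, list[int]] = {}
    depth = phy.depths
    for v in phy.postorder:
        if phy.is_tip[v]:
            tips_below[v] = [pos[int(v)]]
            continue
        groups = [tips_below.pop(c) for c in phy.children[v]]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        d = depth[phy.tip_indices[i]] + depth[phy.tip_indices[j]] - 2 * depth[v]
                        D[i, j] = D[j, i] = d
        tips_below[v] = [i for g in groups for i in g]
    return D


@dataclass
class SpectralEmbedding:
    """Eigendecomposition of L = D - A for a distance-weighted tip graph."""

    eigenvalues: np.ndarray  # descending, >= 0 (smallest is 0)
    eigenvectors: np.ndarray  # columns matched to eigenvalues
    tip_labels: list[str]

    def coordinates(self, k: int) -> np.ndarray:
        """Tip coordinates in the eigenvectors of the k largest eigenvalues.

        Coordinates are scaled by their eigenvalues so that directions
        carrying more of the spectrum dominate the clustering (the deep
        splits of the tree sit in the top of the distance-Laplacian
        spectrum).
        """
        return self.eigenvectors[:, :k] * self.eigenvalues[:k]


def laplacian_spectrum(distance: np.ndarray, tip_labels=None) -> SpectralEmbedding:
    """Spectrum of the graph Laplacian of a dense distance-weighted graph.

    ``L = D - A`` with ``A`` the (symmetric, hollow, nonnegative) distance
    matrix and ``D`` the diagonal of row sums. Eigenvalues are real and
    nonnegative with exactly one zero (constant eigenvector).
    """
    A = np.asarray(distance, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (A < 0).any() or not np.allclose(np.diag(A), 0):
        raise ValueError("distance matrix must be nonnegative with zero diagonal")
    L = np.diag(A.sum(axis=1)) - A
    vals, vecs = np.linalg.eigh(L)
    vals = np.clip(vals, 0.0, None)
    order = np.argsort(vals)[::-1]
    labels = list(tip_labels) if tip_labels is not None else [str(i) for i in range(len(vals))]
    return SpectralEmbedding(vals[order], vecs[:, order], labels)


def spectral_cluster_tips(embedding: SpectralEmbedding, k: int, seed: int = 0,
                          n_init: int = 25) -> dict[str, int]:
    """k-means modality labels for tips, deterministic given ``seed``.

    Best of ``n_init`` restarts by within-cluster sum of squares; ties go to
    the first best restart (scikit-learn behaviour).
    """
    n = len(embedding.tip_labels)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if k == 1:
        return {lab: 0 for lab in embedding.tip_labels}
    X = embedding.coordinates(k)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return {lab: int(c) for lab, c in zip(embedding.tip_labels, km.labels_)}


@dataclass
class Clade:
    label: int
    tips: frozenset[str]
    monophyletic: bool

    @property
    def size(self) -> int:
        return len(self.tips)


@dataclass
class CladePartition:
    """Retained modalities (pairwise disjoint, each >= min_size tips)."""

    labels: dict[str, int]  # every tip -> modality label
    clades: list[Clade]     # retained only
    min_size: int
    k: int
    excluded_fraction: float  # fraction of tips dropped by the size filter

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "min_size": self.min_size,
            "excluded_fraction": self.excluded_fraction,
            "clades": [
                {"label": c.label, "size": c.size, "monophyletic": c.monophyletic,
                 "tips": sorted(c.tips)}
                for c in self.clades
            ],
        }


def extract_clades(phy: Phylogeny, labels: dict[str, int],
                   min_size: int = DEFAULT_MIN_SIZE) -> CladePartition:
    """Candidate clade per modality label; keep those with >= ``min_size`` tips.

    A retained clade is monophyletic iff its tip set equals the full tip set
    of its MRCA; otherwise it is flagged paraphyletic (both kinds are valid
    analysis units).
    """
    missing = set(phy.tip_labels) - set(labels)
    if missing:
        raise ValueError(f"labels missing for tips: {sorted(missing)[:5]}")
    by_label: dict[int, set[str]] = {}
    for tip, lab in labels.items():
        by_label.setdefault(lab, set()).add(tip)
    clades = []
    for lab in sorted(by_label):
        tips = by_label[lab]
        if len(tips) < min_size:
            continue
        mono = phy.tipset(phy.mrca(tips)) == frozenset(tips)
        clades.append(Clade(lab, frozenset(tips), mono))
    kept = sum(c.size for c in clades)
    part = CladePartition(
        labels=dict(labels),
        clades=clades,
        min_size=min_size,
        k=len(by_label),
        excluded_fraction=1.0 - kept / len(labels),
    )
    _assert_partition(part)
    return part


def _assert_partition(part: CladePartition) -> None:
    seen: set[str] = set()
    for c in part.clades:
        if c.size < part.min_size:
            raise AssertionError("retained clade below min_size")
        if seen & c.tips:
            raise AssertionError("retained clades overlap")
        seen |= c.tips


def delineate(phy: Phylogeny, k: int = DEFAULT_K, min_size: int = DEFAULT_MIN_SIZE,
              seed: int = 0, n_init: int = 25) -> CladePartition:
    """End-to-end delineation: patristic graph -> Laplacian -> k-means -> filter."""
    D = patristic_matrix(phy)
    emb = laplacian_spectrum(D, phy.tip_labels)
    labels = spectral_cluster_tips(emb, k=min(k, phy.n_tips), seed=seed, n_init=n_init)
    return extract_clades(phy, labels, min_size=min_size)
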