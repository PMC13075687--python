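"""Clade-specific biogeographic regions ("evoregions") from phylogenetic turnover.

Cell assemblages are summarized by a phylogenetic fuzzy-weighted composition
matrix, ordinated by principal-coordinates analysis of Bray-Curtis
dissimilarities, and clustered with k-means; the number of regions is chosen
by mean silhouette width up to a hard cap (regions later serve as the areas
of the range-evolution model, whose state space grows as 2^K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import PresenceAbsenceMatrix

#: cap on the number of evoregions per clade
DEFAULT_KMAX = 10

#: minimum share of positive-eigenvalue variance for a retained ordination axis
DEFAULT_MIN_EXPLAINED = 0.05


def fuzzy_composition(pam: PresenceAbsenceMatrix, patristic: np.ndarray,
                      species: list[str]) -> pd.DataFrame:
    """Phylogenetic fuzzy-weighted composition, rows = cells occupied by the clade.

    Each cell's occupancy row is smeared over relatives via the similarity
    ``S = 1 - d / max(d)`` derived from patristic distances ``d`` among the
    clade's species, then rescaled to sum to one. Cells with no clade species
    are excluded with a warning.
    """
    if len(species) < 2:
        raise ValueError("need at least two clade species")
    d = np.asarray(patristic, dtype=float)
    if d.shape != (len(species), len(species)):
        raise ValueError("patristic matrix does not match species list")
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("degenerate patristic matrix (max distance is 0)")
    S = 1.0 - d / dmax
    cols = [pam._sp_pos[s] for s in species]
    occ = pam.matrix[:, cols].astype(float)
    keep = occ.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} cells with no clade species")
    P = occ[keep] @ S
    P /= P.sum(axis=1, keepdims=True)
    cells = [c for c, k in zip(pam.cell_ids, keep) if k]
    return pd.DataFrame(P, index=cells, columns=species)


def pcps_axes(P: pd.DataFrame, min_explained: float = DEFAULT_MIN_EXPLAINED):
    """PCoA of Bray-Curtis dissimilarities among fuzzy-composition rows.

    Returns ``(scores, explained)`` where ``scores`` holds the retained axes
    (each explaining at least ``min_explained`` of the total
    positive-eigenvalue variance) and ``explained`` their variance shares.
    """
    X = np.asarray(P, dtype=float)
    if len(np.unique(X.round(12), axis=0)) < 3:
        raise ValueError("degenerate composition: fewer than 3 distinct rows")
    dis = squareform(pdist(X, metric="braycurtis"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative-eigenvalue notes from skbio
        ord_res = pcoa(dis, number_of_dimensions=min(len(X) - 1, X.shape[1]))
    expl = ord_res.proportion_explained.to_numpy()
    keep = expl >= min_explained
    if not keep.any():
        raise ValueError("degenerate composition: no axis reaches min_explained")
    scores = ord_res.samples.to_numpy()[:, keep]
    return pd.DataFrame(scores, index=P.index), expl[keep]


@dataclass
class EvoregionMap:
    """Cell -> region label (1..K) with the silhouette used to pick K."""

    regions: dict[str, int]
    n_regions: int
    silhouette: float
    explained: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.regions, name="region")


def select_evoregions(scores: pd.DataFrame, kmax: int = DEFAULT_KMAX,
                      seed: int = 0, explained=None) -> EvoregionMap:
    """k-means for K = 2..kmax on retained axes; K maximizes mean silhouette."""
    X = np.asarray(scores, dtype=float)
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 cells")
    best = None
    for k in range(2, min(kmax, n - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        if len(np.unique(km.labels_)) < 2:
            continue
        sil = silhouette_score(X, km.labels_)
        if best is None or sil > best[0]:
            best = (sil, k, km.labels_)
    if best is None:
        raise ValueError("clustering failed for every K")
    sil, k, labels = best
    # stable 1..K relabeling by order of first appearance
    remap, out = {}, {}
    for cell, lab in zip(scores.index, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[cell] = remap[lab]
    return EvoregionMap(out, k, float(sil),
                        np.asarray(explained) if explained is not None else np.array([]))


def species_area_sets(evomap: EvoregionMap, pam: PresenceAbsenceMatrix) -> dict[str, frozenset[int]]:
    """Region set per species: labels of the cells where it occurs."""
    out: dict[str, frozenset[int]] = {}
    for j, sp in enumerate(pam.species):
        cells = [pam.cell_ids[i] for i in np.flatnonzero(pam.matrix[:, j])]
        regs = {evomap.regions[c] for c in cells if c in evomap.regions}
        if not regs:
            raise ValueError(f"species {sp!r} occurs in no labeled cell")
        out[sp] = frozenset(regs)
    return out


def delineate_evoregions(pam: PresenceAbsenceMatrix, patristic: np.ndarray,
                         species: list[str], kmax: int = DEFAULT_KMAX,
                         seed: int = 0) -> EvoregionMap:
    """Fuzzy composition -> ordination -> silhouette-selected k-means."""
    P = fuzzy_composition(pam, patristic, species)
    scores, expl = pcps_axes(P)
    return select_evoregions(scores, kmax=kmax, seed=seed, explained=expl)
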