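"""Phylogeny, occupancy-grid and environment containers with Newick/CSV I/O.

Conventions used across the package:

* branch lengths are millions of years (Ma), tips of an ultrametric tree sit
  at the present (age 0);
* grid cells are identified by opaque string ids with decimal-degree
  (latitude, longitude) coordinates — no projection math is performed;
* the minimum arrival time ("very recent colonization") is 10 years,
  i.e. ``1e-5`` Ma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy

#: relative tip-depth spread below which a tree is flagged ultrametric
ULTRAMETRIC_RTOL = 1e-6

#: ten years expressed in Ma; floor for arrival times
ARRIVAL_FLOOR_MA = 1e-5


class NewickError(ValueError):
    """Raised for malformed Newick input (position reported when known)."""


class TreeError(ValueError):
    """Raised for structurally invalid phylogenies or invalid tree queries."""


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """A rooted tree stored as parallel arrays.

    Parameters
    ----------
    parent
        Parent index per node; exactly one entry is ``-1`` (the root).
    branch_length
        Length (Ma, > 0) of the edge above each node; ignored for the root
        (use ``root_length`` for a stem edge retained after pruning).
    labels
        Tip label per node; ``None`` for internal nodes.
    root_length
        Optional stem edge above the root (kept so pruning can preserve
        tip depths); 0 by default.
    """

    def __init__(self, parent, branch_length, labels, root_length: float = 0.0):
        self.parent = np.asarray(parent, dtype=int)
        self.branch_length = np.asarray(branch_length, dtype=float)
        self.labels = list(labels)
        self.root_length = float(root_length)
        self._validate()
        self._index()

    # -- construction-time checks ------------------------------------------
    def _validate(self) -> None:
        n = len(self.parent)
        if n == 0:
            raise TreeError("empty tree")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        nchild = np.zeros(n, dtype=int)
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                nchild[p] += 1
        # connectivity / acyclicity: every node must reach the root
        for v in range(n):
            u, hops = v, 0
            while self.parent[u] >= 0:
                u = self.parent[u]
                hops += 1
                if hops > n:
                    raise TreeError("cycle detected in parent mapping")
            if u != self.root:
                raise TreeError("tree is not connected")
        self._nchild = nchild
        for v in range(n):
            if v == self.root:
                continue
            if not np.isfinite(self.branch_length[v]) or self.branch_length[v] <= 0:
                raise TreeError(f"non-positive branch length at node {v}")
            if nchild[v] == 1:
                raise TreeError(f"unary internal node {v}; suppress before use")
        tips = [self.labels[v] for v in range(n) if nchild[v] == 0]
        if any(t is None for t in tips):
            raise TreeError("unlabeled tip")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")

    def _index(self) -> None:
        n = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            if v != self.root:
                self.children[self.parent[v]].append(v)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        self.tip_indices = np.flatnonzero(self.is_tip)
        self.tip_labels = [self.labels[v] for v in self.tip_indices]
        self._tip_of_label = {lab: int(v) for lab, v in zip(self.tip_labels, self.tip_indices)}
        # iterative postorder
        post, stack = [], [self.root]
        while stack:
            v = stack.pop()
            post.append(v)
            stack.extend(self.children[v])
        post.reverse()
        self.postorder = np.asarray(post, dtype=int)
        depth = np.zeros(n)
        for v in self.postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.branch_length[v]
        self.depths = depth  # distance from the root node (stem excluded)

    # -- basic queries ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    def tip_depths(self) -> np.ndarray:
        return self.depths[self.tip_indices]

    @property
    def is_ultrametric(self) -> bool:
        d = self.tip_depths()
        dmax = d.max()
        return bool(dmax == 0 or (d.max() - d.min()) <= ULTRAMETRIC_RTOL * dmax)

    def node_ages(self) -> np.ndarray:
        """Age (Ma before present) per node, with the present at max tip depth."""
        return self.tip_depths().max() - self.depths

    def tip_index(self, label: str) -> int:
        try:
            return self._tip_of_label[label]
        except KeyError:
            raise TreeError(f"unknown tip label {label!r}") from None

    def mrca(self, labels) -> int:
        """Most recent common ancestor (node index) of a set of tip labels."""
        labels = list(labels)
        if not labels:
            raise TreeError("mrca of empty set")
        anc = None
        for lab in labels:
            v = self.tip_index(lab)
            chain = []
            while v >= 0:
                chain.append(v)
                v = self.parent[v] if v != self.root else -1
            s = set(chain)
            anc = s if anc is None else anc & s
        # deepest shared ancestor = max depth
        return max(anc, key=lambda v: self.depths[v])

    def tipset(self, node: int) -> frozenset[str]:
        """Labels of all tips descending from (or equal to) ``node``."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_tip[v]:
                out.append(self.labels[v])
            else:
                stack.extend(self.children[v])
        return frozenset(out)

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return read_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Phylogeny {self.n_tips} tips, crown {crown_age(self):.3g} Ma>"


def _fmt_len(x: float) -> str:
    s = f"{x:.12g}"
    return s


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (or the contents of a file) into a ``Phylogeny``.

    Unary nodes are suppressed (their branch lengths summed); a root edge
    length, when present, is kept as ``root_length``.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickError("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy reports row/column in its message
        raise NewickError(f"Newick parse error: {exc}") from None
    tree.suppress_unifurcations()
    nodes = list(tree.preorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    parent, length, labels = [], [], []
    for nd in nodes:
        if nd.parent_node is None:
            parent.append(-1)
            length.append(np.nan)
        else:
            parent.append(idx[id(nd.parent_node)])
            if nd.edge.length is None:
                raise NewickError(f"missing branch length above {nd.taxon or 'internal node'}")
            length.append(float(nd.edge.length))
        labels.append(nd.taxon.label if nd.taxon is not None else None)
    root_len = tree.seed_node.edge.length or 0.0
    try:
        return Phylogeny(parent, length, labels, root_length=float(root_len))
    except TreeError as exc:
        raise NewickError(str(exc)) from None


def write_newick(phy: Phylogeny) -> str:
    parts: dict[int, str] = {}
    for v in phy.postorder:
        if phy.is_tip[v]:
            s = phy.labels[v]
        else:
            s = "(" + ",".join(parts.pop(c) for c in phy.children[v]) + ")"
        if v != phy.root:
            s += f":{_fmt_len(phy.branch_length[v])}"
        elif phy.root_length > 0:
            s += f":{_fmt_len(phy.root_length)}"
        parts[v] = s
    return parts[phy.root] + ";"


# ---------------------------------------------------------------------------
# elementary tree summaries
# ---------------------------------------------------------------------------

def crown_age(phy: Phylogeny) -> float:
    """Maximum root-to-tip path length (Ma), stem excluded.

    Equals every tip depth for an ultrametric tree; for non-ultrametric
    input the maximum depth is returned with a warning.
    """
    if phy.n_tips < 2:
        raise TreeError("crown age undefined for a single-tip tree")
    if not phy.is_ultrametric:
        warnings.warn("tree is not ultrametric; crown age is the maximum tip depth")
    return float(phy.tip_depths().max())


def _collapse(parent, length, labels, keep_tips, root_length=0.0):
    """Induced subtree over ``keep_tips`` with unary chains summed.

    Works on raw arrays (which may already contain unary nodes), so it serves
    both ``prune_tree`` and simulator tree assembly. Returns array triple plus
    the accumulated stem length above the new root.
    """
    parent = np.asarray(parent, dtype=int)
    length = np.asarray(length, dtype=float)
    n = len(parent)
    root = int(np.flatnonzero(parent < 0)[0])
    children = [[] for _ in range(n)]
    for v in range(n):
        if v != root:
            children[parent[v]].append(v)
    # postorder kept-tip counts
    post, stack = [], [root]
    while stack:
        v = stack.pop()
        post.append(v)
        stack.extend(children[v])
    nkept = np.zeros(n, dtype=int)
    for v in reversed(post):
        if not children[v]:
            nkept[v] = 1 if labels[v] in keep_tips else 0
        else:
            nkept[v] = sum(nkept[c] for c in children[v])
    if nkept[root] == 0:
        raise TreeError("no kept tips")
    # descend to the first node that bifurcates w.r.t. kept tips
    stem = float(root_length)
    new_root = root
    while children[new_root]:
        active = [c for c in children[new_root] if nkept[c] > 0]
        if len(active) != 1:
            break
        new_root = active[0]
        stem += length[new_root]
    np_, nl, nlab = [], [], []

    def new_node(p, ln, lab):
        np_.append(p)
        nl.append(ln)
        nlab.append(lab)
        return len(np_) - 1

    rid = new_node(-1, np.nan, labels[new_root] if not children[new_root] else None)
    # stack of (orig node, new parent id, accumulated length); children pushed
    # reversed so sibling order (hence node numbering) is preserved
    work = [(c, rid, 0.0) for c in reversed(children[new_root]) if nkept[c] > 0]
    while work:
        v, p, acc = work.pop()
        acc += length[v]
        active = [c for c in children[v] if nkept[c] > 0]
        if not children[v]:
            new_node(p, acc, labels[v])
        elif len(active) == 1:
            work.append((active[0], p, acc))
        else:
            vid = new_node(p, acc, None)
            work.extend((c, vid, 0.0) for c in reversed(active))
    return np_, nl, nlab, stem


def prune_tree(phy: Phylogeny, keep) -> Phylogeny:
    """Induced subtree over ``keep`` tip labels.

    Unary nodes are suppressed with branch lengths summed; the path from the
    old root down to the kept clade is retained as a root stem, so kept tip
    depths (and all patristic distances) are preserved exactly.
    """
    keep = set(keep)
    if len(keep) < 2:
        raise TreeError("need at least two tips to keep")
    unknown = keep - set(phy.tip_labels)
    if unknown:
        raise TreeError(f"unknown tip labels: {sorted(unknown)}")
    par, ln, lab, stem = _collapse(phy.parent, phy.branch_length, phy.labels,
                                   keep, phy.root_length)
    return Phylogeny(par, ln, lab, root_length=stem)


# ---------------------------------------------------------------------------
# Presence-absence matrix and environment table
# ---------------------------------------------------------------------------

@dataclass
class PresenceAbsenceMatrix:
    """Binary cells x species occupancy with cell coordinates.

    ``matrix[i, j] == 1`` iff species ``species[j]`` occurs in cell
    ``cell_ids[i]``. Grain convention: cells approximate a 1-degree grid;
    synthetic worlds use an integer lattice in the same fields.
    """

    cell_ids: list[str]
    coords: np.ndarray  # (n_cells, 2): latitude, longitude
    species: list[str]
    matrix: np.ndarray  # (n_cells, n_species) in {0, 1}

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.cell_ids), len(self.species)):
            raise ValueError("matrix shape does not match cell/species lists")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("occupancy entries must be 0/1")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite cell coordinates")
        empty = [s for s, c in zip(self.species, self.matrix.sum(axis=0)) if c == 0]
        if empty:
            raise ValueError(f"species with no occurrences: {empty[:5]}")
        self.matrix = self.matrix.astype(np.uint8)
        self._cell_pos = {c: i for i, c in enumerate(self.cell_ids)}
        self._sp_pos = {s: j for j, s in enumerate(self.species)}

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, dtype={"cell_id": str})
        sp = [c for c in df.columns if c not in ("cell_id", "lat", "lon")]
        return cls(
            cell_ids=df["cell_id"].tolist(),
            coords=df[["lat", "lon"]].to_numpy(),
            species=sp,
            matrix=df[sp].to_numpy(),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.species)
        df.insert(0, "lon", self.coords[:, 1])
        df.insert(0, "lat", self.coords[:, 0])
        df.insert(0, "cell_id", self.cell_ids)
        return df

    def subset_species(self, species) -> "PresenceAbsenceMatrix":
        """Restrict to a species subset; cells with no remaining species kept."""
        species = [s for s in self.species if s in set(species)]
        cols = [self._sp_pos[s] for s in species]
        return PresenceAbsenceMatrix(self.cell_ids, self.coords, species,
                                     self.matrix[:, cols])


def richness_per_cell(pam: PresenceAbsenceMatrix) -> pd.Series:
    """Per-cell species counts (row sums of the occupancy matrix)."""
    return pd.Series(pam.matrix.sum(axis=1).astype(int), index=pam.cell_ids,
                     name="richness")


def geographic_extent(pam: PresenceAbsenceMatrix, species) -> int:
    """Number of grid cells occupied by at least one species of the subset."""
    species = list(species)
    if not species:
        raise ValueError("empty species subset")
    cols = [pam._sp_pos[s] for s in species]
    return int((pam.matrix[:, cols].sum(axis=1) > 0).sum())


@dataclass
class EnvironmentTable:
    """Per-cell temperature (degC), precipitation (mm/yr) and NPP (>= 0).

    One row per cell of the matching ``PresenceAbsenceMatrix``; latitude /
    longitude copies are optional (used only by spatial sensitivity refits).
    """

    data: pd.DataFrame  # index: cell_id

    def __post_init__(self):
        need = {"temperature", "precipitation", "npp"}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"environment table missing columns: {sorted(missing)}")
        if self.data[sorted(need)].isna().any().any():
            raise ValueError("missing values in environment table")
        if (self.data["npp"] < 0).any():
            raise ValueError("negative NPP")

    @classmethod
    def from_csv(cls, path) -> "EnvironmentTable":
        df = pd.read_csv(path, dtype={"cell_id": str}).set_index("cell_id")
        return cls(df)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="cell_id")
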