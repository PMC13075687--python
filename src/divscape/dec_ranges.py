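"""Dispersal-Extinction-Cladogenesis (DEC) ancestral ranges and arrival times.

The DEC model describes geographic range evolution on a time-calibrated
phylogeny: along branches, ranges expand area by area (dispersal, rate ``d``
per source area per Ma) and contract (local extinction, rate ``e`` per
occupied area per Ma, with single-area ranges collapsing to an absorbing
null state); at speciation the parental range is partitioned among the two
daughters by vicariance or subset sympatry, all outcomes equally weighted.

On top of the fitted reconstruction we compute the arrival-time metric: for
a species present in a region, the age of the deepest ancestral node whose
most-probable range contains that region along an uninterrupted tip-to-node
chain; a species whose immediate ancestor already lacked the region gets the
10-year floor (1e-5 Ma). Cell-level "assemblage age" is the mean arrival
time over the species present in the cell, evaluated for the cell's region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .core import ARRIVAL_FLOOR_MA, Phylogeny, PresenceAbsenceMatrix, TreeError
from .evoregions import EvoregionMap

MAX_AREAS = 10


# ---------------------------------------------------------------------------
# state space and rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DECParams:
    """Dispersal and local-extinction rates (per area per Ma, >= 0)."""

    d: float
    e: float

    def __post_init__(self):
        if not (np.isfinite(self.d) and np.isfinite(self.e)
                and self.d >= 0 and self.e >= 0):
            raise ValueError("rates must be finite and >= 0")


class RangeStateSpace:
    """Ordered nonempty area subsets of size <= mmax, plus a trailing null state.

    Areas are labeled 1..A externally and stored as bitmasks internally.
    States are ordered by (size, bitmask); the absorbing null (empty) state
    is appended last, at index ``n_states``.
    """

    def __init__(self, n_areas: int, mmax: int | None = None):
        mmax = n_areas if mmax is None else mmax
        if not 1 <= mmax <= n_areas <= MAX_AREAS:
            raise ValueError(f"need 1 <= mmax <= A <= {MAX_AREAS}")
        self.n_areas = n_areas
        self.mmax = mmax
        masks = [m for m in range(1, 1 << n_areas) if bin(m).count("1") <= mmax]
        masks.sort(key=lambda m: (bin(m).count("1"), m))
        self.states = tuple(masks)          # non-null states only
        self.n_states = len(masks)          # excludes null
        self.null_index = self.n_states
        self.index = {m: i for i, m in enumerate(masks)}
        self._clado = None

    def mask_of(self, areas) -> int:
        m = 0
        for a in areas:
            if not 1 <= a <= self.n_areas:
                raise ValueError(f"area {a} outside 1..{self.n_areas}")
            m |= 1 << (a - 1)
        return m

    def areas_of(self, mask: int) -> frozenset[int]:
        return frozenset(a + 1 for a in range(self.n_areas) if mask >> a & 1)

    def state_index(self, areas) -> int:
        m = self.mask_of(areas)
        if m not in self.index:
            raise ValueError(f"range {sorted(areas)} exceeds mmax={self.mmax} or is empty")
        return self.index[m]


def build_state_space(n_areas: int, mmax: int | None = None) -> RangeStateSpace:
    return RangeStateSpace(n_areas, mmax)


def anagenetic_Q(space: RangeStateSpace, params: DECParams) -> np.ndarray:
    """Generator over states (+ null): dispersal d*|R| per gainable area, extinction e per area."""
    m = space.n_states + 1
    Q = np.zeros((m, m))
    for i, R in enumerate(space.states):
        size = bin(R).count("1")
        for a in range(space.n_areas):
            bit = 1 << a
            if R & bit:
                # contraction; singletons drop to the null state
                tgt = R ^ bit
                j = space.index[tgt] if tgt else space.null_index
                Q[i, j] += params.e
            elif size + 1 <= space.mmax:
                Q[i, space.index[R | bit]] += params.d * size
        Q[i, i] = -Q[i].sum()
    return Q


def transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """``expm(Q t)``: a stochastic matrix (rows sum to 1, entries >= 0)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    P = expm(Q * t)
    return np.clip(P, 0.0, None)


class _Propagator:
    """Branch propagator P(t) = V diag(e^{w t}) V^{-1}, with expm fallback."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.ok = False
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            if np.linalg.cond(V) < 1e8:
                self.w, self.V, self.Vinv = w, V, Vinv
                self.ok = True
        except np.linalg.LinAlgError:
            pass

    def __call__(self, t: float) -> np.ndarray:
        if self.ok:
            P = (self.V * np.exp(self.w * t)) @ self.Vinv
            return np.clip(P.real, 0.0, None)
        return transition_probs(self.Q, t)


# ---------------------------------------------------------------------------
# cladogenesis
# ---------------------------------------------------------------------------

def cladogenesis_table(space: RangeStateSpace, areas) -> list[tuple[frozenset, frozenset, float]]:
    """Equally weighted daughter-range outcomes for a parental range.

    Single-area ranges are inherited identically by both daughters; wider
    ranges split by vicariance (one area vs the rest, both orders) or subset
    sympatry (one daughter keeps the full range, the other one area).
    """
    mask = space.mask_of(areas)
    if mask == 0:
        raise ValueError("null state has no cladogenetic outcomes")
    out = _outcomes(mask)
    return [(space.areas_of(l), space.areas_of(r), w) for l, r, w in out]


def _outcomes(mask: int) -> list[tuple[int, int, float]]:
    bits = [1 << a for a in range(MAX_AREAS) if mask >> a & 1]
    if len(bits) == 1:
        return [(mask, mask, 1.0)]
    pairs: set[tuple[int, int]] = set()
    for b in bits:
        rest = mask ^ b
        pairs |= {(b, rest), (rest, b), (b, mask), (mask, b)}
    w = 1.0 / len(pairs)
    return [(l, r, w) for l, r in sorted(pairs)]


def _clado_arrays(space: RangeStateSpace):
    """Concatenated (left, right, weight) outcome arrays with per-state offsets."""
    if space._clado is None:
        ptr, L, R, W = [0], [], [], []
        for mask in space.states:
            for l, r, w in _outcomes(mask):
                L.append(space.index[l])
                R.append(space.index[r])
                W.append(w)
            ptr.append(len(L))
        space._clado = (np.array(ptr), np.array(L), np.array(R), np.array(W))
    return space._clado


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _tip_state_indices(phy: Phylogeny, tip_ranges: dict, space: RangeStateSpace) -> dict[int, int]:
    out = {}
    for lab in phy.tip_labels:
        if lab not in tip_ranges:
            raise ValueError(f"no range given for tip {lab!r}")
        out[phy.tip_index(lab)] = space.state_index(tip_ranges[lab])
    return out


def _uppass(phy: Phylogeny, tip_idx: dict[int, int], space: RangeStateSpace,
            prop, keep_branch_partials: bool = False):
    """Felsenstein pruning with per-node rescaling.

    Returns (D, logscale, U) where ``D[v]`` is the conditional likelihood of
    the data below node v given its pre-cladogenesis state, and ``U[v]`` (if
    requested) the likelihood contribution of v's subtree propagated to the
    top of its branch.
    """
    m = space.n_states + 1
    ptr, L, R, W = _clado_arrays(space)
    D = np.zeros((phy.n_nodes, m))
    U = np.zeros((phy.n_nodes, m)) if keep_branch_partials else None
    logscale = 0.0
    for v in phy.postorder:
        if phy.is_tip[v]:
            D[v, tip_idx[v]] = 1.0
        else:
            kids = phy.children[v]
            if len(kids) != 2:
                raise TreeError("DEC likelihood requires a binary tree")
            ups = []
            for c in kids:
                u = prop(phy.branch_length[c]) @ D[c]
                if U is not None:
                    U[c] = u
                ups.append(u)
            prod = W * ups[0][L] * ups[1][R]
            D[v, :space.n_states] = np.add.reduceat(prod, ptr[:-1])
        s = D[v].max()
        if s <= 0:
            return D, -np.inf, U
        D[v] /= s
        logscale += math.log(s)
    return D, logscale, U


def _root_prior(space: RangeStateSpace, root_prior) -> np.ndarray:
    m = space.n_states + 1
    pi = np.zeros(m)
    if isinstance(root_prior, str):
        if root_prior != "uniform":
            raise ValueError("root_prior must be 'uniform' or an explicit vector")
        pi[:space.n_states] = 1.0 / space.n_states
    else:
        arr = np.asarray(root_prior, dtype=float)
        pi[:space.n_states] = arr / arr.sum()
    return pi


def dec_loglik(phy: Phylogeny, tip_ranges: dict, params: DECParams,
               space: RangeStateSpace | None = None,
               root_prior="uniform") -> float:
    """Log-likelihood of observed tip ranges under DEC (pruning algorithm).

    The root is averaged over non-null states with a uniform prior by
    default; pass a vector over non-null states to change the conditioning.
    """
    if space is None:
        space = _infer_space(tip_ranges)
    tip_idx = _tip_state_indices(phy, tip_ranges, space)
    prop = _Propagator(anagenetic_Q(space, params))
    D, logscale, _ = _uppass(phy, tip_idx, space, prop)
    pi = _root_prior(space, root_prior)
    lik = float(pi @ D[phy.root])
    if lik <= 0 or not np.isfinite(logscale):
        return -np.inf
    return math.log(lik) + logscale


def _infer_space(tip_ranges: dict) -> RangeStateSpace:
    areas = set()
    for r in tip_ranges.values():
        areas |= set(r)
    return RangeStateSpace(max(areas))


@dataclass
class DECFit:
    params: DECParams
    loglik: float
    converged: bool
    n_starts: int


def fit_dec(phy: Phylogeny, tip_ranges: dict, space: RangeStateSpace | None = None,
            root_prior="uniform", starts=((0.1, 0.1), (0.02, 0.2), (1.0, 0.05)),
            bounds=(1e-4, 50.0)) -> DECFit:
    """Maximize the DEC log-likelihood over (log d, log e).

    Bounded quasi-Newton (L-BFGS-B) from several starts; the best optimum is
    returned. Raises if every start fails to produce a finite likelihood.
    """
    if space is None:
        space = _infer_space(tip_ranges)
    tip_idx = _tip_state_indices(phy, tip_ranges, space)
    lo, hi = math.log(bounds[0]), math.log(bounds[1])

    def nll(x):
        prop = _Propagator(anagenetic_Q(space, DECParams(math.exp(x[0]), math.exp(x[1]))))
        D, logscale, _ = _uppass(phy, tip_idx, space, prop)
        pi = _root_prior(space, root_prior)
        lik = float(pi @ D[phy.root])
        if lik <= 0 or not np.isfinite(logscale):
            return 1e10
        return -(math.log(lik) + logscale)

    best, ok = None, False
    for d0, e0 in starts:
        x0 = np.clip(np.log([d0, e0]), lo, hi)
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(lo, hi), (lo, hi)],
                       options={"maxiter": 200, "eps": 1e-5})
        if np.isfinite(res.fun) and res.fun < 1e9:
            ok = True
            if best is None or res.fun < best.fun:
                best = res
    if not ok or best is None:
        raise RuntimeError("DEC optimization failed from every start "
                           f"(last status: {res.message if 'res' in dir() else 'n/a'})")
    # derivative-free polish: finite-difference noise can leave L-BFGS-B a
    # hair off the optimum
    res = minimize(nll, best.x, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 400})
    if np.isfinite(res.fun) and res.fun <= best.fun:
        best = res
    x = np.clip(best.x, lo, hi)
    d, e = np.exp(x)
    return DECFit(DECParams(float(d), float(e)), -float(nll(x)),
                  bool(best.success), len(starts))


# ---------------------------------------------------------------------------
# marginal ancestral states
# ---------------------------------------------------------------------------

@dataclass
class AncestralReconstruction:
    """Per-node marginal range probabilities and their argmax ranges."""

    space: RangeStateSpace
    marginals: dict[int, np.ndarray]       # node -> probs over non-null states
    argmax_range: dict[int, frozenset[int]]  # node -> most probable range
    params: DECParams


def ancestral_ranges(phy: Phylogeny, tip_ranges: dict, params: DECParams,
                     space: RangeStateSpace | None = None,
                     root_prior="uniform") -> AncestralReconstruction:
    """Marginal node ranges via the standard up/down (outside) passes.

    Marginals refer to the lineage state immediately before cladogenesis at
    each internal node; tips carry their observed range with probability 1.
    """
    if space is None:
        space = _infer_space(tip_ranges)
    tip_idx = _tip_state_indices(phy, tip_ranges, space)
    prop = _Propagator(anagenetic_Q(space, params))
    ns = space.n_states
    ptr, L, R, W = _clado_arrays(space)
    seg = np.repeat(np.arange(ns), np.diff(ptr))  # parent state per outcome row
    D, logscale, U = _uppass(phy, tip_idx, space, prop, keep_branch_partials=True)
    if not np.isfinite(logscale):
        raise RuntimeError("data have zero likelihood under the supplied parameters")
    m = ns + 1
    O = np.zeros((phy.n_nodes, m))
    O[phy.root] = _root_prior(space, root_prior)
    marg: dict[int, np.ndarray] = {}
    argmax: dict[int, frozenset[int]] = {}
    for v in phy.postorder[::-1]:  # preorder
        p = O[v] * D[v]
        tot = p[:ns].sum()
        marg[v] = p[:ns] / tot if tot > 0 else np.full(ns, 1.0 / ns)
        argmax[v] = space.areas_of(space.states[int(np.argmax(marg[v]))])
        if phy.is_tip[v]:
            continue
        c1, c2 = phy.children[v]
        Ov = O[v][:ns][seg]
        base = W * Ov
        g1 = np.zeros(m)
        g2 = np.zeros(m)
        np.add.at(g1, L, base * U[c2][R])
        np.add.at(g2, R, base * U[c1][L])
        for c, g in ((c1, g1), (c2, g2)):
            oc = g @ prop(phy.branch_length[c])
            s = oc.sum()
            O[c] = oc / s if s > 0 else oc
    return AncestralReconstruction(space, marg, argmax, params)


# ---------------------------------------------------------------------------
# arrival times and assemblage ages
# ---------------------------------------------------------------------------

def arrival_time(species: str, region: int, recon: AncestralReconstruction,
                 phy: Phylogeny, floor: float = ARRIVAL_FLOOR_MA,
                 continuous: bool = True) -> float:
    """Age (Ma) of the deepest ancestral node whose argmax range holds ``region``.

    With ``continuous=True`` (default) occupancy must be uninterrupted from
    the tip's parent up to that node, so a region lost and regained deeper in
    the tree does not inflate the arrival age. If even the tip's parent lacks
    the region the species is taken to have dispersed in after its most
    recent speciation and receives the 10-year floor.
    """
    tip = phy.tip_index(species)
    ages = phy.node_ages()
    deepest = None
    v = int(phy.parent[tip])
    while v >= 0:
        if region in recon.argmax_range[v]:
            deepest = v
        elif continuous:
            break
        v = int(phy.parent[v]) if v != phy.root else -1
    if deepest is None:
        return floor
    return max(float(ages[deepest]), floor)


@dataclass
class ArrivalTable:
    """(species, region) -> arrival time (Ma), clipped to [1e-5, crown age]."""

    arrivals: dict[tuple[str, int], float]

    def get(self, species: str, region: int) -> float:
        return self.arrivals[(species, region)]


def build_arrival_table(recon: AncestralReconstruction, phy: Phylogeny,
                        area_sets: dict[str, frozenset[int]],
                        continuous: bool = True) -> ArrivalTable:
    """Arrival time for every (species, occupied region) pair."""
    out = {}
    for sp, regions in area_sets.items():
        for r in regions:
            out[(sp, r)] = arrival_time(sp, r, recon, phy, continuous=continuous)
    return ArrivalTable(out)


def assemblage_ages(table: ArrivalTable, pam: PresenceAbsenceMatrix,
                    evomap: EvoregionMap) -> pd.Series:
    """Mean arrival time across the species present in each cell (NaN if empty).

    Each species' arrival is evaluated for the cell's evoregion.
    """
    out = {}
    for i, cell in enumerate(pam.cell_ids):
        present = [pam.species[j] for j in np.flatnonzero(pam.matrix[i])]
        region = evomap.regions.get(cell)
        if not present or region is None:
            out[cell] = np.nan
            continue
        vals = [table.arrivals.get((sp, region)) for sp in present]
        vals = [v for v in vals if v is not None]
        out[cell] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out, name="age")


# ---------------------------------------------------------------------------
# forward simulation (used for parameter-recovery checks)
# ---------------------------------------------------------------------------

def simulate_dec_ranges(phy: Phylogeny, space: RangeStateSpace, params: DECParams,
                        rng: np.random.Generator, max_tries: int = 100) -> dict[str, frozenset[int]]:
    """Simulate tip ranges under DEC, conditioned on every lineage surviving.

    Conditioning is branch-wise: a branch history that is absorbed in the
    null (globally extinct) state is redrawn, up to ``max_tries`` per
    branch. This mildly under-represents contraction events relative to the
    unconditional process — the standard price of simulating an observed
    (extant-only) clade.
    """
    Q = anagenetic_Q(space, params)
    ns = space.n_states
    state = {phy.root: int(rng.integers(ns))}
    for v in phy.postorder[::-1]:  # preorder
        if phy.is_tip[v]:
            continue
        R = space.states[state[v]]
        outs = _outcomes(R)
        k = rng.choice(len(outs), p=[w for _, _, w in outs])
        l, r, _ = outs[k]
        for c, s0 in zip(phy.children[v], (l, r)):
            for _ in range(max_tries):
                si = _evolve_branch(space.index[s0], Q, phy.branch_length[c], rng, ns)
                if si != space.null_index:
                    break
            else:
                raise RuntimeError("branch kept hitting the null state; "
                                   "lower e or shorten the tree")
            state[c] = si
    return {phy.labels[v]: space.areas_of(space.states[state[v]])
            for v in phy.tip_indices}


def _evolve_branch(si: int, Q: np.ndarray, t: float, rng, ns: int) -> int:
    """Jump-chain simulation of the anagenetic CTMC along one branch."""
    s, remaining = si, t
    while True:
        rate = -Q[s, s]
        if rate <= 0:
            return s
        wait = rng.exponential(1.0 / rate)
        if wait > remaining:
            return s
        remaining -= wait
        probs = Q[s].copy()
        probs[s] = 0.0
        probs = np.clip(probs, 0, None)
        probs /= probs.sum()
        s = int(rng.choice(len(probs), p=probs))
        if s == ns:  # absorbed in the null state
            return s
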