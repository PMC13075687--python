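"""Synthetic worlds and clades simulated under four richness-generating scenarios.

A world is a hemispheric lattice (equator at row 0) with a latitudinal
temperature gradient, a smoothed random precipitation field, an NPP field
driven by both, and contiguous latitudinal bands serving as biogeographic
areas. A clade is grown on that world by a Gillespie birth-death-dispersal
process over areas, starting from a single lineage in one area:

* stable persistence — speciation constant; per-species extinction rises
  with regional richness relative to an NPP-proportional equilibrium
  K(region), so richness settles where turnover balances;
* speciation balance — speciation varies with regional temperature
  (lambda = lambda0 * exp(gamma_T * T~)); extinction diversity-dependent
  with a common K, so equilibrium richness tracks speciation;
* historical legacy — constant rates with lambda > mu, slow dispersal and a
  short horizon: richness reflects time since colonization;
* cradles of diversity — temperature-dependent speciation, constant low
  extinction, short horizon: richness reflects speciation rate x time.

Diversity dependence acts on extinction only; speciation is within-region
(the new daughter starts in the region where the event fired, the parent
keeps its range). Range-splitting cladogenesis is deliberately not
simulated: the range-evolution model downstream is an inference tool here,
not the generative truth, which is exactly what makes the pipeline's
robustness testable.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import EnvironmentTable, Phylogeny, PresenceAbsenceMatrix, _collapse

SCENARIOS = ("stable_persistence", "speciation_balance",
             "historical_legacy", "cradles_of_diversity")

EQUILIBRIUM = ("stable_persistence", "speciation_balance")


class CladeExtinctError(RuntimeError):
    """The simulated clade died (or stayed trivially small) before the horizon."""


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------

@dataclass
class WorldConfig:
    """Lattice and environment-field settings.

    Latitude equals the row index (equator at row 0), so temperature
    declines monotonically poleward; areas are contiguous latitudinal bands.
    """

    rows: int = 24
    cols: int = 18
    n_areas: int = 6
    temp_equator: float = 28.0
    temp_slope: float = 1.5        # degC lost per row of latitude
    temp_noise_sd: float = 1.0
    precip_mean: float = 1200.0
    precip_sd: float = 500.0
    precip_smoothness: float = 2.0  # gaussian-filter sigma (cells)
    alpha_t: float = 1.0            # NPP sensitivity to standardized temperature
    alpha_p: float = 1.0            # NPP sensitivity to standardized precipitation
    npp_base: float = 4.0
    npp_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.rows < 4 or self.cols < 4:
            raise ValueError("lattice must be at least 4 x 4")
        if not 2 <= self.n_areas <= 10:
            raise ValueError("number of areas must be in 2..10")
        if self.alpha_t < 0 or self.alpha_p < 0:
            raise ValueError("NPP coefficients must be >= 0")


@dataclass
class World:
    config: WorldConfig
    cell_ids: list[str]
    coords: np.ndarray            # (n_cells, 2): lat (row), lon (col)
    env: EnvironmentTable         # includes lat / lon columns
    area_of_cell: np.ndarray      # 1..n_areas per cell
    region_temp_z: np.ndarray     # z-scored mean temperature per area
    region_npp: np.ndarray        # mean NPP per area

    @property
    def n_areas(self) -> int:
        return self.config.n_areas

    def cells_of_area(self, area: int) -> np.ndarray:
        return np.flatnonzero(self.area_of_cell == area)


def make_world(config: WorldConfig) -> World:
    rng = np.random.default_rng(config.seed)
    rows, cols = config.rows, config.cols
    lat, lon = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    lat, lon = lat.ravel().astype(float), lon.ravel().astype(float)
    temp = (config.temp_equator - config.temp_slope * lat
            + rng.normal(0, config.temp_noise_sd, rows * cols))
    fieldp = gaussian_filter(rng.normal(size=(rows, cols)),
                             sigma=config.precip_smoothness).ravel()
    fieldp = (fieldp - fieldp.mean()) / fieldp.std()
    precip = np.clip(config.precip_mean + config.precip_sd * fieldp, 0.0, None)
    zt = (temp - temp.mean()) / temp.std()
    zp = (precip - precip.mean()) / precip.std()
    npp = np.clip(config.npp_base + config.alpha_t * zt + config.alpha_p * zp
                  + rng.normal(0, config.npp_noise_sd, rows * cols), 0.0, None)
    area = (lat * config.n_areas / rows).astype(int) + 1  # latitudinal bands
    cell_ids = [f"r{int(a)}c{int(b)}" for a, b in zip(lat, lon)]
    env = EnvironmentTable(pd.DataFrame({
        "temperature": temp, "precipitation": precip, "npp": npp,
        "lat": lat, "lon": lon,
    }, index=pd.Index(cell_ids, name="cell_id")))
    mt = np.array([temp[area == a].mean() for a in range(1, config.n_areas + 1)])
    mnpp = np.array([npp[area == a].mean() for a in range(1, config.n_areas + 1)])
    return World(config, cell_ids, np.column_stack([lat, lon]), env, area,
                 (mt - mt.mean()) / mt.std(), mnpp)


# ---------------------------------------------------------------------------
# scenario parameters
# ---------------------------------------------------------------------------

@dataclass
class ScenarioParams:
    """Diversification and dispersal rates for one simulated clade.

    ``k_npp`` scales the equilibrium richness K(region) per unit of regional
    mean NPP; ``gamma_t`` is the temperature sensitivity of speciation;
    ``dispersal`` is the per-lineage rate of spreading into an adjacent
    unoccupied area. ``tau=None`` picks the default horizon: 25 / mu0 for
    equilibrium scenarios, 5.5 / max net diversification otherwise (long
    enough for a few hundred extant species).
    """

    scenario: str
    lam0: float = 0.5
    mu0: float = 0.4
    k_npp: float = 10.0
    gamma_t: float = 0.0
    dispersal: float = 0.1
    tau: float | None = None
    seed: int = 0
    thin: float = 0.9   # per-cell occupancy retention inside a species' patch
    patch_radius: tuple[int, int] = (2, 5)  # per-species range radius (cells)
    local_energy_occupancy: bool = False  # weight cell occupancy by local NPP
    dispersal_npp_bias: float = 0.0  # colonization biased toward productive regions
    dispersal_saturation: float | None = None  # cap on per-pair propagule pressure
    cell_grain_rates: bool = False  # lambda set by each species' home-cell temperature
    home_sd: float = 2.5  # daughter home dispersion around the parent home (cells)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for r in (self.lam0, self.mu0, self.k_npp, self.gamma_t, self.dispersal):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be > 0")


def default_scenario_params(scenario: str, seed: int = 0) -> ScenarioParams:
    """Per-scenario defaults with strong, distinguishable effect sizes."""
    table = {
        "stable_persistence":   dict(lam0=0.5, mu0=0.4, k_npp=10.0, gamma_t=0.0,
                                     dispersal=0.30, local_energy_occupancy=True),
        "speciation_balance":   dict(lam0=0.4, mu0=0.4, k_npp=12.0, gamma_t=1.3,
                                     dispersal=0.15, cell_grain_rates=True),
        "historical_legacy":    dict(lam0=0.35, mu0=0.05, k_npp=10.0, gamma_t=0.0,
                                     dispersal=0.25, dispersal_saturation=2.0),
        "cradles_of_diversity": dict(lam0=0.35, mu0=0.05, k_npp=10.0, gamma_t=0.8,
                                     dispersal=0.25, dispersal_saturation=2.0,
                                     cell_grain_rates=True),
    }
    return ScenarioParams(scenario=scenario, seed=seed, **table[scenario])


def _region_rates(world: World, params: ScenarioParams):
    """Per-region speciation rate, K, and the horizon tau."""
    A = world.n_areas
    lam = params.lam0 * np.exp(params.gamma_t * world.region_temp_z)
    if params.scenario == "stable_persistence":
        lam = np.full(A, params.lam0)
        K = params.k_npp * world.region_npp
    elif params.scenario == "speciation_balance":
        K = np.full(A, params.k_npp * world.region_npp.mean())
    else:
        K = np.full(A, np.inf)  # no diversity dependence
    tau = params.tau
    if tau is None:
        if params.scenario in EQUILIBRIUM:
            tau = 25.0 / params.mu0
        else:
            net = lam.max() - params.mu0
            if net <= 0:
                raise ValueError("nonequilibrium scenario needs lambda > mu")
            tau = 5.5 / net
    return lam, K, tau


# ---------------------------------------------------------------------------
# Gillespie simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedClade:
    """A simulated clade with full ground truth."""

    phylogeny: Phylogeny
    pam: PresenceAbsenceMatrix
    env: EnvironmentTable
    world: World
    params: ScenarioParams
    tau: float
    scenario: str
    true_arrival: dict[tuple[str, int], float]   # (tip, region) -> age (Ma)
    true_tip_lambda: dict[str, float]            # speciation rate at origin region
    region_richness: np.ndarray                  # final per-area species counts
    event_log: list[tuple] = field(repr=False, default_factory=list)


class _Occupants:
    """Per-region occupant lists with O(1) uniform sampling and removal."""

    def __init__(self, n_areas: int):
        self.lists = [[] for _ in range(n_areas + 1)]  # 1-based regions
        self.pos: dict[tuple[int, int], int] = {}

    def add(self, region: int, sp: int) -> None:
        self.pos[(region, sp)] = len(self.lists[region])
        self.lists[region].append(sp)

    def remove(self, region: int, sp: int) -> None:
        lst = self.lists[region]
        i = self.pos.pop((region, sp))
        last = lst.pop()
        if i < len(lst):
            lst[i] = last
            self.pos[(region, last)] = i

    def sample(self, region: int, rng) -> int:
        lst = self.lists[region]
        return lst[rng.integers(len(lst))]

    def count(self, region: int) -> int:
        return len(self.lists[region])


def simulate_clade(world: World, params: ScenarioParams,
                   min_tips: int = 2, max_tips: int = 5000,
                   max_events: int = 2_000_000) -> SimulatedClade:
    """Gillespie simulation of the lineage-based birth-death-dispersal process.

    Raises ``CladeExtinctError`` if fewer than ``min_tips`` lineages survive
    to the horizon (the caller resamples with a fresh seed), and if the clade
    exceeds ``max_tips`` (runaway nonequilibrium growth).
    """
    rng = np.random.default_rng(params.seed)
    A = world.n_areas
    lam, K, tau = _region_rates(world, params)
    mu0 = params.mu0
    dd = params.scenario in EQUILIBRIUM
    temp = world.env.data["temperature"].to_numpy()
    zT_cell = (temp - temp.mean()) / temp.std()
    coords = world.coords

    def lam_of_home(cell: int) -> float:
        return params.lam0 * math.exp(params.gamma_t * zT_cell[cell])

    def sample_home(region: int, parent_home: int | None) -> int:
        cells_r = world.cells_of_area(region)
        if parent_home is None:
            return int(cells_r[rng.integers(len(cells_r))])
        d2 = ((coords[cells_r] - coords[parent_home]) ** 2).sum(axis=1)
        w = np.exp(-d2 / (2.0 * params.home_sd ** 2))
        return int(cells_r[rng.choice(len(cells_r), p=w / w.sum())])

    ranges: dict[int, set[int]] = {}
    lam_sp: dict[int, float] = {}           # per-species rate (cell-grain mode)
    home_of: dict[tuple[int, int], int] = {}  # (species, region) -> patch centre
    lam_sum = np.zeros(A + 1)               # per-region occupant rate totals
    parent_sp: list[int] = []
    birth: list[float] = []
    death: list[float | None] = []
    origin_region: list[int] = []
    occ = _Occupants(A)
    # adjacent ordered area pairs (latitudinal bands)
    adj = [(r, r2) for r in range(1, A + 1) for r2 in (r - 1, r + 1) if 1 <= r2 <= A]
    lack = {p: 0 for p in adj}  # of occupants of p[0] lacking p[1]
    # colonization preference for productive destinations (niche-conservatism
    # style establishment bias; mean multiplier 1)
    znpp = (world.region_npp - world.region_npp.mean()) / world.region_npp.std()
    wdest = np.exp(params.dispersal_npp_bias * znpp)
    wdest /= wdest.mean()
    disp_w = np.array([params.dispersal * wdest[r2 - 1] for _, r2 in adj])

    def gain(sp: int, g: int, t: float, home: int | None = None) -> None:
        R = ranges[sp]
        for r2 in (g - 1, g + 1):
            if 1 <= r2 <= A and r2 not in R:
                lack[(g, r2)] += 1
        for r0 in R:
            if abs(r0 - g) == 1:
                lack[(r0, g)] -= 1
        R.add(g)
        occ.add(g, sp)
        acq[(sp, g)] = t
        home_of[(sp, g)] = home if home is not None else sample_home(g, None)
        lam_sum[g] += lam_sp.get(sp, 0.0)

    def lose(sp: int, l: int, t: float) -> None:
        R = ranges[sp]
        R.discard(l)
        for r2 in (l - 1, l + 1):
            if 1 <= r2 <= A and r2 not in R:
                lack[(l, r2)] -= 1
        for r0 in R:
            if abs(r0 - l) == 1:
                lack[(r0, l)] += 1
        occ.remove(l, sp)
        acq.pop((sp, l), None)
        home_of.pop((sp, l), None)
        lam_sum[l] -= lam_sp.get(sp, 0.0)

    acq: dict[tuple[int, int], float] = {}
    log: list[tuple] = []

    # random origin so colonization order is not confounded with the
    # environmental gradient across replicates
    start_region = int(rng.integers(A)) + 1
    ranges[0] = set()
    parent_sp.append(-1)
    birth.append(0.0)
    death.append(None)
    origin_region.append(start_region)
    home0 = sample_home(start_region, None)
    if params.cell_grain_rates:
        lam_sp[0] = lam_of_home(home0)
    gain(0, start_region, 0.0, home=home0)
    log.append(("origin", 0.0, 0, start_region))

    t = 0.0
    n_alive = 1
    for _ in range(max_events):
        N = np.array([occ.count(r) for r in range(1, A + 1)], dtype=float)
        lam_tot = lam_sum[1:].copy() if params.cell_grain_rates else lam * N
        mu_per = mu0 * N / K if dd else np.full(A, mu0)
        mu_tot = mu_per * N
        pressure = np.array([lack[p] for p in adj], dtype=float)
        if params.dispersal_saturation is not None:
            # establishment-limited colonization: propagule pressure saturates,
            # so regions are colonized as a steady wave rather than all at once
            pressure = np.minimum(pressure, params.dispersal_saturation)
        disp_tot = disp_w * pressure
        total = lam_tot.sum() + mu_tot.sum() + disp_tot.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= tau:
            break
        u = rng.uniform(0, total)
        kinds = np.concatenate([lam_tot, mu_tot, disp_tot])
        k = int(np.searchsorted(np.cumsum(kinds), u))
        if k < A:  # speciation in region k+1
            r = k + 1
            if params.cell_grain_rates:
                lst = occ.lists[r]
                w = np.array([lam_sp[s] for s in lst])
                par = lst[int(rng.choice(len(lst), p=w / w.sum()))]
            else:
                par = occ.sample(r, rng)
            sp = len(parent_sp)
            ranges[sp] = set()
            parent_sp.append(par)
            birth.append(t)
            death.append(None)
            origin_region.append(r)
            home = sample_home(r, home_of.get((par, r)))
            if params.cell_grain_rates:
                lam_sp[sp] = lam_of_home(home)
            gain(sp, r, t, home=home)
            n_alive += 1
            log.append(("speciation", t, par, sp, r))
            if n_alive > max_tips:
                raise CladeExtinctError(f"clade exceeded {max_tips} lineages")
        elif k < 2 * A:  # local extinction in region k-A+1
            r = k - A + 1
            sp = occ.sample(r, rng)
            lose(sp, r, t)
            log.append(("extirpation", t, sp, r))
            if not ranges[sp]:
                death[sp] = t
                n_alive -= 1
                if n_alive == 0:
                    raise CladeExtinctError("clade went extinct before the horizon")
        else:  # dispersal along pair adj[k - 2A]
            r, r2 = adj[k - 2 * A]
            cands = [s for s in occ.lists[r] if r2 not in ranges[s]]
            sp = cands[rng.integers(len(cands))]
            gain(sp, r2, t)
            log.append(("dispersal", t, sp, r2))
    else:
        raise RuntimeError("event cap reached; reduce rates or horizon")
    log.append(("end", tau))

    extant = [s for s in range(len(parent_sp)) if death[s] is None]
    if len(extant) < max(min_tips, 2):
        raise CladeExtinctError(f"only {len(extant)} extant lineages")
    phy = _reconstructed_tree(parent_sp, birth, death, tau)
    pam = _occupancy(world, extant, ranges, rng, params, home_of)
    true_arrival = {(f"sp{s}", r): max(tau - tt, 1e-12)
                    for (s, r), tt in acq.items() if death[s] is None}
    if params.cell_grain_rates:
        true_lam = {f"sp{s}": float(lam_sp[s]) for s in extant}
    else:
        true_lam = {f"sp{s}": float(lam[origin_region[s] - 1]) for s in extant}
    richness = np.array([occ.count(r) for r in range(1, A + 1)])
    return SimulatedClade(phy, pam, world.env, world, params, tau,
                          params.scenario, true_arrival, true_lam, richness, log)


def _reconstructed_tree(parent_sp, birth, death, tau) -> Phylogeny:
    """Ultrametric tree over extant lineages from the speciation records."""
    n = len(parent_sp)
    surviving = [death[s] is None for s in range(n)]
    kids: list[list[int]] = [[] for _ in range(n)]
    for s in range(n - 1, 0, -1):
        if surviving[s]:
            kids[parent_sp[s]].append(s)
            surviving[parent_sp[s]] = True
    for k in kids:
        k.sort(key=lambda s: birth[s])
    par, ln, lab = [], [], []

    def new_node(p, length, label):
        par.append(p)
        ln.append(length)
        lab.append(label)
        return len(par) - 1

    stack = [(0, -1, birth[0])]  # (species, parent node, attach time)
    while stack:
        s, pnode, t0 = stack.pop()
        cur, tcur = pnode, t0
        for c in kids[s]:
            nd = new_node(cur, birth[c] - tcur if cur >= 0 else np.nan, None)
            stack.append((c, nd, birth[c]))
            cur, tcur = nd, birth[c]
        if death[s] is None:
            new_node(cur, tau - tcur if cur >= 0 else np.nan, f"sp{s}")
    tips = {lab[i] for i in range(len(lab)) if lab[i] is not None}
    p2, l2, lab2, stem = _collapse(par, ln, lab, tips)
    return Phylogeny(p2, l2, lab2, root_length=0.0)


def _occupancy(world, extant, ranges, rng, params,
               home_of=None) -> PresenceAbsenceMatrix:
    """Cell occupancy: one patch per species per occupied region.

    Species ranges are much smaller than regions: within each occupied
    region a species covers only the cells within a Chebyshev radius of its
    home cell (radius drawn once per species), thinned per cell. With
    ``local_energy_occupancy`` the retention probability additionally scales
    with the cell's NPP relative to its region mean — local persistence
    tracking local energy availability, the stable-persistence mechanism at
    cell grain.
    """
    n_cells = len(world.cell_ids)
    npp = world.env.data["npp"].to_numpy()
    lat, lon = world.coords[:, 0], world.coords[:, 1]
    lo, hi = params.patch_radius
    mat = np.zeros((n_cells, len(extant)), dtype=np.uint8)
    for j, s in enumerate(extant):
        radius = int(rng.integers(lo, hi + 1))
        occupied = []
        for r in sorted(ranges[s]):
            cells_r = world.cells_of_area(r)
            home = None if home_of is None else home_of.get((s, r))
            if home is None:
                home = cells_r[rng.integers(len(cells_r))]
            patch = cells_r[(np.abs(lat[cells_r] - lat[home]) <= radius)
                            & (np.abs(lon[cells_r] - lon[home]) <= radius)]
            p = np.full(len(patch), params.thin)
            if params.local_energy_occupancy:
                local = npp[patch]
                p = np.clip(params.thin * local / max(local.mean(), 1e-9), 0.05, 1.0)
            keep = patch[rng.uniform(size=len(patch)) < p]
            if len(keep) == 0:
                keep = patch[[rng.integers(len(patch))]]
            occupied.append(keep)
        mat[np.concatenate(occupied), j] = 1
    return PresenceAbsenceMatrix(world.cell_ids, world.coords,
                                 [f"sp{s}" for s in extant], mat)


def replay_event_log(clade: SimulatedClade) -> tuple[dict[int, set[int]], int]:
    """Re-derive final ranges and extant count from the event log (consistency check)."""
    ranges: dict[int, set[int]] = {}
    alive: set[int] = set()
    for ev in clade.event_log:
        kind = ev[0]
        if kind == "origin":
            _, _, sp, r = ev
            ranges[sp] = {r}
            alive.add(sp)
        elif kind == "speciation":
            _, _, _, sp, r = ev
            ranges[sp] = {r}
            alive.add(sp)
        elif kind == "extirpation":
            _, _, sp, r = ev
            ranges[sp].discard(r)
            if not ranges[sp]:
                alive.discard(sp)
        elif kind == "dispersal":
            _, _, sp, r = ev
            ranges[sp].add(r)
    return {s: ranges[s] for s in alive}, len(alive)


# ---------------------------------------------------------------------------
# dataset export and the benchmark suite
# ---------------------------------------------------------------------------

def export_dataset(clade: SimulatedClade, directory) -> dict[str, str]:
    """Write tree.nwk / pam.csv / env.csv / truth.json, re-readable by core I/O."""
    os.makedirs(directory, exist_ok=True)
    paths = {k: os.path.join(directory, f) for k, f in
             (("tree", "tree.nwk"), ("pam", "pam.csv"),
              ("env", "env.csv"), ("truth", "truth.json"))}
    with open(paths["tree"], "w") as fh:
        fh.write(clade.phylogeny.to_newick() + "\n")
    clade.pam.to_csv(paths["pam"])
    clade.env.to_csv(paths["env"])
    truth = {
        "scenario": clade.scenario,
        "tau": clade.tau,
        "region_richness": clade.region_richness.tolist(),
        "tip_lambda": clade.true_tip_lambda,
        "arrival": {f"{sp}|{r}": v for (sp, r), v in clade.true_arrival.items()},
        "params": {k: v for k, v in asdict(clade.params).items()},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


def simulate_clade_surviving(world_config: WorldConfig, params: ScenarioParams,
                             min_tips: int = 40, max_tips: int = 1500,
                             max_tries: int = 25) -> SimulatedClade:
    """Simulate until the clade survives with a workable size, varying the seed."""
    for i in range(max_tries):
        cfg = WorldConfig(**{**asdict(world_config),
                             "seed": (world_config.seed + 7919 * i) % 2**31})
        world = make_world(cfg)
        p = ScenarioParams(**{**asdict(params),
                              "seed": (params.seed + 104729 * i) % 2**31})
        try:
            return simulate_clade(world, p, min_tips=min_tips, max_tips=max_tips)
        except CladeExtinctError:
            continue
    raise CladeExtinctError(f"no surviving clade in {max_tries} tries")


def benchmark_suite(n_per_scenario: int, seed: int,
                    world_config: WorldConfig | None = None):
    """Deterministic collection of clades, ``n_per_scenario`` per scenario.

    Returns ``(clades, manifest)`` where the manifest maps each dataset to
    its ground truth (scenario, seeds, size).
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    base = world_config or WorldConfig(cols=10)  # desk-scale default
    clades, manifest = [], []
    for si, scen in enumerate(SCENARIOS):
        for i in range(n_per_scenario):
            ds_seed = int((seed * 1_000_003 + si * 10_007 + i * 101) % 2**31)
            wc = WorldConfig(**{**asdict(base), "seed": ds_seed})
            params = default_scenario_params(scen, seed=ds_seed + 1)
            clade = simulate_clade_surviving(wc, params)
            clades.append(clade)
            manifest.append({
                "index": len(clades) - 1, "scenario": scen, "seed": ds_seed,
                "n_tips": clade.phylogeny.n_tips,
                "region_richness": clade.region_richness.tolist(),
            })
    return clades, manifest
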