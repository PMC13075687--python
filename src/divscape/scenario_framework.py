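"""Scenario-specific path models, AIC/BIC selection, and clade-trait regressions.

Four richness-generating scenarios are encoded as reduced path models over
{temperature, precipitation, npp, age, dr, lnS}:

* stable persistence — an equilibrium maintained by energy availability:
  productivity carries the effect on richness;
* speciation balance — an equilibrium whose level is set by spatial
  variation in speciation rates: climate acts on richness via DR;
* historical legacy — richness out of equilibrium, tracking the time since
  regional colonization: environment acts via assemblage age;
* cradles of diversity — nonequilibrium richness driven by speciation rates,
  with available time also contributing (age and DR enter additively on the
  log scale, the covariance-model linearization of a rate x time product).

Every reduced model is fit over all six variables (variables with no
incoming edge become exogenous with a saturated covariance block) so that
AIC/BIC are computed on identical data and are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import clade_delineation, dec_ranges, evoregions, tip_rates
from .core import EnvironmentTable, Phylogeny, PresenceAbsenceMatrix, crown_age, richness_per_cell
from .path_models import (RESPONSE, FitResult, PathModel, VariableTable,
                          effect_decomposition, fit_path_model,
                          prepare_variables)

VARIABLES = ("temperature", "precipitation", "npp", "age", "dr", RESPONSE)

#: fixed tie-break order
SCENARIO_NAMES = ("stable_persistence", "speciation_balance",
                  "historical_legacy", "cradles_of_diversity")

_CLIMATE_TO_NPP = (("temperature", "npp"), ("precipitation", "npp"))


def full_model() -> PathModel:
    """The integrative model: climate -> NPP; climate & NPP -> age and DR;
    all five predictors -> lnS (13 edges)."""
    edges = list(_CLIMATE_TO_NPP)
    for med in ("age", "dr"):
        edges += [("temperature", med), ("precipitation", med), ("npp", med)]
    edges += [(v, RESPONSE) for v in ("temperature", "precipitation", "npp", "age", "dr")]
    return PathModel(VARIABLES, tuple(edges))


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    model: PathModel


#: richness-equation parents per scenario
_LNS_PARENTS = {
    "stable_persistence": ("npp",),
    "speciation_balance": ("dr",),
    "historical_legacy": ("age",),
    "cradles_of_diversity": ("dr", "age"),
}


def scenario_models(style: str = "shared_upstream") -> tuple[ScenarioSpec, ...]:
    """The four reduced models, each retaining only its dominant pathways.

    ``style='shared_upstream'`` (default, used for model selection): all four
    models share the upstream environmental structure (climate -> NPP;
    climate & NPP -> age and DR) and differ only in which mediators feed the
    richness equation — the scenario-diagnostic pathways. Comparing models
    that differ only in the lnS equation keeps the information criteria
    focused on the scenarios' actual claims.

    ``style='minimal'``: the bare dominant-pathway DAGs (climate -> NPP plus
    each scenario's mediator chain), with unused variables exogenous. These
    are the smallest DAGs realizing each scenario's predictions, but their
    free exogenous blocks let structured nuisance fields ride along for
    free, which degrades selection; they are kept for sensitivity analyses.
    """
    if style == "shared_upstream":
        common = _CLIMATE_TO_NPP + tuple(
            (src, med) for med in ("age", "dr")
            for src in ("temperature", "precipitation", "npp"))
        edge_sets = {n: common + tuple((v, RESPONSE) for v in vs)
                     for n, vs in _LNS_PARENTS.items()}
    elif style == "minimal":
        sp = _CLIMATE_TO_NPP + (("npp", RESPONSE),)
        sb = _CLIMATE_TO_NPP + (("temperature", "dr"), ("precipitation", "dr"),
                                ("npp", "dr"), ("dr", RESPONSE))
        hl = _CLIMATE_TO_NPP + (("temperature", "age"), ("precipitation", "age"),
                                ("npp", "age"), ("age", RESPONSE))
        cr = sb + (("age", RESPONSE),)
        edge_sets = {"stable_persistence": sp, "speciation_balance": sb,
                     "historical_legacy": hl, "cradles_of_diversity": cr}
    else:
        raise ValueError(f"unknown style {style!r}")
    return tuple(ScenarioSpec(n, PathModel(VARIABLES, edge_sets[n]))
                 for n in SCENARIO_NAMES)


@dataclass
class ScenarioSupport:
    """Per-clade information-criterion comparison of the four scenarios."""

    aic: dict[str, float]
    bic: dict[str, float]
    winner_aic: str
    winner_bic: str
    fits: dict[str, FitResult] = field(default_factory=dict, repr=False)

    def delta(self, criterion: str = "aic") -> dict[str, float]:
        vals = getattr(self, criterion)
        best = min(vals.values())
        return {k: v - best for k, v in vals.items()}


def _pick_winner(values: dict[str, float], specs) -> str:
    nparams = {s.name: s.model.n_free_parameters() for s in specs}
    order = {n: i for i, n in enumerate(SCENARIO_NAMES)}
    return min(values, key=lambda n: (values[n], nparams[n], order[n]))


def select_scenario(table: VariableTable, style: str = "shared_upstream") -> ScenarioSupport:
    """Fit the four reduced models and pick the lowest-AIC / lowest-BIC scenario.

    Ties break by fewer free parameters, then by the fixed scenario order.
    A scenario whose model cannot be fit is excluded with a warning.
    """
    specs = scenario_models(style)
    aic, bic, fits = {}, {}, {}
    for spec in specs:
        try:
            fit = fit_path_model(spec.model, table)
        except Exception as exc:  # noqa: BLE001 - surfaced as a warning per contract
            warnings.warn(f"scenario {spec.name} unfittable: {exc}")
            continue
        aic[spec.name] = fit.aic
        bic[spec.name] = fit.bic
        fits[spec.name] = fit
    if not aic:
        raise RuntimeError("no scenario model could be fitted")
    return ScenarioSupport(aic, bic, _pick_winner(aic, specs),
                           _pick_winner(bic, specs), fits)


def tally_support(supports) -> pd.DataFrame:
    """Winner proportions per scenario, by AIC and by BIC side by side."""
    supports = list(supports)
    if not supports:
        raise ValueError("need at least one clade")
    rows = {}
    for crit in ("aic", "bic"):
        winners = [getattr(s, f"winner_{crit}") for s in supports]
        rows[crit] = {n: winners.count(n) / len(winners) for n in SCENARIO_NAMES}
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clade-trait regressions
# ---------------------------------------------------------------------------

@dataclass
class TraitEffectRegression:
    trait: str
    effect: str
    slope: float
    intercept: float
    p_value: float
    r2: float
    n: int


def clade_trait_effects(effects: pd.DataFrame, traits: pd.DataFrame) -> list[TraitEffectRegression]:
    """OLS of each direct-effect column on each clade trait (rows = clades).

    Traits are expected to include crown age, physiology (0/1), diversity
    and geographic extent, but any numeric columns are accepted.
    """
    common = effects.index.intersection(traits.index)
    if len(common) < 3:
        raise ValueError("need at least 3 clades")
    out = []
    for trait in traits.columns:
        x = traits.loc[common, trait].astype(float)
        if x.nunique() < 2:
            raise ValueError(f"constant trait {trait!r}")
        for eff in effects.columns:
            y = effects.loc[common, eff].astype(float)
            res = stats.linregress(x, y)
            out.append(TraitEffectRegression(trait, eff, float(res.slope),
                                             float(res.intercept),
                                             float(res.pvalue),
                                             float(res.rvalue ** 2), len(common)))
    return out


# ---------------------------------------------------------------------------
# end-to-end per-clade pipeline
# ---------------------------------------------------------------------------

@dataclass
class CladeAnalysis:
    """Everything the per-clade pipeline computes for one clade."""

    table: VariableTable
    full_fit: FitResult
    support: ScenarioSupport
    evomap: evoregions.EvoregionMap
    dec_fit: dec_ranges.DECFit
    assemblage_age: pd.Series
    cell_dr: pd.Series
    crown_age: float
    n_species: int
    extent: int

    @property
    def direct_effects(self) -> dict[str, float]:
        dec_ = effect_decomposition(self.full_fit)
        return dec_.direct


def analyze_clade(phy: Phylogeny, pam: PresenceAbsenceMatrix, env: EnvironmentTable,
                  seed: int = 0, kmax: int = 6, min_cells: int = 30,
                  include_coords: bool = False) -> CladeAnalysis:
    """Run the full pipeline for one clade.

    Steps: evoregions from phylogenetic turnover; species area sets; DEC fit
    and marginal ancestral ranges; arrival times and cell assemblage ages;
    DR tip rates and cell medians; variable table; integrative-model fit and
    scenario selection.
    """
    D = clade_delineation.patristic_matrix(phy)
    evomap = evoregions.delineate_evoregions(pam, D, phy.tip_labels,
                                             kmax=kmax, seed=seed)
    areas = evoregions.species_area_sets(evomap, pam)
    space = dec_ranges.build_state_space(evomap.n_regions)
    dec_fit = dec_ranges.fit_dec(phy, areas, space=space)
    recon = dec_ranges.ancestral_ranges(phy, areas, dec_fit.params, space=space)
    arrivals = dec_ranges.build_arrival_table(recon, phy, areas)
    ages = dec_ranges.assemblage_ages(arrivals, pam, evomap)
    rates = tip_rates.dr_statistic(phy)
    cell_dr = tip_rates.cell_median_rate(pam, rates)
    richness = richness_per_cell(pam)
    env_df = env.data.copy()
    if include_coords and "lat" not in env_df.columns:
        env_df["lat"] = pd.Series(pam.coords[:, 0], index=pam.cell_ids)
        env_df["lon"] = pd.Series(pam.coords[:, 1], index=pam.cell_ids)
    table = prepare_variables(richness, env_df, ages, cell_dr,
                              min_cells=min_cells, include_coords=include_coords)
    model = full_model()
    if include_coords:
        model = model.with_spatial_covariates()
    fit = fit_path_model(model, table)
    support = select_scenario(table)
    return CladeAnalysis(
        table=table, full_fit=fit, support=support, evomap=evomap,
        dec_fit=dec_fit, assemblage_age=ages, cell_dr=cell_dr,
        crown_age=crown_age(phy), n_species=phy.n_tips,
        extent=int((pam.matrix.sum(axis=1) > 0).sum()),
    )
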