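# Methods

`divscape` decides which of four richness-generating scenarios best explains
the spatial richness pattern of a clade, given a time-calibrated phylogeny,
a gridded presence–absence matrix (PAM), and per-cell environmental data
(temperature, precipitation, net primary productivity). This note documents
the models, the estimators, the synthetic worlds used to validate them, and
the design choices that were genuinely open.

## The four scenarios

Two axes classify richness-generating hypotheses: whether richness sits at a
speciation–extinction equilibrium, and whether spatial richness variation is
driven by speciation rates.

| scenario | equilibrium | speciation-driven | diagnostic pathway |
|---|---|---|---|
| stable persistence | yes | no | NPP → lnS |
| speciation balance | yes | yes | climate → DR → lnS |
| historical legacy | no | no | environment → age → lnS |
| cradles of diversity | no | yes | DR → lnS and age → lnS |

`lnS` is log richness per grid cell, `age` the assemblage age (mean lineage
arrival time), and `DR` the median tip speciation rate of co-occurring
species.

## Pipeline stages

**Clade delineation.** Tips are clustered on the spectrum of the graph
Laplacian `L = D − A` of the dense patristic-distance graph over tips
(`A` = patristic distances, `D` = diagonal row sums). k-means (default
k = 50 modalities, 25 restarts, fixed seed; 40/60 as sensitivity settings)
runs on the eigenvectors of the k largest eigenvalues, scaled by their
eigenvalues so directions carrying more of the spectrum dominate; deep
splits of the tree concentrate there. Modalities with fewer than 50 tips
are dropped, and each retained clade is flagged paraphyletic when its tip
set differs from its MRCA's full tip set. The tips-only graph and the
top-spectrum embedding are deliberate, isolated choices: clade membership
is a property of tips, and for distance-weighted Laplacians the separation
structure sits at the top of the spectrum (similarity-weighted variants put
it at the bottom).

**Evoregions.** Per clade, cells are described by a phylogenetic
fuzzy-weighted composition (occupancy smeared over relatives via
`S = 1 − d/max d`, rows normalized), ordinated by PCoA of Bray–Curtis
dissimilarities (axes retained while each explains ≥ 5% of the
positive-eigenvalue variance), and clustered by k-means with K = 2..kmax
chosen by mean silhouette width (kmax = 10, pipeline default 6 — the DEC
state space grows as 2^K). Occupied regions per species become the tip
"areas" of the range-evolution model.

**DEC ancestral ranges.** The dispersal–extinction–cladogenesis model:
along a branch a range `R` gains an adjacent-free area at rate `d·|R|` and
loses an occupied area at rate `e` (singletons collapse to an absorbing
null); at speciation the parental range is partitioned into equally
weighted vicariance (one area vs the rest, both orders) or subset-sympatry
(full range plus one area) outcomes. Likelihood is computed by pruning with
per-node rescaling; branch propagators use an eigendecomposition of the
generator with an `expm` fallback. The root is averaged uniformly over
non-null states (an isolated flag; conditioning conventions differ across
implementations). ML fitting maximizes over `(log d, log e)` with bounded
L-BFGS-B from three starts plus a Nelder–Mead polish. Marginal ancestral
ranges come from standard up/down passes, verified against exhaustive
state-history enumeration on small trees.

**Arrival times and assemblage age.** For a species present in a region,
the arrival time is the age of the deepest ancestral node whose
most-probable (argmax) range contains the region along an *uninterrupted*
chain from the tip's parent; continuity prevents a region lost and regained
deep in the tree from inflating arrival ages (a switch restores the
"deepest occupied node anywhere" reading). A species whose immediate
ancestor lacked the region is a post-speciation disperser and receives the
10-year floor (1e-5 Ma; branch lengths are Ma throughout). Assemblage age
per cell is the mean arrival time of the species present, each evaluated
for the cell's evoregion.

**Tip rates.** The DR statistic: with root-to-tip edges e_1 (pendant) …
e_N, `ES = Σ len(e_j)·2^−(j−1)` and `DR = 1/ES`. Cells are summarized by
the median DR of co-occurring species (even counts: midpoint). On Yule
trees the *harmonic* mean of DR calibrates to the birth rate within a few
percent; the arithmetic mean overshoots by ~40%, a known bias, so the
calibration property is stated (and tested) for the harmonic mean.

**Path models.** All variables observed; for recursive DAGs with
uncorrelated errors, equation-wise least squares is the ML solution. All
variables are standardized internally, so coefficients are standardized
path coefficients. The implied covariance is
`Σ(θ) = (I−B)^−1 Ψ (I−B)^−T` with Ψ holding endogenous residual variances
and the saturated sample covariance of the exogenous block. Discrepancy
`T = (n−1)·F_ML`; CFI/TLI/RMSEA from `T` against the independence
baseline; SRMR over standardized residual covariances including the
diagonal; `AIC = −2logL + 2q`, `BIC = −2logL + q ln n` with `q` counting
free coefficients, residual variances and exogenous (co)variances. Indirect
effects are path products; each indirect path is classified by the mediator
whose edge enters lnS, so the three classes (via productivity, via time,
via speciation) partition `total − direct` exactly. Diagnostics: VIF per
predictor and Moran's I on equation residuals (default weights:
row-standardized 8-nearest-neighbour; rook adjacency available). A spatial
sensitivity refit adds latitude and longitude as exogenous parents of every
endogenous variable.

**Scenario selection.** Four reduced models are compared by AIC and BIC,
fitted over all six variables so the criteria are computed on identical
data. The default family shares the upstream structure (climate → NPP;
climate & NPP → age and DR) across all four models and differs *only in
the richness equation* (NPP / DR / age / DR+age). The alternative
`style="minimal"` family keeps only each scenario's dominant-pathway DAG
with remaining variables exogenous; it is retained for sensitivity
analyses, but the free exogenous covariance blocks let structured nuisance
fields ride along at zero discrepancy cost, which empirically collapses
selection toward the most exogenous-rich model — hence the shared-upstream
default. Ties break by fewer free parameters, then by a fixed scenario
order.

## Synthetic worlds

The generator emulates the statistical structure of gridded macroecological
data without external downloads. A world is a hemispheric lattice (default
24 × 18 cells for general use; the benchmark uses 24 × 10) with: a linear
poleward temperature decline (1.5 °C per row, σ = 1 noise), a
Gaussian-filtered random precipitation field (mean 1200 mm/yr, σ = 500,
smoothness 2 cells), an NPP field `npp = 4 + z(T) + z(P) + ε` truncated at
zero, and 6 contiguous latitudinal bands as biogeographic areas.

Clades grow by a Gillespie birth–death–dispersal process over areas from a
single lineage in a *random* area (a random origin keeps colonization order
unconfounded with the environmental gradient across replicates). Diversity
dependence acts on extinction only: `μ(region) = μ0·N/K`. Per scenario:

- **stable persistence** — λ constant (0.5/Ma), μ0 = 0.4, K ∝ regional
  mean NPP (10 species per NPP unit), dispersal 0.3, horizon τ = 25/μ0;
  cell occupancy weighted by local NPP (the scenario's mechanism at cell
  grain).
- **speciation balance** — common K; each species carries a heritable home
  cell whose temperature sets its rate, `λ_s = 0.4·exp(1.3·z_T(home))`,
  daughters' homes dispersed around the parent's (σ = 2.5 cells);
  dispersal 0.15, τ = 25/μ0.
- **historical legacy** — constant λ = 0.35, μ0 = 0.05; colonization is
  establishment-limited (propagule pressure saturates at 2 lineages ×
  rate 0.25), producing a steady colonization wave and staggered regional
  ages; τ = 5.5/(λ−μ0).
- **cradles of diversity** — cell-grain temperature-dependent rates
  (λ0 = 0.35, γ = 0.8) plus the colonization wave; μ0 = 0.05,
  τ = 5.5/max net diversification.

Speciation is within-region (the daughter starts where the event fired;
the parent keeps its range); range-splitting cladogenesis is *not*
simulated — DEC is an inference model here, not the generative truth, and
the mismatch deliberately tests inference robustness. Each species
occupies one random patch (Chebyshev radius 2–5 cells, thinned at 0.9) per
occupied region, so fields vary at cell grain rather than as regional step
functions. The reconstructed tree over extant lineages is assembled from
the event log and is exactly ultrametric; the log supports replay checks
and time-averaged richness trajectories.

Defaults were calibrated once so that the four scenarios are statistically
distinguishable at desk scale (a few hundred species, ~200 cells); the
nonequilibrium horizon 5.5 net-diversification times yields a few hundred
extant species (a shorter horizon leaves clades with a handful of tips,
unusable for any spatial statistics).

What the generator does *not* emulate: continuous range dynamics within
regions, trait or niche evolution, heritable rate shifts beyond the
home-cell rule, climate change through time, and observational error in
range maps. Passing tests therefore show that the pipeline recovers known
dynamics of this world family, not that real tetrapod data meet the same
assumptions.

## Known limitations

- **DEC extinction rate.** On survival-conditioned extant-clade data the
  ML estimate of `e` collapses toward zero: cladogenetic subdivision
  explains small ranges without anagenetic loss, and conditioning on
  survival removes most of the remaining contraction signal. Dispersal `d`
  recovers with ~10–20% median error under the same conditions. Empirical
  DEC fits show the same `ê ≈ 0` behaviour; arrival times depend mostly on
  reconstruction topology and are robust to it.
- **Assemblage-age circularity.** Marginal reconstructions favour placing
  ancestors in species-rich regions (a majority-vote effect), so the
  measured age field carries some information about regional richness
  noise in *every* world. In model selection this systematically benefits
  the one scenario whose richness equation has two mediators (cradles of
  diversity); with the shared-upstream family and cell-grain worlds the
  stable-persistence and cradles scenarios recover reliably, while
  historical-legacy worlds are claimed by cradles in roughly half of
  replicates. This is a property of the age metric, not of the fitting
  code, and is worth bearing in mind when interpreting empirical
  assemblage-age effects.
- Moran's I weights, the evoregion ordination/selection recipe, and the
  reduced-model families are documented substitutes where the upstream
  literature does not pin down a unique construction; each sits behind one
  function or flag so alternatives can be swapped.

## Numerical conventions

Ultrametricity tolerance 1e-6 (relative tip-depth spread); arrival floor
1e-5 Ma; DEC rate bounds [1e-4, 50] /Ma on the log scale; marginals and
partial likelihoods rescaled per node; k-means n_init 25 (delineation) /
10 (evoregions) with fixed seeds; zero-richness cells are dropped before
the log transform; variable tables require ≥ 30 cells.
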