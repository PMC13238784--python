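# Methods

`forestdiv` implements a complete plot-based analysis of how functional
identity, functional diversity and phylogenetic diversity relate to forest
aboveground biomass (AGB) in two tree strata, together with a synthetic
community generator that makes every stage testable against known ground
truth. This note records the models, the defaults and why, the numerical
choices, and the limits of what the synthetic tests demonstrate.

## Biomass and strata

Per-stem biomass follows the power-law allometry

    W = a (D² H)^b        [kg; D in cm, H in m]

with species-specific coefficients where available and a general fallback
otherwise. The compound form — the exponent spanning D²H — is the default
because it is the internally consistent reading of the family of equations
the coefficients come from; a per-entry `form="split"` flag switches an
entry to `W = a D² H^b` where a source prints that form. Coefficients are
config data, not constants: the shipped example table carries a
*Castanopsis* entry (a = 0.03086, b = 0.9696) and a placeholder general
model (a = 0.06, b = 0.95); real analyses must supply their own table. W
is taken to be kg per stem; the historical sources of such coefficients do
not always state units, so this assumption is explicit here and in the
coefficient-table docs.

Stems partition into overstory (DBH ≥ 9 cm; the boundary value is
overstory) and understory (1 cm ≤ DBH < 9 cm; below 1 cm is not censused).
Plot totals convert as `kg / 1000 × (10 000 / plot_area)` → Mg/ha, i.e. a
factor 25 for the 400 m² default plots. Stratum AGBs are additive: they
sum exactly to the whole-plot value.

## Abundance

Relative abundance w_i is the species' share of stems in the plot
(`basis="stem_count"`), with basal area (π(D/2)²) as an option. Stem count
is the default because "abundance" in the trait-diversity literature this
follows conventionally means individuals; the choice is config-exposed
since nothing in the data forbids the other reading.

## Functional metrics

Five leaf traits: SLA (mm²/mg) and leaf N, P, K, C concentration (mg/g).

* **CWM** per trait: Σ w_i·trait_i on the raw trait scale.
* **FDis**: traits are z-scored over the stratum's species pool, the
  community centroid is c = Σ w_i x_i, and FDis = Σ w_i‖x_i − c‖. The
  z-scoring (pool mean 0, sd 1, ddof = 1) keeps any single trait from
  dominating by unit choice and makes FDis/FRic invariant to unit changes.
* **FRic**: the convex-hull volume of the community's species in the
  standardized 5-D trait space divided by the pool's hull volume, so
  FRic ∈ [0, 1] and is comparable across plots. It is presence-based.
  Communities with fewer than 6 species (T+1 points in T = 5 dimensions)
  or an affinely degenerate point set get FRic = 0 plus a
  `FRic_flag="degenerate"` marker rather than an error — small plots are
  data, not bugs.
* **FDiv** (classically the log-variance index FDvar): per trait,
  V_t = Σ_i A_i (ln C_it − ln x̄_t)² with ln x̄_t = Σ_i A_i ln C_it; the
  per-trait score is (2/π)·arctan(5 V_t) and FDiv is their mean across
  the five traits. Traits must be strictly positive; a non-positive value
  is an error, never silently shifted.

No PCA reduction of the trait space is applied before FDis/FRic; all five
standardized traits enter directly.

## Phylogenetic metrics

From a rooted tree with branch lengths, the patristic matrix d(s_i, s_j)
is the sum of branch lengths along each tip pair's path. Per community
(presence-based, exactly as the classical formulas — no abundance
weighting):

* MPD = [2/(n(n−1))] Σ_{i<j} d(s_i, s_j)
* MNTD = (1/n) Σ_i min_{j≠i} d(s_i, s_j)
* PSV = 1 − mean off-diagonal of the phylogenetic correlation matrix C;
  PSR = n·PSV.

C_ij is the shared root-to-MRCA path length divided by the geometric mean
of the two root-to-tip depths. The shared depth is computed as
(depth_i + depth_j − d_ij)/2, which is exact on any tree by path
additivity; on ultrametric trees this reduces to the standard shared
branch-length fraction, and on non-ultrametric trees it stays in [0, 1].
Communities with n < 2 have no pairwise structure: their metrics are NaN
with a `singleton` flag rather than zero, so downstream models cannot
silently absorb them.

Strata can be analyzed against separate per-stratum trees or against one
pool tree. `Phylogeny.subset` prunes without suppressing unifurcations, so
root-to-tip paths — and therefore the patristic matrix, depths and PSV —
are identical between the two modes.

## Environmental axes

Two separate correlation-matrix PCAs (variables z-scored first: the units
mix m, °, g/kg and pH) reduce the topographic (elevation, slope, aspect)
and edaphic (pH, SOM, TN, TP, TK, AN, AP, AK, AB) tables to Topo_PC1/2 and
Soil_PC1/2 scores. Aspect is circular and enters as sin/cos by default
(raw degrees as a fallback). Each component is oriented so its
largest-magnitude loading is positive, which fixes the eigenvector sign
ambiguity and makes reports reproducible. A constant column is an error —
it cannot be standardized and usually signals an upstream data problem.

## PLS, VIP and shaving

Per stratum, the candidate matrix has 15 columns — 5 CWMs, FDis, FRic,
FDiv, MPD, MNTD, PSR, Soil_PC1/2, Topo_PC1/2 — and the response is the
stratum's plot AGB. Single-response PLS is fit by NIPALS deflation on
z-standardized X and y; with A = rank(X) components it reproduces OLS,
which the tests assert. VIP for predictor j is

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),

SSY_a the response sum of squares captured by component a, so
Σ_j VIP_j² = p identically.

Variable selection is backward "shaving": each round chooses the component
count (≤ 5) by K-fold cross-validated RMSEP (K = 10, folds drawn once from
the seed), fits, and drops the 20% of predictors with the lowest VIP (at
least one, never the last one); the visited subset with minimal CV RMSEP
wins and the final model is refit on it. All of K, the step fraction, the
component cap and the seed are config keys. This is one transparent,
deterministic procedure in the spirit of the plsVarSel/plsdepot workflow;
reproducing any particular R package's internals is a non-goal, so exact
numeric VIPs from studies that used those packages are not expected to be
reproduced — only the qualitative selection behaviour.

VIP bands: > 1 major, (0.8, 1] medium, ≤ 0.8 negligible. The sources that
define the bands leave the boundary values ambiguous ("VIP > 1", "between
1 and 0.8"); the half-open convention is fixed here and values exactly at
a boundary are flagged in the output.

Bivariate OLS fits of AGB on each predictor that survives shaving (slope,
intercept, R² = squared Pearson r, two-sided p from the slope t with n−2
df) round out the report. P-values are reported unadjusted, matching the
descriptive role they play; the report header carries a multiplicity note.

## Synthetic communities

The generator emulates a 30-plot (20 m × 20 m) montane evergreen
broadleaf census along a 2450–2650 m gradient:

* **Phylogeny**: Yule tree (birth rate 1.0) over a 60-species pool, grown
  to n tips and then observed an Exp(n·b)-distributed time after the last
  split so terminal branches are never zero.
* **Traits**: each trait's latent value is λ·(Brownian motion on the
  tree) + (1−λ)·independent noise (λ = 0.5 by default), mapped through
  exp(μ_t + s_t z) to strictly positive lognormal values around realistic
  leaf-trait magnitudes (SLA ≈ 12 mm²/mg, N ≈ 20, P ≈ 1.5, K ≈ 8,
  C ≈ 460 mg/g).
* **Composition**: overstory and understory draw 48 and 44 species
  independently from the pool; per plot, abundances are
  Dirichlet(concentration × lognormal pool unevenness) and stems are
  multinomial (overstory ≈ 45 stems/plot, understory ≈ 150).
* **Sizes**: DBH from stratum-specific truncated lognormals (overstory
  median 20 cm on [9, 100); understory median 3 cm on [1, 9)); heights
  H = 2.5·D^0.55·e^ε with lognormal ε (sd 0.15), giving ~24 m at
  D = 60 cm. With the default general allometry these produce overstory
  plot AGB of a few hundred Mg/ha and understory AGB of roughly ten —
  the magnitudes typical of dense old-growth subtropical stands.
* **Environment**: elevation/slope/aspect uniform over the study ranges;
  the nine soil variables load on two latent factors (a fertility axis
  for SOM/TN/TP/TK/AN/AK and a second axis for pH/AP/AB), giving a
  realistic two-component correlation structure. The environment is
  generated independently of the communities.
* **Planted effects**: per stratum, a named-predictor effect vector β
  defines target plot AGB = mean(AGB)·exp(s·(Σ β_k z_k + ε)), with z_k
  the standardized predictor computed from the generated community by the
  package's own metric code, ε Gaussian with sd 25% of the signal sd, and
  s = 0.35 the relative AGB swing per signal sd (chosen so the simulated
  coefficient of variation of plot AGB matches what mature forest plots
  show, ≈ 0.4). The exponential link keeps targets strictly positive —
  a literal linear model goes negative in a few percent of datasets at
  these effect sizes — and is indistinguishable from linear over the
  realized ±2 sd range. Plots are then pulled to their targets by
  replicating or thinning stems: a mass-matched greedy subset (plus one
  Bernoulli stem for the remainder) so the realized biomass lands within
  about one small stem of the target, and never removing a species' last
  stem so presence-based predictors are exactly invariant under the
  rescaling. Defaults plant CWM_SLA (+) and MPD (+) on overstory AGB and
  PSR (+) / CWM_SLA (−) on understory AGB, mirroring the contrast between
  acquisitive overstory and conservative understory strategies this kind
  of study reports.

Everything is deterministic under the config seed, including the
dendropy tree simulation (driven by a seeded `random.Random`).

### What the generator does not emulate

No spatial stem mapping, no environmental niche sorting (composition is
independent of the environment tables, so environment axes are exactly
null predictors unless planted), no succession, no intraspecific trait
variation, no measurement error on DBH/height or traits, and the planted
effect operates at plot level through stem counts rather than through
individual growth. Passing recovery tests therefore demonstrate that the
statistical machinery finds drivers that are present by construction under
realistic noise and collinearity — not that the same drivers operate in
any real forest.

## Validation experiments

`planted_recovery_experiment` regenerates 100 independent studies (strong
planted effects, β = 1 on CWM_SLA and MPD for overstory AGB), appends a
pure-noise predictor to each candidate matrix, and measures: how often
shaving retains both planted drivers; how often both get VIP > 1 in the
full candidate model (2 components — the full-model VIP is the
appropriate scale for "does this predictor stand out among all
candidates", since in a final model shaved down to exactly the two drivers
Σ VIP² = 2 forces one of them below 1 by construction); and how often the
noise predictor reaches VIP > 1. The acceptance thresholds are ≥ 90%,
≥ 90% and ≤ 15%.

Problem sizes throughout the test-suite oracles (200 random communities
for the brute-force metric checks, 5000 Brownian draws for the PSV
statistical oracle, 100 replicate studies for recovery) were chosen as the
smallest sizes at which the Monte-Carlo error is comfortably inside each
check's tolerance.

## Numerical choices and degenerate inputs

* Convex hulls via Qhull; a `QhullError` on a community is the degenerate
  case above, while a degenerate *pool* is a hard error.
* The Brownian covariance Cholesky adds 1e-10·t̄ jitter for tips whose
  shared depth makes the matrix numerically semidefinite.
* PLS deflation stops with an error if a component's weight norm falls
  below 1e-14 (X carries no covariance with y) or if the request exceeds
  rank(X).
* Name matching trims, collapses internal whitespace and case-folds —
  nothing fuzzier; taxonomy mismatches must be resolved explicitly (the
  pipeline aborts listing them, or drops them consistently from all
  structures when `drop_unmatched_species=True`).
* Missing branch lengths are an error by default (`'zero'` opt-in), since
  every path-length quantity depends on them.
* CSV/TSV delimiters are sniffed from the header and overridable.

## Known limitations

* FRic in 5-D needs ≥ 6 affinely independent species; small communities
  carry flags and FRic = 0, which biases FRic low in very sparse plots.
* The shared-depth PSV generalization to non-ultrametric trees is one of
  several reasonable conventions; on ultrametric trees (including all
  simulated ones) it is exact.
* The shaving path depends on the CV fold draw; different seeds can
  select different near-optimal subsets when predictors are highly
  collinear. The seed is part of the config and recorded in the manifest.
* Real coefficient tables, not the shipped placeholders, are required for
  defensible absolute AGB levels on field data.
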