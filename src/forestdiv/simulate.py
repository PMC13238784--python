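"""Synthetic forest communities with known ground truth.

Emulates the study design the pipeline targets: 30 plots of 20 m x 20 m
along a montane gradient, a ~60-species pool from which the overstory
(DBH >= 9 cm, ~48 species) and understory (~44 species) draw independently,
five lognormal leaf traits evolved on a Yule phylogeny with tunable
phylogenetic signal, stem sizes from stratum-specific truncated lognormals,
heights from H = h1 * D^h2 * exp(eps), and per-stem biomass from the
configured allometry. Plot-level AGB is then pulled toward a planted
log-linear model AGB ~ exp(beta . (named predictors) + noise) by rescaling
stem counts, so the true drivers of every synthetic dataset are known
exactly (the exponential link keeps planted AGB positive and is close to
linear at the default effect size).

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from . import allometry as _allometry
from .community import abundance_matrix
from .env_pca import env_scores
from .functional import functional_profile
from .io import (
    AllometricEntry,
    AllometricModel,
    EnvironmentTable,
    Phylogeny,
    PlotInventory,
    SOIL_VARS,
    TRAIT_NAMES,
    TraitTable,
    TreeRecord,
)
from .phylo import patristic_matrix, phylo_profile


class GenerationError(RuntimeError):
    """The requested synthetic conditions are infeasible."""


#: Log-scale location and spread per trait: SLA ~ 12 mm^2/mg, leaf N ~ 20,
#: P ~ 1.5, K ~ 8, C ~ 460 mg/g, with spreads typical of woody floras.
TRAIT_LOG_MEAN = {"SLA": np.log(12.0), "LN": np.log(20.0), "LP": np.log(1.5),
                  "LK": np.log(8.0), "LC": np.log(460.0)}
TRAIT_LOG_SD = {"SLA": 0.35, "LN": 0.25, "LP": 0.30, "LK": 0.30, "LC": 0.08}


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator; defaults emulate the target
    30-plot montane broadleaf census."""

    n_plots: int = 30
    n_species_pool: int = 60
    n_species_overstory: int = 48
    n_species_understory: int = 44
    plot_area: float = 400.0
    stratum_threshold: float = 9.0

    birth_rate: float = 1.0           # Yule branching rate
    sigma2: float = 1.0               # Brownian rate per trait, per unit time
    lambda_signal: float = 0.5        # phylogenetic-signal blend in [0, 1]

    abundance_concentration: float = 20.0   # Dirichlet mass per plot
    abundance_lognormal_sd: float = 1.0     # pool-level species unevenness

    mean_stems_overstory: float = 45.0      # per 400 m^2 plot
    mean_stems_understory: float = 150.0
    dbh_log_mean_overstory: float = np.log(20.0)
    dbh_log_sd_overstory: float = 0.45
    dbh_log_mean_understory: float = np.log(3.0)
    dbh_log_sd_understory: float = 0.50
    dbh_max: float = 100.0

    height_h1: float = 2.5            # H = h1 * D^h2 * exp(eps)
    height_h2: float = 0.55
    height_log_sd: float = 0.15

    allometric_a: float = 0.06        # general W = a*(D^2*H)^b, kg
    allometric_b: float = 0.95

    #: planted effects per stratum: predictor name -> coefficient on the
    #: standardized predictor; empty dict = no planted association.
    beta: dict = field(default_factory=lambda: {
        "overstory": {"CWM_SLA": 1.0, "MPD": 1.0},
        "understory": {"PSR": 1.0, "CWM_SLA": -1.0},
    })
    effect_scale: float = 0.35        # relative AGB swing per signal s.d.
    noise_sd_fraction: float = 0.25   # residual noise s.d. / signal s.d.

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_signal <= 1.0:
            raise ValueError("lambda_signal must lie in [0, 1]")
        if self.n_species_pool < 4:
            raise ValueError("n_species_pool must be >= 4")
        for name in ("birth_rate", "abundance_concentration",
                     "mean_stems_overstory", "mean_stems_understory"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if max(self.n_species_overstory, self.n_species_understory) > self.n_species_pool:
            raise ValueError("stratum species subsets exceed the pool")

    def allometric_model(self) -> AllometricModel:
        return AllometricModel(
            general=AllometricEntry(a=self.allometric_a, b=self.allometric_b)
        )


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would estimate."""

    stems: pd.DataFrame               # plot_id, species, dbh, height, stratum, agb_kg
    plots: pd.DataFrame               # per plot x stratum: baseline/target/realized AGB
    predictors: dict                  # stratum -> DataFrame of planted predictor values
    beta: dict
    config: SimulationConfig
    phylogeny: Phylogeny = None       # the pool tree the traits evolved on
    traits: TraitTable = None


# ---------------------------------------------------------------------------
# Phylogeny and traits
# ---------------------------------------------------------------------------

def simulate_phylogeny(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Rooted binary Yule (pure-birth) tree with ``n_species`` extant tips.

    Reproducible under ``seed``; tips are labelled sp001, sp002, ...
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    # the simulator stops at the n-th birth; observe the process a random
    # Exp(n*b) time later so terminal branches are never zero
    dt = rng.expovariate(n_species * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + dt
    taxa = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"sp{i + 1:03d}")
    tree.taxon_namespace = taxa
    return Phylogeny(tree)


def _shared_depth_matrix(phylogeny: Phylogeny) -> tuple[np.ndarray, list[str]]:
    """Tip covariance structure of Brownian motion: shared root-to-MRCA
    path length per tip pair (diagonal = root-to-tip depth)."""
    pm = patristic_matrix(phylogeny)
    h = pm.depths.to_numpy(float)
    D = pm.data.to_numpy(float)
    V = (h[:, None] + h[None, :] - D) / 2.0
    np.fill_diagonal(V, h)
    return V, list(pm.data.index)


def simulate_traits(
    phylogeny: Phylogeny,
    sigma2: float = 1.0,
    lambda_signal: float = 0.5,
    seed: int = 0,
) -> TraitTable:
    """Five lognormal leaf traits with tunable phylogenetic signal.

    Each trait's latent value is lambda * (Brownian motion on the tree)
    + (1 - lambda) * independent noise, standardized and mapped to
    exp(mu_t + s_t * z) so values are strictly positive on realistic
    scales. sigma2 = 0 collapses every species to the trait's reference
    value.
    """
    if not 0.0 <= lambda_signal <= 1.0:
        raise ValueError("lambda_signal must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    V, labels = _shared_depth_matrix(phylogeny)
    n = len(labels)
    tbar = float(np.mean(np.diag(V))) or 1.0
    jitter = 1e-10 * tbar * np.eye(n)
    L = np.linalg.cholesky(sigma2 * V + jitter) if sigma2 > 0 else np.zeros((n, n))
    lam = lambda_signal
    data = {}
    for t in TRAIT_NAMES:
        bm = L @ rng.standard_normal(n)
        noise = rng.standard_normal(n) * np.sqrt(sigma2 * tbar)
        z = lam * bm + (1.0 - lam) * noise
        scale = np.sqrt(sigma2 * tbar * (lam**2 + (1.0 - lam) ** 2)) or 1.0
        data[t] = np.exp(TRAIT_LOG_MEAN[t] + TRAIT_LOG_SD[t] * z / scale)
    return TraitTable(pd.DataFrame(data, index=pd.Index(labels, name="species")))


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------

#: factor loading pattern: fertility axis (AK, AN, SOM, TN, TP, TK) and a
#: second axis (AB, AP, pH), matching two correlated soil gradients.
_SOIL_SPEC = {
    # var: (mean, sd, factor index, loading)
    "pH": (4.55, 0.15, 1, 0.8), "SOM": (80.0, 20.0, 0, 0.8),
    "TN": (4.0, 1.0, 0, 0.8), "TP": (0.8, 0.2, 0, 0.7),
    "TK": (15.0, 3.0, 0, 0.7), "AN": (0.30, 0.08, 0, 0.8),
    "AP": (0.020, 0.005, 1, 0.8), "AK": (0.15, 0.04, 0, 0.8),
    "AB": (0.0015, 0.0004, 1, 0.7),
}


def simulate_environment(config: SimulationConfig, rng: np.random.Generator) -> EnvironmentTable:
    """Topographic and edaphic plot variables with a two-factor soil
    correlation structure; elevations span the 2450-2650 m gradient."""
    n = config.n_plots
    plots = [f"P{i + 1:02d}" for i in range(n)]
    out = pd.DataFrame(index=pd.Index(plots, name="plot_id"))
    out["elevation"] = rng.uniform(2450.0, 2650.0, n)
    out["slope"] = rng.uniform(5.0, 35.0, n)
    out["aspect"] = rng.uniform(0.0, 360.0, n)
    factors = rng.standard_normal((n, 2))
    for var in SOIL_VARS:
        mean, sd, k, load = _SOIL_SPEC[var]
        z = load * factors[:, k] + np.sqrt(1 - load**2) * rng.standard_normal(n)
        out[var] = np.maximum(mean + sd * z, mean * 0.05)
    return EnvironmentTable(out)


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = rng.lognormal(mu, sd, need.size)
        ok = (draw >= lo) & (draw < hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def _stratum_stems(
    config: SimulationConfig,
    rng: np.random.Generator,
    species: list[str],
    stratum: str,
    plots: list[str],
) -> list[TreeRecord]:
    over = stratum == _allometry.OVERSTORY
    mean_stems = config.mean_stems_overstory if over else config.mean_stems_understory
    mu = config.dbh_log_mean_overstory if over else config.dbh_log_mean_understory
    sd = config.dbh_log_sd_overstory if over else config.dbh_log_sd_understory
    lo = config.stratum_threshold if over else 1.0
    hi = config.dbh_max if over else config.stratum_threshold

    base = rng.lognormal(0.0, config.abundance_lognormal_sd, len(species))
    base /= base.sum()
    alpha = config.abundance_concentration * base
    records: list[TreeRecord] = []
    for pid in plots:
        probs = rng.dirichlet(alpha)
        n_stems = max(int(rng.poisson(mean_stems)), 2)
        counts = rng.multinomial(n_stems, probs)
        for sp_i in np.flatnonzero(counts):
            k = int(counts[sp_i])
            dbh = _truncated_lognormal(rng, mu, sd, lo, hi, k)
            eps = rng.normal(0.0, config.height_log_sd, k)
            height = config.height_h1 * dbh**config.height_h2 * np.exp(eps)
            records.extend(
                TreeRecord(pid, species[sp_i], float(d), float(h))
                for d, h in zip(dbh, height)
            )
    return records


def _predictor_values(
    records: list[TreeRecord],
    stratum: str,
    traits: TraitTable,
    phylogeny: Phylogeny,
    config: SimulationConfig,
    names: list[str],
) -> pd.DataFrame:
    """Plot-level values of the named diversity predictors for the planted
    linear model, computed with the package's own metric code."""
    inv = PlotInventory(list(records), plot_area=config.plot_area)
    ab = abundance_matrix(inv, basis="stem_count", stratum=stratum)
    func = functional_profile(ab, traits)
    phylo = phylo_profile(ab, phylogeny.subset(ab.species))
    table = pd.concat([func.drop(columns=["stratum"]),
                       phylo.drop(columns=["stratum"])], axis=1)
    missing = [n for n in names if n not in table.columns]
    if missing:
        raise GenerationError(f"unknown planted predictor(s): {missing}")
    return table[names]


def _rescale_counts(
    records: list[TreeRecord],
    masses: np.ndarray,
    factors: pd.Series,
    rng: np.random.Generator,
) -> list[TreeRecord]:
    """Replicate/thin stems so each plot's biomass moves to factor f of its
    baseline, never eliminating a species from a plot.

    Keeping at least one stem per (plot, species) cell leaves the
    presence-based ground-truth predictors (MPD, MNTD, PSR, FRic,
    richness) exactly invariant under the rescaling. Up-scaling (f >= 1)
    duplicates stems with stochastic rounding; down-scaling removes
    non-mandatory stems with a mass-weighted-unbiased probability, so the
    realized plot biomass is the target in expectation either way.
    """
    by_plot: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_plot.setdefault(r.plot_id, []).append(i)
    out: list[TreeRecord] = []
    for pid, idx in by_plot.items():
        f = float(factors.loc[pid])
        total = float(masses[idx].sum())
        if f >= 1.0:
            whole, frac = divmod(f - 1.0, 1.0)
            for i in idx:
                out.extend([records[i]] * (1 + int(whole)))
            chosen = _mass_matched_subset(idx, masses, frac * total, rng)
            out.extend(records[i] for i in chosen)
            continue
        # keep the lightest stem of every species; remove a mass-matched
        # subset of the rest
        lightest: dict[str, int] = {}
        for i in idx:
            sp = records[i].species
            if sp not in lightest or masses[i] < masses[lightest[sp]]:
                lightest[sp] = i
        mandatory = set(lightest.values())
        removable = [i for i in idx if i not in mandatory]
        floor_mass = total - float(masses[removable].sum()) if removable else total
        target = max(f * total, floor_mass)
        drop = set(_mass_matched_subset(removable, masses, total - target, rng))
        out.extend(records[i] for i in idx if i not in drop)
    return out


def _mass_matched_subset(
    candidates: list[int], masses: np.ndarray, target: float,
    rng: np.random.Generator,
) -> list[int]:
    """Subset of candidate stems whose total mass ~ target: greedy fill in
    shuffled order, then one Bernoulli stem so the expectation matches."""
    if target <= 0 or not candidates:
        return []
    order = list(rng.permutation(candidates))
    chosen, acc = [], 0.0
    leftovers = []
    for i in order:
        if acc + masses[i] <= target:
            chosen.append(i)
            acc += masses[i]
        else:
            leftovers.append(i)
    rem = target - acc
    if rem > 0 and leftovers:
        i = min(leftovers, key=lambda j: masses[j])
        if rng.random() < rem / masses[i]:
            chosen.append(i)
    return chosen


def simulate_community(
    config: SimulationConfig,
) -> tuple[PlotInventory, EnvironmentTable, GroundTruth]:
    """Full synthetic dataset: inventory, environment, and ground truth.

    Per stratum, plot communities are drawn Dirichlet-multinomially from an
    uneven species pool, sized, and given allometric biomass; plot AGB is
    then rescaled toward the planted model
    ``AGB = mean_AGB * exp(effect_scale*(sum_k beta_k z_k + eps))`` (mean-
    normalized; strictly positive, ~linear at the default effect size) with
    ``z_k`` the standardized named predictor and ``eps`` Gaussian noise
    whose s.d. is ``noise_sd_fraction`` times the signal s.d. Raises
    GenerationError when a planted target AGB is non-positive.
    """
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, 8)
    phylogeny = simulate_phylogeny(config.n_species_pool, config.birth_rate, int(seeds[0]))
    traits = simulate_traits(phylogeny, config.sigma2, config.lambda_signal, int(seeds[1]))
    env = simulate_environment(config, np.random.default_rng(int(seeds[2])))

    pool = list(traits.species)
    pick = np.random.default_rng(int(seeds[3]))
    over_species = list(pick.choice(pool, config.n_species_overstory, replace=False))
    under_species = list(pick.choice(pool, config.n_species_understory, replace=False))
    plots = list(env.data.index)

    model = config.allometric_model()
    all_records: list[TreeRecord] = []
    plot_rows = []
    predictor_tables: dict[str, pd.DataFrame] = {}
    for stratum, species, s_stems, s_resc in (
        (_allometry.OVERSTORY, over_species, int(seeds[4]), int(seeds[6])),
        (_allometry.UNDERSTORY, under_species, int(seeds[5]), int(seeds[7])),
    ):
        srng = np.random.default_rng(s_stems)
        records = _stratum_stems(config, srng, species, stratum, plots)
        inv0 = PlotInventory(records, plot_area=config.plot_area)
        agb0 = _allometry.plot_agb(inv0, model, stratum, plot_ids=plots)["agb"]

        beta = dict(config.beta.get(stratum, {}))
        if beta:
            preds = _predictor_values(records, stratum, traits, phylogeny, config, list(beta))
            preds = preds.reindex(plots)
            if preds.isna().any().any():
                raise GenerationError(
                    f"planted predictors undefined for some plots ({stratum})"
                )
            z = (preds - preds.mean()) / preds.std(ddof=1)
            signal = z.to_numpy() @ np.array([beta[k] for k in preds.columns])
            s_sd = float(np.std(signal, ddof=1))
            if s_sd <= 0:
                raise GenerationError("planted signal has zero variance")
            signal = signal / s_sd
            nrng = np.random.default_rng(s_resc)
            eps = nrng.normal(0.0, config.noise_sd_fraction, len(plots))
            # exponential link keeps the planted AGB strictly positive while
            # staying ~linear in the signal at the default effect size
            lin = config.effect_scale * (signal + eps)
            mult = np.exp(lin)
            if not np.all(np.isfinite(mult)) or np.any(mult <= 0):
                raise GenerationError(
                    f"infeasible beta for {stratum}: planted model implies "
                    "non-positive or unbounded AGB"
                )
            target = pd.Series(agb0.mean() * mult / mult.mean(), index=plots)
            factors = target / agb0.replace(0.0, np.nan)
            if factors.isna().any():
                raise GenerationError(f"empty baseline plot in {stratum}")
            masses = np.array([_allometry.stem_agb(r, model) for r in records])
            records = _rescale_counts(records, masses, factors, nrng)
            predictor_tables[stratum] = preds
        else:
            target = agb0.copy()
            predictor_tables[stratum] = pd.DataFrame(index=pd.Index(plots))

        inv1 = PlotInventory(records, plot_area=config.plot_area)
        agb1 = _allometry.plot_agb(inv1, model, stratum, plot_ids=plots)["agb"]
        for pid in plots:
            plot_rows.append(
                {
                    "plot_id": pid, "stratum": stratum,
                    "baseline_agb": float(agb0.loc[pid]),
                    "target_agb": float(target.loc[pid]),
                    "realized_agb": float(agb1.loc[pid]),
                }
            )
        all_records.extend(records)

    inventory = PlotInventory(all_records, plot_area=config.plot_area)
    threshold = config.stratum_threshold
    stems = inventory.to_dataframe()
    stems["stratum"] = np.where(
        stems["dbh"] >= threshold, _allometry.OVERSTORY, _allometry.UNDERSTORY
    )
    stems["agb_kg"] = [
        _allometry.stem_agb(r, model) for r in inventory.records
    ]
    truth = GroundTruth(
        stems=stems,
        plots=pd.DataFrame(plot_rows),
        predictors=predictor_tables,
        beta={k: dict(v) for k, v in config.beta.items()},
        config=config,
        phylogeny=phylogeny,
        traits=traits,
    )
    return inventory, env, truth
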