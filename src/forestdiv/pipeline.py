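"""End-to-end orchestration and the association report.

Runs the full analysis per stratum: allometric AGB, abundance structure,
functional and phylogenetic diversity profiles, environmental PCA scores,
PLS regression with VIP-guided shaving, and bivariate linear fits of AGB
on the predictors surviving shaving. Every report table is recomputable
from the persisted intermediates; a run manifest records seed, config hash
and library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import allometry as _allometry
from .community import AbundanceMatrix, abundance_matrix
from .env_pca import EnvScores, env_scores
from .functional import functional_profile
from .io import (
    EnvironmentTable,
    Phylogeny,
    PlotInventory,
    TraitTable,
    match_names,
)
from .phylo import phylo_profile
from .pls import ShaveResult, classify_vip, shave
from .simulate import GroundTruth, SimulationConfig, simulate_community

log = logging.getLogger("forestdiv")

#: Candidate predictor columns of the PLS matrix, per stratum.
PREDICTOR_COLUMNS = [
    "CWM_SLA", "CWM_LN", "CWM_LP", "CWM_LK", "CWM_LC",
    "FDis", "FRic", "FDiv",
    "MPD", "MNTD", "PSR",
    "Soil_PC1", "Soil_PC2", "Topo_PC1", "Topo_PC2",
]


@dataclass(frozen=True)
class BivariateFit:
    """OLS fit of AGB on one predictor (R^2 = squared Pearson r; p from
    the slope t-statistic, n-2 df)."""

    stratum: str
    predictor: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def bivariate_fit(x, y, stratum: str = "", predictor: str = "") -> BivariateFit:
    """Simple linear regression of y on x; requires n >= 3, finite values
    and non-constant x."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("bivariate fit needs >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression input")
    if np.std(x) == 0:
        raise ValueError(f"zero-variance predictor {predictor!r}")
    res = stats.linregress(x, y)
    return BivariateFit(
        stratum=stratum,
        predictor=predictor,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


@dataclass
class StratumResult:
    """All per-stratum outputs of one pipeline run."""

    stratum: str
    agb: pd.DataFrame                 # plot x [agb, n_stems, n_species]
    diversity: pd.DataFrame           # plot x predictor matrix incl. flags
    predictors: pd.DataFrame          # plot x PREDICTOR_COLUMNS (model input)
    shaving: ShaveResult
    vip_table: pd.DataFrame           # predictor, VIP, band, boundary
    bivariate: pd.DataFrame           # per selected predictor


@dataclass
class PipelineResult:
    strata: dict[str, StratumResult]
    env: EnvScores
    manifest: dict
    ground_truth: GroundTruth | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        env_tab = self.env.scores.copy()
        env_tab.rename_axis("plot_id").to_csv(out / "env_scores.csv")
        for name, res in self.strata.items():
            res.agb.to_csv(out / f"agb_{name}.csv")
            res.diversity.rename_axis("plot_id").to_csv(out / f"diversity_{name}.csv")
            res.vip_table.to_csv(out / f"vip_{name}.csv", index=False)
            res.bivariate.to_csv(out / f"bivariate_{name}.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def diversity_profile(
    abund: AbundanceMatrix,
    traits: TraitTable,
    phylogeny: Phylogeny,
) -> pd.DataFrame:
    """Functional + phylogenetic profile for one stratum (the metric half
    of the PLS predictor matrix)."""
    func = functional_profile(abund, traits)
    phyl = phylo_profile(abund, phylogeny)
    return pd.concat([func, phyl.drop(columns=["stratum"])], axis=1)


def analyze_stratum(
    stratum: str,
    inventory: PlotInventory,
    traits: TraitTable,
    phylogeny: Phylogeny,
    env: EnvScores,
    model,
    plot_ids: list[str],
    pls_settings: dict,
) -> StratumResult:
    """Run the per-stratum half of the analysis (AGB, metrics, PLS, fits)."""
    abund = abundance_matrix(inventory, basis="stem_count", stratum=stratum)
    agb = _allometry.plot_agb(inventory, model, stratum, plot_ids=plot_ids)
    div = diversity_profile(abund, traits, phylogeny)
    predictors = pd.concat(
        [div, env.scores.reindex(div.index)], axis=1
    )[PREDICTOR_COLUMNS]
    if predictors.isna().any().any():
        bad = predictors.columns[predictors.isna().any()].tolist()
        raise ValueError(
            f"{stratum}: undefined predictor(s) {bad}; too few species in "
            "some plots"
        )
    y = agb.loc[predictors.index, "agb"]
    log.info("%s: %d plots, %d candidate predictors", stratum,
             predictors.shape[0], predictors.shape[1])
    shaved = shave(
        predictors, y,
        cv_folds=pls_settings.get("cv_folds", 10),
        step_fraction=pls_settings.get("step_fraction", 0.2),
        max_components=pls_settings.get("components_max", 5),
        seed=pls_settings.get("seed", 0),
    )
    vip_table = classify_vip(shaved.vips)
    vip_table.insert(0, "stratum", stratum)
    fits = [
        bivariate_fit(predictors[name], y, stratum=stratum, predictor=name)
        for name in shaved.selected
    ]
    bft = pd.DataFrame([vars(f) for f in fits])
    return StratumResult(
        stratum=stratum, agb=agb, diversity=div, predictors=predictors,
        shaving=shaved, vip_table=vip_table, bivariate=bft,
    )


def _config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(
        {k: (sorted(v.items()) if isinstance(v, dict) else v)
         for k, v in vars(config).items()
         if not isinstance(v, (pd.DataFrame,))},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config: SimulationConfig | None = None,
    *,
    inventory: PlotInventory | None = None,
    traits: TraitTable | None = None,
    phylogeny: Phylogeny | None = None,
    environment: EnvironmentTable | None = None,
    allometric_model=None,
    stratum_threshold: float | None = None,
    pls_settings: dict | None = None,
    drop_unmatched_species: bool = False,
) -> PipelineResult:
    """Run the whole analysis, synthetic or on supplied data.

    Synthetic mode (``config`` given, data args omitted) generates the
    dataset first and keeps its ground truth in the result. In data mode
    the inventory, traits, phylogeny and environment must all be supplied;
    any species mismatch aborts unless ``drop_unmatched_species`` is set.
    Deterministic given the config seed.
    """
    import dendropy
    import scipy

    pls_settings = dict(pls_settings or {})
    truth = None
    if inventory is None:
        config = config or SimulationConfig()
        log.info("synthetic mode: seed=%d, %d plots", config.seed, config.n_plots)
        inventory, environment, truth = simulate_community(config)
        phylogeny = truth.phylogeny
        traits = truth.traits
        allometric_model = config.allometric_model()
        threshold = config.stratum_threshold
        pls_settings.setdefault("seed", config.seed)
    else:
        if traits is None or phylogeny is None or environment is None:
            raise ValueError(
                "data mode needs inventory, traits, phylogeny and environment"
            )
        threshold = stratum_threshold or 9.0
        if allometric_model is None:
            raise ValueError("data mode needs an allometric coefficient model")

    report = match_names(inventory, traits, phylogeny)
    if not report.ok:
        if drop_unmatched_species:
            from .io import drop_unmatched
            inventory, traits, phylogeny, report = drop_unmatched(
                inventory, traits, phylogeny)
            log.warning("dropped unmatched species: %s",
                        sorted(set(report.missing_from_traits +
                                   report.missing_from_tree)))
        else:
            raise ValueError(
                "species mismatch between inventory, traits and phylogeny: "
                f"missing traits {report.missing_from_traits}, "
                f"missing tips {report.missing_from_tree}"
            )

    env = env_scores(environment)
    over_inv, under_inv = _allometry.split_strata(inventory, threshold)
    plot_ids = inventory.plot_ids
    strata: dict[str, StratumResult] = {}
    for name, inv in (
        (_allometry.OVERSTORY, over_inv),
        (_allometry.UNDERSTORY, under_inv),
    ):
        sub_tree = phylogeny.subset(
            abundance_matrix(inv, stratum=name).species)
        strata[name] = analyze_stratum(
            name, inv, traits, sub_tree, env, allometric_model,
            plot_ids, pls_settings,
        )
    manifest = {
        "seed": pls_settings.get("seed", None),
        "stratum_threshold_cm": threshold,
        "n_plots": len(plot_ids),
        "config_hash": _config_hash(config) if config is not None else None,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "dendropy": dendropy.__version__,
        },
        "note": (
            "bivariate p-values are unadjusted for multiplicity; interpret "
            "jointly with the VIP selection"
        ),
    }
    return PipelineResult(strata=strata, env=env, manifest=manifest,
                          ground_truth=truth)
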