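"""Functional identity and diversity metrics per plot.

Four quantities per plot x stratum, computed from the species x trait table
and relative abundances w_i:

* CWM_t  = sum_i w_i * trait_it, on the raw trait scale, one per trait.
* FDis   = sum_i w_i * ||x_i - c||, with x_i the species' coordinates in
  z-standardized trait space and c = sum_i w_i * x_i the weighted centroid.
* FRic   = hull volume of the community's species in standardized trait
  space divided by the hull volume of the stratum species pool, in [0, 1];
  presence-based. Communities with fewer than T+1 points or a degenerate
  (affinely dependent) point set score 0 and carry a quality flag.
* FDiv   = mean over traits of (2/pi)*arctan(5*V_t), where V_t is the
  abundance-weighted variance of log trait values (the classical
  log-variance dispersion index); raw traits must be strictly positive.

Traits are z-scored over the stratum species pool before any distance or
hull computation so that no trait dominates by unit choice; CWM and the
log-variance index use the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .community import AbundanceMatrix
from .io import TRAIT_NAMES, TraitTable, ValidationError, normalize_name


@dataclass
class FunctionalSpace:
    """Species pool coordinates in standardized trait space."""

    coords: pd.DataFrame      # species x traits, z-scored over the pool
    mean: pd.Series
    std: pd.Series

    @property
    def n_traits(self) -> int:
        return self.coords.shape[1]


def _align_traits(abund: AbundanceMatrix, traits: TraitTable) -> pd.DataFrame:
    """Trait rows for the abundance matrix's species, error if any missing."""
    lookup = traits.normalized_index()
    rows, missing = [], []
    for sp in abund.species:
        key = normalize_name(sp)
        if key in lookup:
            rows.append(lookup[key])
        else:
            missing.append(sp)
    if missing:
        raise ValidationError(f"species missing trait values: {missing}")
    out = traits.data.loc[rows, list(TRAIT_NAMES)].copy()
    out.index = pd.Index(abund.species)
    return out


def functional_space(
    abund: AbundanceMatrix, traits: TraitTable, ddof: int = 1
) -> FunctionalSpace:
    """Z-score traits over the stratum pool (the abundance matrix's species)."""
    X = _align_traits(abund, traits)
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=ddof)
    if (std <= 0).any():
        zero = std.index[std <= 0].tolist()
        raise ValidationError(f"traits constant across the pool: {zero}")
    return FunctionalSpace(coords=(X - mean) / std, mean=mean, std=std)


def cwm(abund: AbundanceMatrix, traits: TraitTable) -> pd.DataFrame:
    """Community-weighted mean per trait, raw trait scale.

    Returns a plots x traits frame with columns CWM_SLA ... CWM_LC.
    """
    X = _align_traits(abund, traits)
    W = abund.relative[X.index]
    out = W.to_numpy() @ X.to_numpy()
    return pd.DataFrame(
        out, index=abund.relative.index, columns=[f"CWM_{t}" for t in TRAIT_NAMES]
    )


def fdis(abund: AbundanceMatrix, space: FunctionalSpace) -> pd.Series:
    """Functional dispersion: abundance-weighted mean distance to the
    weighted centroid in standardized trait space."""
    Z = space.coords.loc[abund.species].to_numpy()
    W = abund.relative.to_numpy()
    centroids = W @ Z                                    # plots x traits
    out = np.empty(W.shape[0])
    for p in range(W.shape[0]):
        dist = np.linalg.norm(Z - centroids[p], axis=1)
        out[p] = float(W[p] @ dist)
    return pd.Series(out, index=abund.relative.index, name="FDis")


def _hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume; raises QhullError on degenerate input."""
    return float(ConvexHull(points).volume)


def fric(
    abund: AbundanceMatrix, space: FunctionalSpace
) -> tuple[pd.Series, pd.Series]:
    """Functional richness relative to the stratum pool hull.

    Presence-based: FRic_p = vol(hull of species present in p) /
    vol(hull of the pool). Returns (fric, quality flag); plots with fewer
    than T+1 species or an affinely degenerate point set get 0 with
    flag='degenerate'.
    """
    Z = space.coords
    T = space.n_traits
    try:
        pool_vol = _hull_volume(Z.to_numpy())
    except QhullError as exc:
        raise ValidationError(
            f"species pool is degenerate in {T}-D trait space"
        ) from exc
    vals, flags = [], []
    for pid in abund.plot_ids:
        present = abund.plot_species(pid)
        if len(present) < T + 1:
            vals.append(0.0)
            flags.append("degenerate")
            continue
        try:
            vals.append(_hull_volume(Z.loc[present].to_numpy()) / pool_vol)
            flags.append("ok")
        except QhullError:
            vals.append(0.0)
            flags.append("degenerate")
    idx = abund.relative.index
    return (
        pd.Series(vals, index=idx, name="FRic"),
        pd.Series(flags, index=idx, name="FRic_flag"),
    )


def fdiv(abund: AbundanceMatrix, traits: TraitTable) -> pd.Series:
    """Arctangent-transformed weighted log-variance of traits, averaged
    across the five traits; 0 when all species share a trait value, -> 1 as
    the weighted log-variance grows."""
    X = _align_traits(abund, traits)
    if (X.to_numpy() <= 0).any():
        raise ValidationError("trait values must be strictly positive for FDiv")
    lnX = np.log(X.to_numpy())                          # species x traits
    W = abund.relative[X.index].to_numpy()              # plots x species
    ln_mean = W @ lnX                                   # plots x traits
    out = np.empty(W.shape[0])
    for p in range(W.shape[0]):
        dev2 = (lnX - ln_mean[p]) ** 2
        V = W[p] @ dev2                                 # per-trait weighted var
        out[p] = float(np.mean(2.0 / np.pi * np.arctan(5.0 * V)))
    return pd.Series(out, index=abund.relative.index, name="FDiv")


def functional_profile(abund: AbundanceMatrix, traits: TraitTable) -> pd.DataFrame:
    """CWMs, FDis, FRic (+flag) and FDiv for every plot of one stratum."""
    space = functional_space(abund, traits)
    parts = [cwm(abund, traits), fdis(abund, space)]
    fr, flag = fric(abund, space)
    parts += [fr, flag, fdiv(abund, traits)]
    out = pd.concat(parts, axis=1)
    out.insert(0, "stratum", abund.stratum)
    return out
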