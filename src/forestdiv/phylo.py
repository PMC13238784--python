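"""Phylogenetic community metrics: patristic distances, MPD, MNTD, PSV, PSR.

All quantities are presence-based, exactly as the classical definitions:

* MPD  = [2 / (n(n-1))] * sum_{i<j} d(s_i, s_j)
* MNTD = (1/n) * sum_i min_{j != i} d(s_i, s_j)
* PSV  = (n * tr(C) - sum(C)) / (n(n-1)) = 1 - mean off-diagonal of the
  phylogenetic correlation matrix C; PSR = n * PSV.

C_ij is the shared root-to-MRCA path length normalized by the geometric
mean of the two root-to-tip depths, which reduces to the standard shared
branch-length fraction on ultrametric trees and stays in [0, 1] on
non-ultrametric ones. Communities of fewer than two species have no
pairwise structure; their metrics are recorded as missing with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import AbundanceMatrix
from .io import Phylogeny, ValidationError, normalize_name


@dataclass
class PatristicMatrix:
    """Tip-to-tip path lengths d(s_i, s_j) on the tree."""

    data: pd.DataFrame      # species x species, symmetric, zero diagonal
    depths: pd.Series       # root-to-tip path length per species

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def submatrix(self, species: list[str]) -> np.ndarray:
        rows = self._resolve(species)
        return self.data.loc[rows, rows].to_numpy(float)

    def _resolve(self, species: list[str]) -> list[str]:
        lookup = {normalize_name(s): s for s in self.data.index}
        out, missing = [], []
        for sp in species:
            key = normalize_name(sp)
            if key in lookup:
                out.append(lookup[key])
            else:
                missing.append(sp)
        if missing:
            raise ValidationError(f"species missing from phylogeny: {missing}")
        return out


def patristic_matrix(phylogeny: Phylogeny) -> PatristicMatrix:
    """Sum of branch lengths along the unique path between every tip pair,
    plus root-to-tip depths (needed for the correlation matrix)."""
    tree = phylogeny.tree
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [lf.taxon for lf in tree.leaf_node_iter()]
    labels = [t.label for t in taxa]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    depth = {lf.taxon.label: float(lf.root_distance) for lf in tree.leaf_node_iter()}
    return PatristicMatrix(
        data=pd.DataFrame(D, index=labels, columns=labels),
        depths=pd.Series([depth[l] for l in labels], index=labels, name="depth"),
    )


def mpd(species: list[str], patristic: PatristicMatrix) -> float:
    """Mean pairwise patristic distance; NaN for n < 2."""
    if len(species) < 2:
        return float("nan")
    D = patristic.submatrix(species)
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(2.0 * D[iu].sum() / (n * (n - 1)))


def mntd(species: list[str], patristic: PatristicMatrix) -> float:
    """Mean distance to the nearest neighbour in the community; NaN for n < 2."""
    if len(species) < 2:
        return float("nan")
    D = patristic.submatrix(species)
    np.fill_diagonal(D, np.inf)
    return float(D.min(axis=1).mean())


def phylo_correlation(
    species: list[str], patristic: PatristicMatrix
) -> np.ndarray:
    """Phylogenetic correlation matrix C for a species set.

    Shared depth of tips i, j is (depth_i + depth_j - d_ij) / 2 (path
    additivity on a tree); C_ij divides it by sqrt(depth_i * depth_j).
    """
    rows = patristic._resolve(species)
    D = patristic.data.loc[rows, rows].to_numpy(float)
    h = patristic.depths.loc[rows].to_numpy(float)
    if np.any(h <= 0):
        raise ValidationError("zero root-to-tip depth; C is undefined")
    shared = (h[:, None] + h[None, :] - D) / 2.0
    C = shared / np.sqrt(np.outer(h, h))
    np.fill_diagonal(C, 1.0)
    return np.clip(C, 0.0, 1.0)


def psv_psr(species: list[str], patristic: PatristicMatrix) -> tuple[float, float]:
    """Phylogenetic species variability and richness.

    PSV = 1 - mean off-diagonal phylogenetic correlation, in [0, 1]
    (1 = star-like, maximally unrelated); PSR = n * PSV. NaN for n < 2.
    """
    n = len(species)
    if n < 2:
        return float("nan"), float("nan")
    C = phylo_correlation(species, patristic)
    psv = float((n * np.trace(C) - C.sum()) / (n * (n - 1)))
    return psv, n * psv


def phylo_profile(
    abund: AbundanceMatrix,
    phylogeny: Phylogeny,
    patristic: PatristicMatrix | None = None,
) -> pd.DataFrame:
    """Per-plot n, MPD, MNTD, PSV, PSR for one stratum.

    The tree may be stratum-specific or a larger pool tree; only the tips
    of the plot's species enter each metric either way. Plots with n < 2
    get NaN metrics and flag='singleton'.
    """
    if patristic is None:
        patristic = patristic_matrix(phylogeny)
    rows = []
    for pid in abund.plot_ids:
        present = abund.plot_species(pid)
        n = len(present)
        psv, psr = psv_psr(present, patristic)
        rows.append(
            {
                "stratum": abund.stratum,
                "n_species": n,
                "MPD": mpd(present, patristic),
                "MNTD": mntd(present, patristic),
                "PSV": psv,
                "PSR": psr,
                "phylo_flag": "ok" if n >= 2 else "singleton",
            }
        )
    return pd.DataFrame(rows, index=abund.relative.index)
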