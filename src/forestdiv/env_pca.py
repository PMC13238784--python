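"""Principal component analysis of topographic and edaphic variables.

Two separate correlation-matrix PCAs (variables z-scored first, since units
mix degrees, metres, g/kg and pH) reduce the plot x environment table to
Topo_PC1/2 and Soil_PC1/2 scores. Each component is oriented so that its
largest-magnitude loading is positive, which removes the eigenvector sign
ambiguity. Aspect is circular; by default it enters as sin(aspect) and
cos(aspect), with a raw-degrees fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EnvironmentTable, ValidationError


@dataclass
class PCAResult:
    scores: pd.DataFrame              # plots x kept components
    loadings: pd.DataFrame            # variables x all components
    explained_fraction: pd.Series     # over ALL components, sums to 1
    n_keep: int


@dataclass
class EnvScores:
    """Topo_PC1/2 and Soil_PC1/2 plot scores plus full PCA diagnostics."""

    scores: pd.DataFrame              # plots x [Topo_PC1, Topo_PC2, Soil_PC1, Soil_PC2]
    topo: PCAResult = field(repr=False, default=None)
    soil: PCAResult = field(repr=False, default=None)


def run_pca(table: pd.DataFrame, n_keep: int = 2, prefix: str = "PC") -> PCAResult:
    """Correlation-matrix PCA via SVD of the standardized data.

    Requires >= 3 rows; a constant column is an error (it cannot be
    standardized). Scores are centred; per-component variances equal the
    eigenvalues of the correlation matrix.
    """
    if table.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 plots")
    X = table.to_numpy(float)
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    constant = table.columns[std <= 0].tolist()
    if constant:
        raise ValidationError(f"constant variable(s) in PCA input: {constant}")
    Z = (X - mean) / std
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    n = X.shape[0]
    eigvals = s**2 / (n - 1)
    # orient: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    comp_names = [f"{prefix}{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(
        U * s, index=table.index, columns=comp_names
    ).iloc[:, :n_keep]
    loadings = pd.DataFrame(Vt.T, index=table.columns, columns=comp_names)
    frac = pd.Series(eigvals / eigvals.sum(), index=comp_names, name="explained")
    return PCAResult(scores=scores, loadings=loadings, explained_fraction=frac, n_keep=n_keep)


def encode_aspect(topo: pd.DataFrame, circular: bool = True) -> pd.DataFrame:
    """Replace the circular aspect column (degrees) by sin/cos components."""
    if not circular or "aspect" not in topo.columns:
        return topo
    out = topo.drop(columns=["aspect"]).copy()
    rad = np.deg2rad(topo["aspect"].to_numpy(float))
    out["aspect_sin"] = np.sin(rad)
    out["aspect_cos"] = np.cos(rad)
    return out


def env_scores(
    env: EnvironmentTable, n_keep: int = 2, circular_aspect: bool = True
) -> EnvScores:
    """Separate PCAs of the topographic and edaphic tables; returns the
    Topo_PC1/2 + Soil_PC1/2 score block used as AGB predictors."""
    topo = run_pca(encode_aspect(env.topographic, circular_aspect), n_keep, prefix="Topo_PC")
    soil = run_pca(env.edaphic, n_keep, prefix="Soil_PC")
    scores = pd.concat([topo.scores, soil.scores], axis=1)
    return EnvScores(scores=scores, topo=topo, soil=soil)
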