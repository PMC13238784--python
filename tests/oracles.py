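"""Independent straight-from-formula oracles used to check the package.

Everything here is deliberately naive (explicit loops, rejection sampling,
graph shortest paths) and shares no code with the implementation under
test.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay


def cwm_brute(weights: dict, traits: dict) -> float:
    """Community-weighted mean of one trait by explicit summation."""
    return sum(weights[sp] * traits[sp] for sp in weights)


def fdis_brute(weights: dict, coords: dict) -> float:
    """FDis: weighted centroid then weighted mean Euclidean distance."""
    species = list(weights)
    dim = len(next(iter(coords.values())))
    centroid = [
        sum(weights[sp] * coords[sp][k] for sp in species) for k in range(dim)
    ]
    total = 0.0
    for sp in species:
        d = sum((coords[sp][k] - centroid[k]) ** 2 for k in range(dim)) ** 0.5
        total += weights[sp] * d
    return total


def fdvar_brute(weights: dict, trait_matrix: dict) -> float:
    """Mean over traits of (2/pi)*arctan(5*V_t), V_t the weighted variance
    of log trait values."""
    species = list(weights)
    n_traits = len(next(iter(trait_matrix.values())))
    scores = []
    for t in range(n_traits):
        ln_mean = sum(weights[sp] * np.log(trait_matrix[sp][t]) for sp in species)
        v = sum(
            weights[sp] * (np.log(trait_matrix[sp][t]) - ln_mean) ** 2
            for sp in species
        )
        scores.append(2.0 / np.pi * np.arctan(5.0 * v))
    return float(np.mean(scores))


def mpd_brute(species: list, dist: dict) -> float:
    """Mean over all unordered pairs of patristic distances."""
    pairs = [
        dist[(a, b)] for i, a in enumerate(species) for b in species[i + 1:]
    ]
    return float(np.mean(pairs))


def mntd_brute(species: list, dist: dict) -> float:
    """Mean nearest-neighbour distance by explicit min scan."""
    total = 0.0
    for a in species:
        total += min(dist[(a, b)] for b in species if b != a)
    return total / len(species)


def hull_volume_mc(
    points: np.ndarray, rng: np.random.Generator, n_samples: int = 300_000
) -> float:
    """Convex-hull volume by rejection sampling in the bounding box."""
    lo, hi = points.min(axis=0), points.max(axis=0)
    box = np.prod(hi - lo)
    tri = Delaunay(points)
    draws = rng.uniform(lo, hi, size=(n_samples, points.shape[1]))
    inside = tri.find_simplex(draws) >= 0
    return float(box * inside.mean())


def patristic_networkx(tree) -> dict:
    """Tip-to-tip distances via shortest paths on the tree graph."""
    import networkx as nx

    g = nx.Graph()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            g.add_edge(id(edge.tail_node), id(edge.head_node),
                       weight=float(edge.length or 0.0))
    leaves = {lf.taxon.label: id(lf) for lf in tree.leaf_node_iter()}
    out = {}
    labels = list(leaves)
    for i, a in enumerate(labels):
        lengths = nx.single_source_dijkstra_path_length(g, leaves[a])
        for b in labels:
            out[(a, b)] = 0.0 if a == b else lengths[leaves[b]]
    return out


def ols_coefficients(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares slope vector and intercept via lstsq on the
    intercept-augmented design."""
    A = np.column_stack([np.ones(len(y)), X])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return sol[1:], float(sol[0])


def brownian_tip_draws(
    shared_depth: np.ndarray, rng: np.random.Generator, n_draws: int
) -> np.ndarray:
    """Sample Brownian tip values x ~ N(0, V) for V the shared-depth
    matrix; returns n_draws x n_tips."""
    L = np.linalg.cholesky(shared_depth + 1e-10 * np.eye(len(shared_depth)))
    return rng.standard_normal((n_draws, len(shared_depth))) @ L.T
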