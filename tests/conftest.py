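import numpy as np
import pandas as pd
import pytest

import forestdiv as fd


@pytest.fixture
def caterpillar():
    """((A:1,B:1):1,C:2); — 3 tips, total branch length 5, depth 2."""
    return fd.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star3():
    return fd.read_newick("(A:1,B:1,C:1);")


def make_inventory(rows, plot_area=400.0):
    return fd.PlotInventory(
        [fd.TreeRecord(*r) for r in rows], plot_area=plot_area
    )


@pytest.fixture
def small_inventory():
    return make_inventory(
        [
            ("P1", "A", 12.0, 10.0),
            ("P1", "A", 30.0, 18.0),
            ("P1", "B", 5.0, 4.0),
            ("P2", "B", 9.0, 8.0),
            ("P2", "C", 2.0, 2.5),
            ("P2", "C", 2.5, 3.0),
        ]
    )


def make_abundance(rel_rows: dict, stratum=""):
    """AbundanceMatrix straight from a {plot: {species: w}} dict."""
    rel = pd.DataFrame(rel_rows).T.fillna(0.0)
    rel.index.name = "plot_id"
    return fd.AbundanceMatrix(relative=rel, raw=rel.copy(), basis="stem_count",
                              stratum=stratum)


def random_community(rng, n_species, n_plots=1):
    """Random relative-abundance rows over n_species labelled s0..s{k}."""
    species = [f"s{i}" for i in range(n_species)]
    rows = {}
    for p in range(n_plots):
        w = rng.dirichlet(np.ones(n_species) * 0.8)
        rows[f"P{p}"] = dict(zip(species, w))
    return make_abundance(rows), species
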