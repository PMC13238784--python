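"""Plot x species abundance structures feeding the diversity metrics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PlotInventory, normalize_name


@dataclass
class AbundanceMatrix:
    """Plots x species relative abundances with companion raw measures.

    Rows sum to 1; species with zero total abundance are excluded. ``basis``
    records whether abundance is stem counts or basal area.
    """

    relative: pd.DataFrame  # plots x species, rows sum to 1
    raw: pd.DataFrame       # same shape, unnormalized measure
    basis: str
    stratum: str = ""

    @property
    def plot_ids(self) -> list[str]:
        return list(self.relative.index)

    @property
    def species(self) -> list[str]:
        return list(self.relative.columns)

    def plot_species(self, plot_id: str) -> list[str]:
        row = self.relative.loc[plot_id]
        return list(row.index[row > 0])

    def richness(self) -> pd.Series:
        return (self.relative > 0).sum(axis=1).rename("n_species")


def abundance_matrix(
    stratum_inventory: PlotInventory,
    basis: str = "stem_count",
    stratum: str = "",
) -> AbundanceMatrix:
    """Relative abundance w_i per plot: species measure / plot total.

    ``basis='stem_count'`` counts stems (the conventional reading of
    abundance); ``basis='basal_area'`` weights by pi*(D/2)^2. Plots with no
    stems are dropped with a warning.
    """
    if basis not in ("stem_count", "basal_area"):
        raise ValueError(f"unknown abundance basis {basis!r}")
    if not stratum_inventory.records:
        raise ValueError("empty stratum inventory")
    canon: dict[str, str] = {}
    cells: dict[tuple[str, str], float] = {}
    for r in stratum_inventory.records:
        sp = canon.setdefault(normalize_name(r.species), r.species)
        w = 1.0 if basis == "stem_count" else np.pi * (r.dbh / 2.0) ** 2
        cells[(r.plot_id, sp)] = cells.get((r.plot_id, sp), 0.0) + w
    raw = pd.Series(cells).unstack(fill_value=0.0)
    raw.index.name = "plot_id"
    # preserve first-appearance plot order rather than lexical sort
    plot_order = list(dict.fromkeys(r.plot_id for r in stratum_inventory.records))
    raw = raw.reindex(plot_order)
    totals = raw.sum(axis=1)
    empty = totals[totals <= 0].index.tolist()
    if empty:
        warnings.warn(f"dropping empty plot(s): {empty}", stacklevel=2)
        raw = raw.drop(index=empty)
        totals = totals.drop(index=empty)
    rel = raw.div(totals, axis=0)
    return AbundanceMatrix(relative=rel, raw=raw, basis=basis, stratum=stratum)
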