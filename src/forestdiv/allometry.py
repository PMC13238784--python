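"""Allometric aboveground-biomass estimation and stratum accounting.

Per-stem mass follows the power law W = a*(D^2*H)^b (kg; D in cm, H in m),
with an optional 'split' form W = a*D^2*H^b per coefficient entry. Stems are
partitioned into overstory (DBH >= threshold, default 9 cm) and understory,
and plot totals are scaled from kg per plot to Mg/ha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    AllometricModel,
    DEFAULT_STRATUM_THRESHOLD_CM,
    PlotInventory,
    TreeRecord,
    normalize_name,
)

OVERSTORY = "overstory"
UNDERSTORY = "understory"

KG_PER_MG = 1000.0
M2_PER_HA = 10000.0


@dataclass(frozen=True)
class StratumAGB:
    """Per-plot, per-stratum biomass summary (agb in Mg/ha)."""

    plot_id: str
    stratum: str
    agb: float
    n_stems: int
    n_species: int


def stem_agb(record: TreeRecord, model: AllometricModel) -> float:
    """Aboveground biomass of one stem, kg.

    Coefficients are resolved species-specifically, falling back to the
    general model; monotone increasing in both D and H.
    """
    entry = model.resolve(record.species)
    d, h = record.dbh, record.height
    if entry.form == "split":
        return entry.a * d * d * h**entry.b
    return entry.a * (d * d * h) ** entry.b


def split_strata(
    inventory: PlotInventory,
    threshold: float = DEFAULT_STRATUM_THRESHOLD_CM,
) -> tuple[PlotInventory, PlotInventory]:
    """Partition stems into (overstory, understory) at the DBH threshold.

    DBH exactly at the threshold goes to the overstory; the partition is
    exhaustive and disjoint.
    """
    over = [r for r in inventory.records if r.dbh >= threshold]
    under = [r for r in inventory.records if r.dbh < threshold]
    return (
        PlotInventory(over, plot_area=inventory.plot_area),
        PlotInventory(under, plot_area=inventory.plot_area),
    )


def plot_agb(
    stratum_inventory: PlotInventory,
    model: AllometricModel,
    stratum: str = OVERSTORY,
    plot_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-plot AGB in Mg/ha for one stratum.

    agb = sum of stem masses (kg) / 1000 * (10000 / plot_area); a 400 m^2
    plot is therefore scaled by 25. ``plot_ids`` forces rows (agb 0) for
    plots with no stems in this stratum.
    """
    area = stratum_inventory.plot_area
    if area <= 0:
        raise ValueError("plot_area must be positive")
    scale = M2_PER_HA / area / KG_PER_MG
    per_plot: dict[str, list[TreeRecord]] = {}
    for r in stratum_inventory.records:
        per_plot.setdefault(r.plot_id, []).append(r)
    ids = plot_ids if plot_ids is not None else list(per_plot)
    rows = []
    for pid in ids:
        recs = per_plot.get(pid, [])
        total_kg = float(sum(stem_agb(r, model) for r in recs))
        rows.append(
            StratumAGB(
                plot_id=pid,
                stratum=stratum,
                agb=total_kg * scale,
                n_stems=len(recs),
                n_species=len({normalize_name(r.species) for r in recs}),
            )
        )
    df = pd.DataFrame(
        [(s.plot_id, s.stratum, s.agb, s.n_stems, s.n_species) for s in rows],
        columns=["plot_id", "stratum", "agb", "n_stems", "n_species"],
    )
    return df.set_index("plot_id")


def stratum_agb_tables(
    inventory: PlotInventory,
    model: AllometricModel,
    threshold: float = DEFAULT_STRATUM_THRESHOLD_CM,
) -> dict[str, pd.DataFrame]:
    """Convenience: split and summarize both strata with aligned plot rows."""
    over, under = split_strata(inventory, threshold)
    ids = inventory.plot_ids
    return {
        OVERSTORY: plot_agb(over, model, OVERSTORY, plot_ids=ids),
        UNDERSTORY: plot_agb(under, model, UNDERSTORY, plot_ids=ids),
    }
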