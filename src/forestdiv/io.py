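"""Domain types, validation and file readers/writers.

All tabular inputs are UTF-8 delimited text with headers (comma or tab,
auto-detected, overridable). Phylogenies are Newick with branch lengths.
Species names are matched after trimming and collapsing internal whitespace
and case-folding; no fuzzy matching — taxonomic errors must surface.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

#: The five leaf traits used throughout: specific leaf area (mm^2/mg) and
#: leaf nitrogen / phosphorus / potassium / carbon concentration (mg/g).
TRAIT_NAMES = ("SLA", "LN", "LP", "LK", "LC")

#: Topographic variables (elevation m, slope deg, aspect deg).
TOPO_VARS = ("elevation", "slope", "aspect")

#: Edaphic variables (g/kg except pH): soil organic matter, total and
#: available N/P/K, available boron.
SOIL_VARS = ("pH", "SOM", "TN", "TP", "TK", "AN", "AP", "AK", "AB")

#: Census threshold: stems below 1 cm DBH are not inventoried.
MIN_DBH_CM = 1.0

#: Plot area of the study design, m^2 (20 m x 20 m).
DEFAULT_PLOT_AREA_M2 = 400.0

#: DBH threshold (cm) separating overstory (>=) from understory (<).
DEFAULT_STRATUM_THRESHOLD_CM = 9.0

_WS = re.compile(r"\s+")


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


def normalize_name(name: str) -> str:
    """Canonical species-name key: trimmed, internal whitespace collapsed,
    case-folded. Idempotent."""
    return _WS.sub(" ", name.strip()).casefold()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeRecord:
    """One censused stem: plot, species, DBH (cm), height (m)."""

    plot_id: str
    species: str
    dbh: float
    height: float

    def __post_init__(self) -> None:
        if not self.species or not self.species.strip():
            raise ValidationError("species name must be non-empty")
        if not np.isfinite(self.dbh) or self.dbh < MIN_DBH_CM:
            raise ValidationError(
                f"dbh must be >= {MIN_DBH_CM} cm, got {self.dbh!r} "
                f"(plot {self.plot_id}, {self.species})"
            )
        if not np.isfinite(self.height) or self.height <= 0:
            raise ValidationError(
                f"height must be positive, got {self.height!r} "
                f"(plot {self.plot_id}, {self.species})"
            )


@dataclass
class PlotInventory:
    """All stems of a census, with the (uniform) plot area in m^2."""

    records: list[TreeRecord]
    plot_area: float = DEFAULT_PLOT_AREA_M2

    def __post_init__(self) -> None:
        if self.plot_area <= 0:
            raise ValidationError("plot_area must be positive")

    @property
    def plot_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.plot_id, None)
        return list(seen)

    @property
    def species(self) -> list[str]:
        seen: dict[str, str] = {}
        for r in self.records:
            seen.setdefault(normalize_name(r.species), r.species)
        return list(seen.values())

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(r) for r in self.records],
            columns=["plot_id", "species", "dbh", "height"],
        )


@dataclass
class TraitTable:
    """Species x trait values; strictly positive (log-variance index needs
    logs). One row per species."""

    data: pd.DataFrame  # index: species, columns: TRAIT_NAMES

    def __post_init__(self) -> None:
        dupes = self.data.index[self.data.index.duplicated()]
        if len(dupes):
            raise ValidationError(f"duplicate species in trait table: {list(dupes)}")
        missing = [c for c in TRAIT_NAMES if c not in self.data.columns]
        if missing:
            raise FormatError(f"trait table missing columns: {missing}")
        vals = self.data[list(TRAIT_NAMES)].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("trait table contains non-finite values")
        if np.any(vals <= 0):
            bad = self.data.index[(vals <= 0).any(axis=1)]
            raise ValidationError(f"non-positive trait values for: {list(bad)}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def normalized_index(self) -> dict[str, str]:
        return {normalize_name(s): s for s in self.data.index}


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths; tips are species names."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def total_branch_length(self) -> float:
        return sum(
            e.length for e in self.tree.preorder_edge_iter() if e.length is not None
        )

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def subset(self, species: Iterable[str]) -> "Phylogeny":
        """Prune to the given tips (normalized name matching).

        Unifurcations left by the pruning are kept, so every retained
        root-to-tip path — and hence the patristic matrix, tip depths and
        the correlation structure behind PSV — is exactly preserved.
        """
        keep = {normalize_name(s) for s in species}
        taxa = [
            t for t in self.tree.taxon_namespace if normalize_name(t.label) in keep
        ]
        clone = self.tree.clone(depth=1)
        clone.retain_taxa(taxa, suppress_unifurcations=False)
        return Phylogeny(clone)


@dataclass
class EnvironmentTable:
    """Plot x environment: topographic and edaphic variables, one row per
    plot, no missing cells."""

    data: pd.DataFrame  # index: plot_id

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate plot_id in environment table")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValidationError(f"missing cells in environment columns: {bad}")

    @property
    def topographic(self) -> pd.DataFrame:
        cols = [c for c in TOPO_VARS if c in self.data.columns]
        return self.data[cols]

    @property
    def edaphic(self) -> pd.DataFrame:
        cols = [c for c in SOIL_VARS if c in self.data.columns]
        return self.data[cols]


@dataclass(frozen=True)
class AllometricEntry:
    """Power-law biomass coefficients. ``form`` selects the equation:
    'compound' -> W = a*(D^2*H)^b ; 'split' -> W = a*D^2*H^b."""

    a: float
    b: float
    form: str = "compound"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValidationError("allometric coefficients a, b must be positive")
        if self.form not in ("compound", "split"):
            raise ValidationError(f"unknown allometric form {self.form!r}")


@dataclass
class AllometricModel:
    """Species-specific entries plus a general fallback. W is in kg/stem."""

    general: AllometricEntry | None
    species: dict[str, AllometricEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = {normalize_name(k): v for k, v in self.species.items()}

    def resolve(self, species_name: str) -> AllometricEntry:
        entry = self.species.get(normalize_name(species_name))
        if entry is not None:
            return entry
        if self.general is None:
            raise ValidationError(
                f"no allometric coefficients for {species_name!r} and no "
                "general model configured"
            )
        return self.general


# ---------------------------------------------------------------------------
# Delimited-table plumbing
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _read_table(path: str | Path, delimiter: str | None, required: Sequence[str]) -> pd.DataFrame:
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_inventory(
    path: str | Path,
    delimiter: str | None = None,
    plot_area: float = DEFAULT_PLOT_AREA_M2,
) -> PlotInventory:
    """Read a stem inventory (plot_id, species, dbh, height).

    Raises FormatError on a missing column and ValidationError listing every
    offending row when DBH or height violates the census invariants.
    """
    df = _read_table(path, delimiter, ["plot_id", "species", "dbh", "height"])
    records, problems = [], []
    for i, row in df.iterrows():
        try:
            records.append(
                TreeRecord(
                    plot_id=str(row["plot_id"]),
                    species=str(row["species"]),
                    dbh=float(row["dbh"]),
                    height=float(row["height"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {i + 2}: {exc}")  # +2: header + 1-basing
    if problems:
        raise ValidationError(
            f"{path}: {len(problems)} invalid inventory row(s):\n" + "\n".join(problems)
        )
    return PlotInventory(records, plot_area=plot_area)


def write_inventory(inventory: PlotInventory, path: str | Path, delimiter: str = ",") -> None:
    inventory.to_dataframe().to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def read_traits(path: str | Path, delimiter: str | None = None) -> TraitTable:
    df = _read_table(path, delimiter, ["species", *TRAIT_NAMES])
    return TraitTable(df.set_index("species")[list(TRAIT_NAMES)].astype(float))


def write_traits(traits: TraitTable, path: str | Path, delimiter: str = ",") -> None:
    traits.data.rename_axis("species").to_csv(path, sep=delimiter, encoding="utf-8")


def read_environment(path: str | Path, delimiter: str | None = None) -> EnvironmentTable:
    df = _read_table(path, delimiter, ["plot_id"])
    df["plot_id"] = df["plot_id"].astype(str)
    return EnvironmentTable(df.set_index("plot_id").astype(float))


def write_environment(env: EnvironmentTable, path: str | Path, delimiter: str = ",") -> None:
    env.data.rename_axis("plot_id").to_csv(path, sep=delimiter, encoding="utf-8")


def read_allometry(path: str | Path, delimiter: str | None = None) -> AllometricModel:
    """Coefficient table with columns species, a, b[, form]; the row whose
    species is 'general' (case-insensitive) becomes the fallback."""
    df = _read_table(path, delimiter, ["species", "a", "b"])
    general = None
    species: dict[str, AllometricEntry] = {}
    for _, row in df.iterrows():
        form = str(row["form"]).strip() if "form" in df.columns and pd.notna(row.get("form")) else "compound"
        entry = AllometricEntry(a=float(row["a"]), b=float(row["b"]), form=form)
        name = str(row["species"]).strip()
        if normalize_name(name) == "general":
            general = entry
        else:
            species[name] = entry
    return AllometricModel(general=general, species=species)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(
    source: str | Path,
    missing_branch_lengths: str = "error",
) -> Phylogeny:
    """Read a single Newick tree.

    ``source`` may be a path or a Newick string. Missing branch lengths are
    an error by default (every path-length quantity depends on them);
    ``missing_branch_lengths='zero'`` treats them as 0 instead.
    """
    if missing_branch_lengths not in ("error", "zero"):
        raise ValueError("missing_branch_lengths must be 'error' or 'zero'")
    text = None
    if isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    else:
        text = Path(source).read_text(encoding="utf-8")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise FormatError(f"Newick parse error: {exc}") from exc
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge length is conventionally absent
        if edge.length is None:
            n_missing += 1
            if missing_branch_lengths == "zero":
                edge.length = 0.0
        elif edge.length < 0:
            raise ValidationError("negative branch length in phylogeny")
    if n_missing and missing_branch_lengths == "error":
        raise ValidationError(
            f"{n_missing} branch(es) lack lengths; pass "
            "missing_branch_lengths='zero' to accept them as zero"
        )
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    return Phylogeny(tree)


def write_newick(phylogeny: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phylogeny.as_newick() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Name reconciliation
# ---------------------------------------------------------------------------

@dataclass
class NameReport:
    """Mismatches between inventory, trait table and phylogeny tips."""

    missing_from_traits: list[str]
    missing_from_tree: list[str]

    @property
    def ok(self) -> bool:
        return not self.missing_from_traits and not self.missing_from_tree

    def __len__(self) -> int:
        return len(set(self.missing_from_traits) | set(self.missing_from_tree))


def match_names(
    inventory: PlotInventory,
    traits: TraitTable,
    phylogeny: Phylogeny,
) -> NameReport:
    """Report inventory species absent from the trait table or the tree."""
    trait_keys = {normalize_name(s) for s in traits.species}
    tip_keys = {normalize_name(t) for t in phylogeny.tip_labels}
    missing_traits, missing_tree = [], []
    for sp in inventory.species:
        key = normalize_name(sp)
        if key not in trait_keys:
            missing_traits.append(sp)
        if key not in tip_keys:
            missing_tree.append(sp)
    return NameReport(missing_traits, missing_tree)


def drop_unmatched(
    inventory: PlotInventory,
    traits: TraitTable,
    phylogeny: Phylogeny,
) -> tuple[PlotInventory, TraitTable, Phylogeny, NameReport]:
    """Remove species not present in all three structures, consistently.

    Returns the pruned structures plus the report of what was dropped.
    Intended for the explicit drop-with-warning path; the default pipeline
    refuses to proceed on any mismatch instead.
    """
    report = match_names(inventory, traits, phylogeny)
    bad = {normalize_name(s) for s in report.missing_from_traits}
    bad |= {normalize_name(s) for s in report.missing_from_tree}
    keep_records = [r for r in inventory.records if normalize_name(r.species) not in bad]
    kept_species = {normalize_name(r.species) for r in keep_records}
    new_inv = PlotInventory(keep_records, plot_area=inventory.plot_area)
    keep_rows = [s for s in traits.species if normalize_name(s) in kept_species]
    new_traits = TraitTable(traits.data.loc[keep_rows])
    new_tree = phylogeny.subset([s for s in new_inv.species])
    return new_inv, new_traits, new_tree, report
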