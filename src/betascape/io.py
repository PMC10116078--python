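"""Core data containers and delimited-text / Newick readers and writers.

All tabular containers hold pandas objects internally and enforce their
structural invariants at construction time.  Species labels are forced to a
single canonical (lexicographic) order when a table is loaded; downstream
operations receiving inconsistently ordered inputs raise rather than silently
reindexing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical trait-table columns: 10 diet proportions, 8 foraging-stratum
#: proportions, 1 activity-time ordinal, 1 body mass (grams).
DIET_COLS = [f"diet_{c}" for c in (
    "inv", "vend", "vect", "vfish", "vunk", "scav", "fruit", "nect", "seed", "plant")]
FORAGE_COLS = [f"forage_{c}" for c in (
    "watbelow", "wataround", "ground", "understory", "midhigh", "canopy", "aerial", "other")]
TRAIT_COLS = DIET_COLS + FORAGE_COLS + ["activity", "body_mass_g"]

#: Canonical unit-covariate columns.
COVARIATE_COLS = ["hfi", "forest_loss", "npp", "habitat_div", "mean_temp", "n_points"]


class SpeciesOrderError(ValueError):
    """Raised when two species-indexed objects disagree on label order."""


def check_species_order(a, b, what: str = "inputs") -> None:
    """Raise :class:`SpeciesOrderError` unless label sequences are identical."""
    if list(a) != list(b):
        raise SpeciesOrderError(
            f"species order mismatch between {what}: {list(a)[:5]}... vs {list(b)[:5]}..."
        )


@dataclass
class CommunityTable:
    """Abundance matrix of local communities with unit membership and coordinates.

    Parameters
    ----------
    abundance : DataFrame
        Integer counts, rows indexed by community id, columns by species id
        (canonical order).
    unit_of : Series
        Maps community id -> unit id.
    unit_coords : DataFrame
        Planar (x, y) centroid per unit, indexed by unit id.
    community_coords : DataFrame, optional
        Planar (x, y) per community, used only by point de-duplication.
    dates : Series, optional
        Observation date (ordinal day number) per community.
    """

    abundance: pd.DataFrame
    unit_of: pd.Series
    unit_coords: pd.DataFrame
    community_coords: pd.DataFrame | None = None
    dates: pd.Series | None = None

    def __post_init__(self) -> None:
        ab = self.abundance
        if ab.index.duplicated().any():
            dups = ab.index[ab.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate community ids: {dups}")
        if (ab.to_numpy() < 0).any():
            raise ValueError("negative abundances")
        totals = ab.sum(axis=1)
        empty = totals.index[totals == 0].tolist()
        if empty:
            raise ValueError(f"communities with zero total abundance: {empty}")
        missing = set(self.unit_of) - set(self.unit_coords.index)
        if missing:
            raise ValueError(f"units without coordinates: {sorted(map(str, missing))}")
        if not self.unit_of.index.equals(ab.index):
            raise ValueError("unit_of index must match abundance rows")

    @property
    def species_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def community_ids(self) -> list:
        return list(self.abundance.index)

    @property
    def unit_ids(self) -> list:
        return list(pd.unique(self.unit_of))

    def communities_of(self, unit_id) -> pd.DataFrame:
        """Abundance sub-matrix of one unit's communities."""
        return self.abundance.loc[self.unit_of[self.unit_of == unit_id].index]

    def n_points(self) -> pd.Series:
        """Number of local communities per unit."""
        return self.unit_of.value_counts().reindex(self.unit_ids)


@dataclass
class TraitTable:
    """20 numeric functional traits per species.

    10 diet proportions and 8 foraging-stratum proportions each sum to 100
    per species (values on a 10-unit grid in field data), one activity-time
    ordinal (0-100, 20-unit steps) and body mass in grams.
    """

    traits: pd.DataFrame

    def __post_init__(self) -> None:
        tr = self.traits
        if list(tr.columns) != TRAIT_COLS:
            raise ValueError(
                f"trait table must have exactly the 20 canonical columns, got {list(tr.columns)}"
            )
        if tr.isna().any().any():
            bad = tr.index[tr.isna().any(axis=1)].tolist()
            raise ValueError(f"missing trait values for species: {bad}")
        for cols, name in ((DIET_COLS, "diet"), (FORAGE_COLS, "foraging")):
            sums = tr[cols].sum(axis=1)
            off = sums.index[~np.isclose(sums, 100.0)].tolist()
            if off:
                raise ValueError(f"{name} proportions do not sum to 100 for: {off}")

    @property
    def species_ids(self) -> list[str]:
        return list(self.traits.index)


@dataclass
class TreeSet:
    """A set of candidate phylogenies over one shared taxon set."""

    trees: dendropy.TreeList

    def __post_init__(self) -> None:
        if len(self.trees) == 0:
            raise ValueError("TreeSet must contain at least one tree")
        ref = self.tip_labels(0)
        for i, tree in enumerate(self.trees):
            tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
            if tips != ref:
                raise ValueError(
                    f"tree {i} tip set differs from tree 0 "
                    f"(missing {sorted(ref - tips)}, extra {sorted(tips - ref)})"
                )
            for edge in tree.preorder_edge_iter():
                if edge.length is not None and edge.length < 0:
                    raise ValueError(f"tree {i} has a negative branch length")

    def tip_labels(self, i: int = 0) -> set[str]:
        return {leaf.taxon.label for leaf in self.trees[i].leaf_node_iter()}

    @property
    def count(self) -> int:
        return len(self.trees)


@dataclass
class UnitCovariates:
    """Per-unit predictor table.

    Columns: ``hfi`` (human footprint, 0-100), ``forest_loss`` (% cover lost,
    >= 0), ``npp`` (kg C/m^2/year), ``habitat_div`` (mean habitat
    alpha-diversity), ``mean_temp`` (deg C), ``n_points`` (local communities
    per unit, >= 3 for units entering analysis).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        tb = self.table
        missing = [c for c in COVARIATE_COLS if c not in tb.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        if (tb["forest_loss"] < 0).any():
            raise ValueError("forest_loss must be non-negative")
        if (tb["n_points"] < 3).any():
            bad = tb.index[tb["n_points"] < 3].tolist()
            raise ValueError(f"units with fewer than 3 points: {bad}")

    @property
    def unit_ids(self) -> list:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep(tab: bool) -> str:
    return "\t" if tab else ","


def read_community_table(
    path: str | Path,
    coords_path: str | Path,
    *,
    community_coords_path: str | Path | None = None,
    tab: bool = False,
) -> CommunityTable:
    """Read a community abundance file plus a unit-coordinates file.

    The abundance file has one row per community with columns ``community_id``,
    ``unit_id`` and one integer column per species; the coordinates file has
    columns ``unit_id``, ``x``, ``y``.  Species columns are reordered to the
    canonical (lexicographic) order.  An optional community-coordinates file
    (``community_id``, ``x``, ``y`` and optionally ``date``) supports the
    point-deduplication filter.
    """
    sep = _sep(tab)
    df = pd.read_csv(path, sep=sep)
    if "community_id" not in df.columns or "unit_id" not in df.columns:
        raise ValueError("abundance file needs 'community_id' and 'unit_id' columns")
    if df["community_id"].duplicated().any():
        dups = df.loc[df["community_id"].duplicated(), "community_id"].tolist()
        raise ValueError(f"duplicate community ids: {dups}")
    df = df.set_index("community_id")
    unit_of = df.pop("unit_id")
    species = sorted(df.columns)
    abundance = df[species].astype(int)

    coords = pd.read_csv(coords_path, sep=sep).set_index("unit_id")[["x", "y"]]

    community_coords = dates = None
    if community_coords_path is not None:
        cc = pd.read_csv(community_coords_path, sep=sep).set_index("community_id")
        community_coords = cc[["x", "y"]]
        if "date" in cc.columns:
            dates = cc["date"]
    return CommunityTable(abundance, unit_of, coords, community_coords, dates)


def write_community_table(
    ct: CommunityTable, path: str | Path, coords_path: str | Path,
    *, community_coords_path: str | Path | None = None, tab: bool = False,
) -> None:
    sep = _sep(tab)
    out = ct.abundance.copy()
    out.insert(0, "unit_id", ct.unit_of)
    out.to_csv(path, sep=sep, index_label="community_id")
    ct.unit_coords.to_csv(coords_path, sep=sep, index_label="unit_id")
    if community_coords_path is not None and ct.community_coords is not None:
        cc = ct.community_coords.copy()
        if ct.dates is not None:
            cc["date"] = ct.dates
        cc.to_csv(community_coords_path, sep=sep, index_label="community_id")


def read_trait_table(path: str | Path, *, tab: bool = False) -> TraitTable:
    df = pd.read_csv(path, sep=_sep(tab)).set_index("species_id").sort_index()
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        for col in non_numeric:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ValueError(f"non-numeric trait '{col}' for species {bad}")
    return TraitTable(df[TRAIT_COLS])


def write_trait_table(tt: TraitTable, path: str | Path, *, tab: bool = False) -> None:
    tt.traits.to_csv(path, sep=_sep(tab), index_label="species_id")


def read_covariates(path: str | Path, *, tab: bool = False) -> UnitCovariates:
    df = pd.read_csv(path, sep=_sep(tab)).set_index("unit_id")
    return UnitCovariates(df[COVARIATE_COLS])


def write_covariates(uc: UnitCovariates, path: str | Path, *, tab: bool = False) -> None:
    uc.table.to_csv(path, sep=_sep(tab), index_label="unit_id")


def read_tree_set(path: str | Path) -> TreeSet:
    """Read a multi-tree Newick file (one tree per line) into a TreeSet."""
    taxa = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(taxon_namespace=taxa)
    with open(path) as fh:
        lines = [(i, line.strip()) for i, line in enumerate(fh, start=1) if line.strip()]
    if not lines:
        raise ValueError(f"no Newick trees found in {path}")
    for lineno, text in lines:
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", taxon_namespace=taxa,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"malformed Newick on line {lineno}: {exc}") from exc
        trees.append(tree)
    return TreeSet(trees)


def write_tree_set(ts: TreeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tree in ts.trees:
            fh.write(tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n")
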