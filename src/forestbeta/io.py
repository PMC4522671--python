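"""Readers, writers and validated domain containers.

Every external format the pipeline touches goes through this module:
newick trees (via dendropy), CSV tables for the stem census, species
traits, soil point samples and distance matrices, and YAML run
configuration.  Coordinates are continuous with the origin at a plot
corner and half-open extents [0, width) x [0, height), so grid-cell
assignment downstream is unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("forestbeta")

#: Soil variables measured in a typical forest-dynamics-plot campaign:
#: water content plus nine nutrient/physical variables.
DEFAULT_SOIL_VARIABLES = (
    "pH",
    "total_N",
    "total_P",
    "total_K",
    "available_N",
    "extractable_P",
    "extractable_K",
    "total_C",
    "bulk_density",
    "water_content",
)


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal, non-negative distance matrix with labels.

    Houses species distances (phylogenetic or trait cophenetic), geographic
    distances between subplot centers and environmental distances alike.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite entries in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(self.values < 0):
            raise ValidationError("negative distances")
        self._index = {l: i for i, l in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        try:
            idx = [self._index[l] for l in labels]
        except KeyError as exc:
            raise ValidationError(f"label {exc.args[0]!r} not in matrix") from exc
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "label"
        df.to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths; tip labels are species ids."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        tips = self.tip_labels
        if len(tips) != len(set(tips)):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.as_newick() + "\n")


def read_newick(path: str | Path) -> Phylogeny:
    """Parse a rooted newick tree with branch lengths.

    Raises a parse error naming the offending position for malformed input
    and a :class:`ValidationError` for duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate tip labels in {path}: {exc}") from exc
    phylo = Phylogeny(tree)
    logger.info("read %d tips from %s", phylo.n_tips, path)
    return phylo


def phylogeny_from_newick_string(s: str) -> Phylogeny:
    tree = dendropy.Tree.get(
        data=s,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return Phylogeny(tree)


def cophenetic_distance(phylo: Phylogeny) -> DistanceMatrix:
    """Patristic distance between every pair of tips.

    Entry (i, j) is the sum of branch lengths on the path between tips i
    and j; this is the species distance delta used by the beta-diversity
    metrics when the source is the molecular phylogeny.
    """
    labels = sorted(phylo.tip_labels)
    if len(labels) < 2:
        raise ValidationError("cophenetic distance needs at least two tips")
    pdm = phylo.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in phylo.tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels, out)


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------


@dataclass
class StemCensus:
    """Stem-mapped census: one record per stem with species and x/y in m."""

    stems: pd.DataFrame  # columns: stem_id, species, x, y
    width: float
    height: float

    def __post_init__(self) -> None:
        required = {"stem_id", "species", "x", "y"}
        missing = required - set(self.stems.columns)
        if missing:
            raise ValidationError(f"census missing columns: {sorted(missing)}")
        if self.stems["species"].isna().any() or (self.stems["species"] == "").any():
            raise ValidationError("empty species id in census")
        x = self.stems["x"].to_numpy(float)
        y = self.stems["y"].to_numpy(float)
        bad = (x < 0) | (x >= self.width) | (y < 0) | (y >= self.height)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"census row {row} at ({x[row]}, {y[row]}) outside half-open "
                f"plot extent [0, {self.width}) x [0, {self.height})"
            )

    @property
    def n_stems(self) -> int:
        return len(self.stems)

    @property
    def species(self) -> list[str]:
        return sorted(self.stems["species"].unique())

    def write_csv(self, path: str | Path) -> None:
        self.stems.to_csv(path, index=False)


@dataclass
class TraitTable:
    """Species-level trait means: one row per species, one column per trait."""

    table: pd.DataFrame  # index: species; columns: trait names

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate species rows in trait table")
        non_numeric = [
            c for c in self.table.columns
            if not np.issubdtype(self.table[c].dtype, np.number)
        ]
        if non_numeric:
            raise ValidationError(f"non-numeric trait columns: {non_numeric}")
        n_missing = int(self.table.isna().sum().sum())
        if n_missing:
            logger.warning("trait table has %d missing values", n_missing)

    @property
    def species(self) -> list[str]:
        return sorted(self.table.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.table.columns)

    def write_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "species"
        out.to_csv(path)


@dataclass
class SoilSampleTable:
    """Soil point samples: x, y plus one column per soil variable."""

    samples: pd.DataFrame  # columns: x, y, <variables...>
    variables: list[str]

    def __post_init__(self) -> None:
        missing = {"x", "y"} - set(self.samples.columns)
        if missing:
            raise ValidationError(f"soil table missing columns: {sorted(missing)}")
        absent = [v for v in self.variables if v not in self.samples.columns]
        if absent:
            raise ValidationError(f"soil variables absent from table: {absent}")
        if self.samples[self.variables].isna().any().any():
            raise ValidationError("soil table has unsampled variable values")

    @property
    def n_points(self) -> int:
        return len(self.samples)

    def coords(self) -> np.ndarray:
        return self.samples[["x", "y"]].to_numpy(float)

    def write_csv(self, path: str | Path) -> None:
        self.samples.to_csv(path, index=False)


def read_census(path: str | Path, width: float, height: float) -> StemCensus:
    df = pd.read_csv(path)
    census = StemCensus(df, width=width, height=height)
    logger.info("read %d stems, %d species from %s",
                census.n_stems, len(census.species), path)
    return census


def read_traits(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, index_col="species")
    table = TraitTable(df)
    logger.info("read traits for %d species (%d traits) from %s",
                len(table.species), len(table.trait_names), path)
    return table


def read_soil(path: str | Path, variables: Sequence[str] | None = None,
              width: float | None = None, height: float | None = None
              ) -> SoilSampleTable:
    df = pd.read_csv(path)
    if variables is None:
        variables = [c for c in df.columns if c not in ("x", "y")]
    table = SoilSampleTable(df, list(variables))
    if width is not None and height is not None:
        xy = table.coords()
        bad = ((xy[:, 0] < 0) | (xy[:, 0] >= width)
               | (xy[:, 1] < 0) | (xy[:, 1] >= height))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"soil sample row {row} outside plot")
    logger.info("read %d soil samples, %d variables from %s",
                table.n_points, len(table.variables), path)
    return table


# ---------------------------------------------------------------------------
# Elevation grid
# ---------------------------------------------------------------------------


@dataclass
class ElevationGrid:
    """Gridded elevation surface; node (i, j) covers the cell whose origin
    is (j * resolution, i * resolution)."""

    width: float
    height: float
    resolution: float
    elevation: np.ndarray

    def __post_init__(self) -> None:
        n_rows = int(round(self.height / self.resolution))
        n_cols = int(round(self.width / self.resolution))
        if self.elevation.shape != (n_rows, n_cols):
            raise ValidationError(
                f"elevation shape {self.elevation.shape} does not match "
                f"plot {self.width} x {self.height} at {self.resolution} m"
            )


def write_elevation(grid, path: str | Path) -> None:
    """Write an elevation surface (or any object with width/height/
    resolution/elevation attributes) as a commented CSV matrix."""
    with open(path, "w") as fh:
        fh.write(f"# width={grid.width} height={grid.height} "
                 f"resolution={grid.resolution}\n")
        np.savetxt(fh, grid.elevation, delimiter=",", fmt="%.6f")


def read_elevation(path: str | Path) -> ElevationGrid:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        arr = np.loadtxt(fh, delimiter=",")
    return ElevationGrid(width=float(meta["width"]),
                         height=float(meta["height"]),
                         resolution=float(meta["resolution"]),
                         elevation=np.atleast_2d(arr))


# ---------------------------------------------------------------------------
# Species reconciliation
# ---------------------------------------------------------------------------


@dataclass
class Reconciliation:
    """Census species missing from the tree or trait table.

    Species absent from a distance source are dropped from that analysis
    (phylogenetic or functional) with a logged count, mirroring the common
    situation where the community phylogeny covers most but not all of the
    censused flora.
    """

    census_species: list[str]
    missing_from_tree: list[str] = field(default_factory=list)
    missing_from_traits: list[str] = field(default_factory=list)

    @property
    def phylo_species(self) -> list[str]:
        drop = set(self.missing_from_tree)
        return [s for s in self.census_species if s not in drop]

    @property
    def trait_species(self) -> list[str]:
        drop = set(self.missing_from_traits)
        return [s for s in self.census_species if s not in drop]


def reconcile_species(census: StemCensus,
                      phylo: Phylogeny | None = None,
                      traits: TraitTable | None = None) -> Reconciliation:
    """Report census species missing from the tree and/or trait table."""
    census_sp = census.species
    rec = Reconciliation(census_species=census_sp)
    if phylo is not None:
        on_tree = set(phylo.tip_labels)
        rec.missing_from_tree = [s for s in census_sp if s not in on_tree]
        if rec.missing_from_tree:
            logger.warning("%d census species absent from tree; dropped from "
                           "phylogenetic analysis", len(rec.missing_from_tree))
    if traits is not None:
        with_traits = set(traits.species)
        rec.missing_from_traits = [s for s in census_sp if s not in with_traits]
        if rec.missing_from_traits:
            logger.warning("%d census species absent from trait table; dropped "
                           "from functional analysis", len(rec.missing_from_traits))
    return rec


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (plot dims, scales, reps, seeds...)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} did not parse to a mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
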