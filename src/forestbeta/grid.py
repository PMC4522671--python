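"""Multi-scale plot subdivision and community matrices.

A rectangular stem-mapped plot is tiled exactly by square subplots at one
or more scales (cell sides in m); stems are binned into cells by the
half-open convention floor(x / scale), floor(y / scale).  Cells are indexed
row-major from the origin corner so habitat maps and community matrices
align across modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DistanceMatrix, StemCensus, ValidationError, logger


@dataclass
class SubplotGrid:
    """Exact square tiling of the plot at one scale."""

    width: float
    height: float
    scale: float

    def __post_init__(self) -> None:
        for dim, name in ((self.width, "width"), (self.height, "height")):
            q = dim / self.scale
            if abs(q - round(q)) > 1e-9:
                raise ValidationError(
                    f"scale {self.scale} does not divide {name} {dim} "
                    f"(remainder {dim % self.scale:g})"
                )
        self.n_cols = int(round(self.width / self.scale))
        self.n_rows = int(round(self.height / self.scale))

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def cell_ids(self) -> list[str]:
        return [f"c{i:04d}" for i in range(self.n_cells)]

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Row-major cell index of points; half-open cell intervals."""
        col = np.floor(np.asarray(x) / self.scale).astype(int)
        row = np.floor(np.asarray(y) / self.scale).astype(int)
        return row * self.n_cols + col

    def centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates in m."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        cx = (cols + 0.5) * self.scale
        cy = (rows + 0.5) * self.scale
        gx, gy = np.meshgrid(cx, cy)  # row-major: y outer, x inner
        return np.column_stack([gx.ravel(), gy.ravel()])


def subdivide_plot(width: float, height: float, scale: float) -> SubplotGrid:
    """Tile a width x height plot by square subplots of the given side.

    A 20-ha 400 x 500 m plot yields 2000 / 500 / 80 / 20 subplots at the
    10 / 20 / 50 / 100 m scales.
    """
    grid = SubplotGrid(width=width, height=height, scale=scale)
    logger.info("grid at %g m: %d cells (%d x %d)",
                scale, grid.n_cells, grid.n_cols, grid.n_rows)
    return grid


@dataclass
class CommunityMatrix:
    """Subplot x species abundance counts on one grid."""

    grid: SubplotGrid
    abundance: pd.DataFrame  # index: cell ids; columns: species

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.abundance.to_numpy(float)

    def nonempty_cells(self) -> np.ndarray:
        """Boolean mask of subplots containing at least one stem."""
        return self.counts.sum(axis=1) > 0

    def restrict_species(self, species: list[str]) -> "CommunityMatrix":
        keep = [s for s in species if s in self.abundance.columns]
        return CommunityMatrix(self.grid, self.abundance[keep])

    def write_csv(self, path) -> None:
        out = self.abundance.copy()
        out.index.name = "subplot_id"
        out.to_csv(path)


def build_community_matrix(census: StemCensus, grid: SubplotGrid
                           ) -> CommunityMatrix:
    """Count stems of each species in each grid cell."""
    cells = grid.cell_index(census.stems["x"].to_numpy(float),
                            census.stems["y"].to_numpy(float))
    species = census.species
    sp_index = {s: k for k, s in enumerate(species)}
    sp = census.stems["species"].map(sp_index).to_numpy(int)
    counts = np.zeros((grid.n_cells, len(species)), dtype=int)
    np.add.at(counts, (cells, sp), 1)
    cm = CommunityMatrix(
        grid, pd.DataFrame(counts, index=grid.cell_ids, columns=species)
    )
    assert counts.sum() == census.n_stems
    return cm


def geographic_distances(grid: SubplotGrid) -> DistanceMatrix:
    """Euclidean distance between subplot centers."""
    if grid.n_cells < 2:
        raise ValidationError("geographic distances need at least two cells")
    centers = grid.centers()
    diff = centers[:, None, :] - centers[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    return DistanceMatrix(grid.cell_ids, d)
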