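"""Gridded surfaces on a single planar CRS.

A :class:`Grid` is a 2-D array plus a georeference: the coordinates of
the lower-left corner, a square cell size in metres, and row order fixed
so that row index increases with the y coordinate.  Surfaces are stored
on disk as whitespace-delimited text arrays next to one shared
``georef.json``, which keeps every artifact diff-able and loadable with
nothing but numpy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: land-cover class codes used throughout the package
LANDCOVER_CLASSES = ("forest", "built", "water", "other")


@dataclass
class Grid:
    """A single-band gridded surface with georeferencing.

    Parameters
    ----------
    data:
        2-D array, shape ``(nrows, ncols)``.  Row 0 is the southernmost
        row (y increases with row index).
    origin:
        ``(x0, y0)`` of the lower-left corner of the lower-left cell, m.
    cell_size:
        Square cell edge length, m.
    """

    data: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1000.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("grid data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` coordinate arrays of all cell centres.

        Both arrays have shape ``(nrows, ncols)``.
        """
        x0, y0 = self.origin
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 + (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Return the ``(row, col)`` index of the cell containing a point."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y - y0) / self.cell_size))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def same_georef(self, other: "Grid") -> bool:
        return (
            self.data.shape == other.data.shape
            and self.origin == other.origin
            and self.cell_size == other.cell_size
        )


@dataclass
class SurfaceStack:
    """Named co-registered grids (continuous covariates + land cover).

    ``landcover`` holds integer class codes indexing
    :data:`LANDCOVER_CLASSES`; all other surfaces are continuous.
    """

    surfaces: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.surfaces.values())
        for g in grids[1:]:
            if not g.same_georef(grids[0]):
                raise ValueError("all surfaces must share shape and georeference")

    def __getitem__(self, name: str) -> Grid:
        return self.surfaces[name]

    def __contains__(self, name: str) -> bool:
        return name in self.surfaces

    @property
    def names(self) -> list[str]:
        return list(self.surfaces)

    @property
    def continuous_names(self) -> list[str]:
        return [n for n in self.surfaces if n != "landcover"]

    @property
    def template(self) -> Grid:
        return next(iter(self.surfaces.values()))


def write_stack(stack: SurfaceStack, directory: str | Path) -> None:
    """Write each surface as ``<name>.txt`` plus a shared ``georef.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tpl = stack.template
    meta = {
        "origin": list(tpl.origin),
        "cell_size": tpl.cell_size,
        "nrows": tpl.nrows,
        "ncols": tpl.ncols,
        "row_order": "row0_south",
        "crs": "local-planar-metres",
        "landcover_classes": list(LANDCOVER_CLASSES),
        "surfaces": stack.names,
    }
    (directory / "georef.json").write_text(json.dumps(meta, indent=2))
    for name, grid in stack.surfaces.items():
        fmt = "%d" if name == "landcover" else "%.10g"
        np.savetxt(directory / f"{name}.txt", grid.data, fmt=fmt)


def read_stack(directory: str | Path) -> SurfaceStack:
    """Load a surface stack written by :func:`write_stack`."""
    directory = Path(directory)
    meta = json.loads((directory / "georef.json").read_text())
    origin = tuple(meta["origin"])
    cell_size = meta["cell_size"]
    surfaces = {}
    for name in meta["surfaces"]:
        data = np.loadtxt(directory / f"{name}.txt")
        if name == "landcover":
            data = data.astype(int)
        data = data.reshape(meta["nrows"], meta["ncols"])
        surfaces[name] = Grid(data, origin=origin, cell_size=cell_size)
    return SurfaceStack(surfaces)


def write_grid(grid: Grid, path: str | Path) -> None:
    """Write one grid as text with a sidecar ``<path>.json`` georeference."""
    path = Path(path)
    np.savetxt(path, grid.data, fmt="%.10g")
    meta = {
        "origin": list(grid.origin),
        "cell_size": grid.cell_size,
        "nrows": grid.nrows,
        "ncols": grid.ncols,
        "row_order": "row0_south",
        "crs": "local-planar-metres",
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_grid(path: str | Path) -> Grid:
    meta = json.loads(Path(str(path) + ".json").read_text())
    data = np.loadtxt(path).reshape(meta["nrows"], meta["ncols"])
    return Grid(data, origin=tuple(meta["origin"]), cell_size=meta["cell_size"])
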