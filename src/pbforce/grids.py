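"""Regular grids and scalar fields (dielectric, charge, potential maps)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Default grid spacing, Å.
DEFAULT_SPACING = 0.8
#: Default solute fill fraction per axis (DelPhi "perfil" convention).
DEFAULT_FILL = 0.7


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular node-centered grid: origin (Å), spacing (Å), shape."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        for n in self.shape:
            if n < 9 or n % 2 == 0:
                raise ValueError(f"grid shape components must be odd and >= 9, got {self.shape}")

    @property
    def extent(self) -> np.ndarray:
        """Box edge lengths, Å."""
        return (np.asarray(self.shape) - 1) * self.spacing

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        return tuple(o[k] + self.spacing * np.arange(self.shape[k]) for k in range(3))

    def to_grid_coords(self, points: np.ndarray) -> np.ndarray:
        """Cartesian (Å) -> fractional node indices."""
        return (np.atleast_2d(points) - np.asarray(self.origin)) / self.spacing

    def node_coords(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of node positions, Å."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    @staticmethod
    def for_atoms(
        coords: np.ndarray,
        radii: np.ndarray,
        spacing: float = DEFAULT_SPACING,
        fill: float = DEFAULT_FILL,
        min_nodes: int = 9,
    ) -> "GridSpec":
        """Centered grid enclosing the atoms with at most ``fill`` occupancy.

        Each axis extent is (solute extent incl. radii) / fill, so the solute
        occupies at most ``fill`` of the box per dimension; the node count is
        rounded up to the next odd integer.
        """
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        radii = np.asarray(radii, dtype=float)
        lo = (coords - radii[:, None]).min(axis=0)
        hi = (coords + radii[:, None]).max(axis=0)
        center = 0.5 * (lo + hi)
        extent = np.maximum(hi - lo, spacing) / fill
        shape = []
        for e in extent:
            n = int(np.ceil(e / spacing)) + 1
            if n % 2 == 0:
                n += 1
            shape.append(max(n, min_nodes))
        origin = center - 0.5 * (np.asarray(shape) - 1) * spacing
        return GridSpec(tuple(origin), spacing, tuple(shape))


@dataclass
class ScalarField:
    """A scalar sampled at every grid node."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar field contains non-finite values")


def write_opendx(field: ScalarField, path: str | Path, name: str = "field") -> None:
    """Export a scalar field in OpenDX format (as used by APBS/DelPhi tools)."""
    g = field.grid
    nx, ny, nz = g.shape
    with open(path, "w") as fh:
        fh.write(f"# pbforce scalar field: {name}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6e} {:.6e} {:.6e}\n".format(*g.origin))
        fh.write(f"delta {g.spacing:.6e} 0.0 0.0\n")
        fh.write(f"delta 0.0 {g.spacing:.6e} 0.0\n")
        fh.write(f"delta 0.0 0.0 {g.spacing:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = field.values.ravel(order="C")
        for start in range(0, flat.size, 3):
            chunk = flat[start:start + 3]
            fh.write(" ".join(f"{v:.6e}" for v in chunk) + "\n")
        fh.write(f'attribute "dep" string "positions"\n')
        fh.write(f'object "{name}" class field\n')
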