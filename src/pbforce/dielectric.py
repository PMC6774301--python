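"""Dielectric maps: sharp two-dielectric and Gaussian smooth models.

Two descriptions of the dielectric response of a solvated molecule are
supported.

**Two-dielectric model.**  The solute is a uniform low-dielectric cavity
(``eps_in``) immersed in high-dielectric solvent (``eps_out``) with a sharp
jump at the molecular surface.  The cavity is the probe-closed molecular
volume: the union of van der Waals spheres, morphologically closed with a
spherical solvent probe (default radius 1.4 Å).  Crevices too narrow for the
probe are therefore part of the cavity — when two partners approach within
about a water diameter, the inter-partner gap switches from solvent to
solute dielectric.  This geometric switch is what produces the desolvation
penalty (and its force signature) at 2–4 Å separation.

**Gaussian smooth model.**  Each atom carries a Gaussian density

    rho_i(r) = exp(-r_i^2 / (sigma^2 * R_i^2)),

densities combine as ``rho_mol = 1 - prod_i(1 - rho_i)``, and the dielectric
interpolates smoothly:

    eps(r) = rho_mol(r) * eps_in + (1 - rho_mol(r)) * eps_out.

``sigma`` controls the effective molecular size: larger sigma extends the
low-dielectric region further into the solvent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage

from .grids import GridSpec, ScalarField
from .structures import Atom

#: Per-atom density below this value is treated as zero when building maps.
DENSITY_CUTOFF = 1e-6

ModelName = Literal["two_dielectric", "gaussian"]


@dataclass(frozen=True)
class DielectricParams:
    """Dielectric model parameters.

    eps_in / eps_out are the solute and solvent reference dielectric values
    (defaults 2 and 80); sigma is the dimensionless Gaussian width
    multiplier; probe_radius (Å) is the solvent probe used for the
    two-dielectric molecular surface.
    """

    eps_in: float = 2.0
    eps_out: float = 80.0
    sigma: float = 0.96
    probe_radius: float = 1.4
    model: ModelName = "two_dielectric"

    def __post_init__(self) -> None:
        if not 1 <= self.eps_in < self.eps_out:
            raise ValueError("require 1 <= eps_in < eps_out")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")

    def with_model(self, model: ModelName, **kw) -> "DielectricParams":
        return replace(self, model=model, **kw)

    @property
    def tag(self) -> str:
        if self.model == "gaussian":
            return f"gaussian_s{self.sigma:g}"
        return "two_dielectric"


def atomic_density(atom: Atom, points: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian density of one atom at the given point(s)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r2 = np.sum((pts - np.asarray(atom.coords)) ** 2, axis=-1)
    out = np.exp(-r2 / (sigma**2 * atom.radius**2))
    return out if np.asarray(points).ndim > 1 else float(out[0])


def molecular_density(atoms: Sequence[Atom], points: np.ndarray, sigma: float) -> np.ndarray:
    """Total molecular density 1 - prod_i (1 - rho_i); always in [0, 1]."""
    if not atoms:
        raise ValueError("atoms must be non-empty")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    complement = np.ones(pts.shape[0])
    for atom in atoms:
        rho = np.asarray(atomic_density(atom, pts, sigma))
        rho = np.where(rho < DENSITY_CUTOFF, 0.0, rho)
        complement *= 1.0 - rho
    dens = 1.0 - complement
    return dens if np.asarray(points).ndim > 1 else float(dens[0])


def _atom_local_box(grid: GridSpec, center: np.ndarray, reach: float):
    """Index slices and node coordinates of the sub-box within ``reach`` of center."""
    h = grid.spacing
    origin = np.asarray(grid.origin)
    lo_idx = np.maximum(np.floor((center - reach - origin) / h).astype(int), 0)
    hi_idx = np.minimum(
        np.ceil((center + reach - origin) / h).astype(int) + 1, np.asarray(grid.shape)
    )
    if np.any(lo_idx >= hi_idx):
        return None
    slices = tuple(slice(lo_idx[k], hi_idx[k]) for k in range(3))
    axes = [origin[k] + h * np.arange(lo_idx[k], hi_idx[k]) for k in range(3)]
    return slices, axes


def _local_r2(axes, center):
    dx2 = (axes[0] - center[0]) ** 2
    dy2 = (axes[1] - center[1]) ** 2
    dz2 = (axes[2] - center[2]) ** 2
    return dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]


def gaussian_dielectric_map(
    atoms: Iterable[Atom], grid: GridSpec, params: DielectricParams
) -> ScalarField:
    """Smooth dielectric map eps(r) = rho_mol*eps_in + (1-rho_mol)*eps_out.

    Per-atom contributions are truncated where rho_i < 1e-6 (a relative
    error below 1e-6 * n_atoms on the density).
    """
    if params.model != "gaussian":
        raise ValueError("params.model must be 'gaussian'")
    atoms = list(atoms)
    if not atoms:
        raise ValueError("atoms must be non-empty")
    # exp(-r^2 / (sigma R)^2) >= cutoff  <=>  r <= sigma R sqrt(-ln cutoff)
    reach_factor = params.sigma * float(np.sqrt(-np.log(DENSITY_CUTOFF)))
    complement = np.ones(grid.shape)
    for atom in atoms:
        center = np.asarray(atom.coords)
        box = _atom_local_box(grid, center, reach_factor * atom.radius)
        if box is None:
            continue
        slices, axes = box
        r2 = _local_r2(axes, center)
        rho = np.exp(-r2 / (params.sigma**2 * atom.radius**2))
        complement[slices] *= 1.0 - np.where(rho < DENSITY_CUTOFF, 0.0, rho)
    density = 1.0 - complement
    eps = density * params.eps_in + (1.0 - density) * params.eps_out
    return ScalarField(grid, eps)


def two_dielectric_map(
    atoms: Iterable[Atom], grid: GridSpec, params: DielectricParams
) -> ScalarField:
    """Sharp dielectric map over the probe-closed molecular volume.

    Nodes are classified in three steps: (1) nodes inside any van der Waals
    sphere are solute; (2) nodes farther than R_i + probe_radius from every
    atom are solvent-accessible; (3) the remaining contact-shell nodes are
    solute unless a probe centered at an accessible node can reach them
    (i.e. they lie within probe_radius of an accessible node).
    """
    if params.model != "two_dielectric":
        raise ValueError("params.model must be 'two_dielectric'")
    atoms = list(atoms)
    if not atoms:
        raise ValueError("atoms must be non-empty")
    inside_vdw = np.zeros(grid.shape, dtype=bool)
    inside_inflated = np.zeros(grid.shape, dtype=bool)
    for atom in atoms:
        center = np.asarray(atom.coords)
        box = _atom_local_box(grid, center, atom.radius + params.probe_radius)
        if box is None:
            continue
        slices, axes = box
        r2 = _local_r2(axes, center)
        inside_vdw[slices] |= r2 <= atom.radius**2
        inside_inflated[slices] |= r2 <= (atom.radius + params.probe_radius) ** 2
    accessible = ~inside_inflated
    interior = inside_vdw.copy()
    shell = inside_inflated & ~inside_vdw
    if params.probe_radius > 0 and np.any(shell):
        if np.any(accessible):
            # distance from every node to the nearest accessible node
            dist = ndimage.distance_transform_edt(
                ~accessible, sampling=(grid.spacing,) * 3
            )
            interior |= shell & (dist > params.probe_radius)
        else:
            interior |= shell
    eps = np.where(interior, params.eps_in, params.eps_out)
    return ScalarField(grid, eps.astype(float))


def dielectric_map(
    atoms: Iterable[Atom], grid: GridSpec, params: DielectricParams
) -> ScalarField:
    """Dispatch on ``params.model``."""
    if params.model == "gaussian":
        return gaussian_dielectric_map(atoms, grid, params)
    return two_dielectric_map(atoms, grid, params)


def uniform_map(grid: GridSpec, eps: float) -> ScalarField:
    """A spatially uniform dielectric map (reference medium)."""
    return ScalarField(grid, np.full(grid.shape, float(eps)))
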