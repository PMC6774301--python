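"""Finite-difference variable-coefficient Poisson solver on a regular grid.

Solves div(eps grad phi) = -4*pi*C*rho at zero ionic strength, with phi in
kT/e, charge in e and length in Å (C is the Coulomb constant in kT·Å/e²).
The discretization is the standard 7-point flux stencil with the dielectric
evaluated on edges as the harmonic mean of the two adjacent node values
(harmonic averaging keeps the normal flux continuous across sharp dielectric
jumps).  Atomic charges are spread onto the 8 surrounding nodes with
trilinear weights; Dirichlet boundary values are either zero or the analytic
Coulomb potential of all charges screened by the solvent dielectric.

The linear system is symmetric positive definite and is solved either by
preconditioned conjugate gradients (default) or by red-black SOR; both
iterate to a caller-set relative-residual tolerance, and the residual is
rechecked independently after the solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg as _cg

from .constants import COULOMB_KT_ANGSTROM, FOUR_PI_C
from .errors import ConvergenceError, GridError
from .grids import GridSpec, ScalarField
from .structures import Atom


@dataclass
class ChargeGrid:
    """Charge per node (e), trilinearly spread from atom positions."""

    grid: GridSpec
    values: np.ndarray


@dataclass(frozen=True)
class SolverSettings:
    """Iteration controls for the grid Poisson solve."""

    tolerance: float = 1e-8
    max_iterations: int = 20000
    relaxation: float = 1.9
    boundary: Literal["coulombic", "zero"] = "coulombic"
    method: Literal["cg", "sor"] = "cg"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if not 0 < self.relaxation < 2:
            raise ValueError("SOR relaxation factor must be in (0, 2)")


@dataclass
class PotentialField:
    """Grid potential (kT/e) with convergence metadata."""

    grid: GridSpec
    values: np.ndarray
    converged: bool = True
    residual: float = 0.0
    iterations: int = 0


def distribute_charges(atoms: Sequence[Atom], grid: GridSpec) -> ChargeGrid:
    """Spread each atomic charge over its 8 surrounding nodes (trilinear weights).

    Raises :class:`GridError` for atoms closer than 2 nodes to the boundary.
    """
    values = np.zeros(grid.shape)
    n = np.asarray(grid.shape)
    for atom in atoms:
        f = grid.to_grid_coords(np.asarray(atom.coords))[0]
        if np.any(f < 2.0) or np.any(f > n - 3.0):
            raise GridError(
                f"atom {atom.serial} at {atom.coords} is within 2 nodes of the grid "
                f"boundary (fractional index {np.round(f, 2)})"
            )
        i0 = np.floor(f).astype(int)
        t = f - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (t[0] if dx else 1 - t[0])
                        * (t[1] if dy else 1 - t[1])
                        * (t[2] if dz else 1 - t[2])
                    )
                    values[i0[0] + dx, i0[1] + dy, i0[2] + dz] += atom.charge * w
    return ChargeGrid(grid, values)


def _boundary_mask(shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[0, :, :] = mask[-1, :, :] = True
    mask[:, 0, :] = mask[:, -1, :] = True
    mask[:, :, 0] = mask[:, :, -1] = True
    return mask


def boundary_potential(
    atoms: Sequence[Atom], grid: GridSpec, eps_out: float
) -> np.ndarray:
    """Coulombic Dirichlet values on the 6 box faces: sum_i C q_i/(eps_out r_i).

    Returns a full-grid array that is zero except on boundary nodes.
    """
    values = np.zeros(grid.shape)
    mask = _boundary_mask(grid.shape)
    charged = [a for a in atoms if a.charge != 0.0]
    if not charged:
        return values
    nodes = grid.node_coords()[mask]  # (M, 3)
    centers = np.array([a.coords for a in charged])
    charges = np.array([a.charge for a in charged])
    diff = nodes[:, None, :] - centers[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    r = np.maximum(r, 1e-9)
    phi = (COULOMB_KT_ANGSTROM / eps_out) * (charges[None, :] / r).sum(axis=1)
    values[mask] = phi
    return values


def _edge_eps(eps: np.ndarray):
    """Harmonic-mean edge dielectrics along the three axes."""
    def harm(a, b):
        return 2.0 * a * b / (a + b)

    ex = harm(eps[:-1, :, :], eps[1:, :, :])
    ey = harm(eps[:, :-1, :], eps[:, 1:, :])
    ez = harm(eps[:, :, :-1], eps[:, :, 1:])
    return ex, ey, ez


def _assemble_system(charges: ChargeGrid, eps: ScalarField, phi_b: np.ndarray):
    """Sparse SPD system A x = b over interior nodes (Dirichlet folded into b)."""
    grid = charges.grid
    nx, ny, nz = grid.shape
    h = grid.spacing
    ex, ey, ez = _edge_eps(eps.values)

    index = -np.ones(grid.shape, dtype=np.int64)
    ni, nj, nk = nx - 2, ny - 2, nz - 2
    n_int = ni * nj * nk
    index[1:-1, 1:-1, 1:-1] = np.arange(n_int).reshape(ni, nj, nk)

    b = (FOUR_PI_C / h) * charges.values[1:-1, 1:-1, 1:-1].astype(float)
    diag = np.zeros((ni, nj, nk))
    rows, cols, vals = [], [], []
    me = index[1:-1, 1:-1, 1:-1]

    # (edge coeff array sliced to interior, neighbour index array, boundary phi)
    neighbours = [
        (ex[:-1, 1:-1, 1:-1], index[0:-2, 1:-1, 1:-1], phi_b[0:-2, 1:-1, 1:-1]),
        (ex[1:, 1:-1, 1:-1], index[2:, 1:-1, 1:-1], phi_b[2:, 1:-1, 1:-1]),
        (ey[1:-1, :-1, 1:-1], index[1:-1, 0:-2, 1:-1], phi_b[1:-1, 0:-2, 1:-1]),
        (ey[1:-1, 1:, 1:-1], index[1:-1, 2:, 1:-1], phi_b[1:-1, 2:, 1:-1]),
        (ez[1:-1, 1:-1, :-1], index[1:-1, 1:-1, 0:-2], phi_b[1:-1, 1:-1, 0:-2]),
        (ez[1:-1, 1:-1, 1:], index[1:-1, 1:-1, 2:], phi_b[1:-1, 1:-1, 2:]),
    ]
    for coef, nb_idx, nb_phi in neighbours:
        diag += coef
        inner = nb_idx >= 0
        rows.append(me[inner])
        cols.append(nb_idx[inner])
        vals.append(-coef[inner])
        # Dirichlet neighbour: move known eps*phi to the right-hand side
        b += np.where(inner, 0.0, coef * nb_phi)

    rows.append(me.ravel())
    cols.append(me.ravel())
    vals.append(diag.ravel())
    A = sparse.csr_matrix(
        (np.concatenate([v.ravel() for v in vals]),
         (np.concatenate([r.ravel() for r in rows]),
          np.concatenate([c.ravel() for c in cols]))),
        shape=(n_int, n_int),
    )
    return A, b.ravel()


def _solve_sor(A, b, diag, settings: SolverSettings):
    """Red-black SOR is awkward on a CSR matrix; use classic weighted Jacobi-free
    Gauss-Seidel via matrix splitting instead (kept simple: this path exists for
    cross-checking the CG path on small systems)."""
    x = np.zeros_like(b)
    L = sparse.tril(A, k=-1, format="csr")
    U = sparse.triu(A, k=1, format="csr")
    D = diag
    omega = settings.relaxation
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return x, 0, 0.0
    it = 0
    for it in range(1, settings.max_iterations + 1):
        # (D/omega + L) x_new = b - U x - (1 - 1/omega) D x
        rhs = b - U @ x - (1.0 - 1.0 / omega) * D * x
        x = sparse.linalg.spsolve_triangular(
            (sparse.diags(D / omega) + L).tocsr(), rhs, lower=True
        )
        if it % 10 == 0 or it == settings.max_iterations:
            res = np.linalg.norm(A @ x - b) / bnorm
            if res <= settings.tolerance:
                return x, it, res
    res = float(np.linalg.norm(A @ x - b) / bnorm)
    return x, it, res


def solve_poisson(
    charges: ChargeGrid, eps: ScalarField, settings: SolverSettings | None = None,
    atoms: Sequence[Atom] | None = None,
) -> PotentialField:
    """Solve the gridded Poisson equation to the requested tolerance.

    ``atoms`` supplies the point charges for the Coulombic boundary (they
    must be the same charges that were gridded); with ``boundary='zero'``
    the box faces are grounded.
    """
    settings = settings or SolverSettings()
    grid = charges.grid
    if eps.grid != grid:
        raise ValueError("dielectric map and charge grid must share a GridSpec")
    if np.any(eps.values <= 0):
        raise ValueError("dielectric map must be positive everywhere")
    if settings.boundary == "coulombic":
        if atoms is None:
            raise ValueError("coulombic boundary requires the atom list")
        eps_out = float(np.max(eps.values))
        phi_b = boundary_potential(atoms, grid, eps_out)
    else:
        phi_b = np.zeros(grid.shape)

    A, b = _assemble_system(charges, eps, phi_b)
    diag = A.diagonal()
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        x = np.zeros_like(b)
        iters, res = 0, 0.0
    elif settings.method == "sor":
        x, iters, res = _solve_sor(A, b, diag, settings)
    else:
        counter = {"n": 0}

        def cb(_):
            counter["n"] += 1

        M = sparse.diags(1.0 / diag)
        x, info = _cg(
            A, b, rtol=settings.tolerance * 0.5, atol=0.0,
            maxiter=settings.max_iterations, M=M, callback=cb,
        )
        iters = counter["n"]
        res = float(np.linalg.norm(A @ x - b) / bnorm)

    if bnorm > 0 and res > settings.tolerance:
        raise ConvergenceError(res, iters)

    phi = phi_b.copy()
    ni, nj, nk = grid.shape[0] - 2, grid.shape[1] - 2, grid.shape[2] - 2
    phi[1:-1, 1:-1, 1:-1] = x.reshape(ni, nj, nk)
    return PotentialField(grid, phi, converged=True, residual=res, iterations=iters)


def grid_energy(potential: PotentialField, charges: ChargeGrid) -> float:
    """Grid energy 1/2 sum(q * phi) in kT.

    Includes the grid self-energy of each charge: only differences between
    systems gridded identically are physically meaningful.
    """
    if potential.grid != charges.grid:
        raise ValueError("potential and charges must share a GridSpec")
    return 0.5 * float(np.sum(charges.values * potential.values))


def potential_at_points(potential: PotentialField, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the node potential at arbitrary points."""
    f = potential.grid.to_grid_coords(np.atleast_2d(points))
    n = np.asarray(potential.grid.shape)
    if np.any(f < 1.0) or np.any(f > n - 2.0):
        raise GridError("point outside the interpolable interior of the grid")
    return ndimage.map_coordinates(potential.values, f.T, order=1, mode="nearest")


def field_at_points(potential: PotentialField, points: np.ndarray) -> np.ndarray:
    """Electric field E = -grad(phi) (kT/(e·Å)) interpolated at points.

    The gradient is taken by central differences on the nodes, then each
    component is interpolated trilinearly (exact for fields linear in space).
    """
    h = potential.grid.spacing
    grads = np.gradient(potential.values, h)
    f = potential.grid.to_grid_coords(np.atleast_2d(points))
    n = np.asarray(potential.grid.shape)
    if np.any(f < 1.0) or np.any(f > n - 2.0):
        raise GridError("point outside the interpolable interior of the grid")
    comps = [
        -ndimage.map_coordinates(g, f.T, order=1, mode="nearest") for g in grads
    ]
    return np.stack(comps, axis=-1)
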