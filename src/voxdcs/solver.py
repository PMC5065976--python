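"""Quasi-static volume-conductor solver.

Solves the DC current-conservation equation  div(sigma grad phi) = 0  on the
voxel lattice with a cell-centered 7-point finite-volume scheme.  Face
conductance between two adjacent voxels is the harmonic mean of their
conductivities times face area over center distance, which enforces current
continuity at tissue interfaces.  Voxels with sigma = 0 (exterior and
internal air) are excluded from the unknown set; their faces carry zero
conductance, which is exactly the discrete "no current into air" (insulated
skin-air / bounding-box) condition.  Electrode pad voxels are Dirichlet
nodes at +V/2 (anode) and -V/2 (cathode).

The resulting system is symmetric positive definite and is solved with
Jacobi-preconditioned conjugate gradients (deterministic: fixed assembly
order, no randomized components).  The potential is solved once at unit
inter-electrode voltage and rescaled to the target injected current by
linearity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .volume import ConductivityVolume, GridSpec

__all__ = [
    "SolverConfig",
    "PotentialField",
    "solve_potential",
    "injected_current",
    "scale_to_target",
]


class SolverError(RuntimeError):
    """Ill-posed system or non-convergence."""


@dataclass(frozen=True)
class SolverConfig:
    """Linear-solver settings.

    ``tolerance`` is the relative residual target of the conjugate-gradient
    iteration; ``voltage`` the inter-electrode Dirichlet difference used for
    the unit solve before current rescaling.
    """

    tolerance: float = 1e-8
    max_iterations: int = 50_000
    voltage: float = 1.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class PotentialField:
    """Solved electric potential phi (V) on the grid.

    ``phi`` is NaN on non-conducting voxels and on conducting voxels not
    connected to the electrode pair (no defined potential there).
    """

    grid: GridSpec
    phi: np.ndarray
    anode: np.ndarray
    cathode: np.ndarray
    residual: float
    iterations: int
    voltage: float
    scale: float = 1.0

    @property
    def mask(self) -> np.ndarray:
        """Voxels where phi is defined."""
        return np.isfinite(self.phi)


def _face_conductance(sigma: np.ndarray, axis: int, spacing_m: float) -> np.ndarray:
    """Harmonic-mean face conductance (S) between voxel i and i+1 along axis."""
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    s1 = sigma[tuple(lo)]
    s2 = sigma[tuple(hi)]
    den = s1 + s2
    with np.errstate(divide="ignore", invalid="ignore"):
        hm = np.where(den > 0, 2.0 * s1 * s2 / np.where(den > 0, den, 1.0), 0.0)
    # area / distance = spacing_m**2 / spacing_m
    return hm * spacing_m


def solve_potential(
    sigma: ConductivityVolume,
    anode: np.ndarray,
    cathode: np.ndarray,
    config: SolverConfig | None = None,
) -> PotentialField:
    """Solve for phi with Dirichlet electrodes at +-V/2.

    Raises
    ------
    SolverError
        If the electrode sets are empty, overlap, sit on non-conducting
        voxels, are not connected through conducting tissue, or the
        iteration does not reach the residual tolerance.
    """
    config = config or SolverConfig()
    s = sigma.sigma
    conducting = s > 0
    anode = np.asarray(anode, dtype=bool)
    cathode = np.asarray(cathode, dtype=bool)
    if not anode.any() or not cathode.any():
        raise SolverError("anode and cathode must be nonempty")
    if np.any(anode & cathode):
        raise SolverError("anode and cathode overlap")
    for name, mask in (("anode", anode), ("cathode", cathode)):
        if not conducting[mask].all():
            raise SolverError(f"{name} contains non-conducting voxels")

    # connectivity through conducting tissue (6-connected)
    structure = ndimage.generate_binary_structure(3, 1)
    comp, _ = ndimage.label(conducting, structure=structure)
    comp_a = np.unique(comp[anode])
    comp_c = np.unique(comp[cathode])
    if len(comp_a) != 1 or len(comp_c) != 1 or comp_a[0] != comp_c[0]:
        raise SolverError("anode and cathode are not connected by conducting tissue")
    domain = comp == comp_a[0]

    dirichlet = anode | cathode
    phi_d = np.zeros(s.shape)
    phi_d[anode] = +config.voltage / 2.0
    phi_d[cathode] = -config.voltage / 2.0

    unknown = domain & ~dirichlet
    n = int(np.count_nonzero(unknown))
    if n == 0:
        raise SolverError("no unknown voxels between the electrodes")
    index = -np.ones(s.shape, dtype=np.int64)
    index[unknown] = np.arange(n)

    spacing_m = sigma.grid.spacing * 1e-3
    diag = np.zeros(n)
    rhs = np.zeros(n)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for axis in range(3):
        g = _face_conductance(s, axis, spacing_m)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        i1 = index[tuple(lo)].ravel()
        i2 = index[tuple(hi)].ravel()
        u1 = unknown[tuple(lo)].ravel()
        u2 = unknown[tuple(hi)].ravel()
        d1 = dirichlet[tuple(lo)].ravel()
        d2 = dirichlet[tuple(hi)].ravel()
        pd1 = phi_d[tuple(lo)].ravel()
        pd2 = phi_d[tuple(hi)].ravel()
        gf = g.ravel()
        active = gf > 0

        # unknown-unknown faces: off-diagonal entries
        uu = active & u1 & u2
        rows.append(i1[uu])
        cols.append(i2[uu])
        vals.append(-gf[uu])
        np.add.at(diag, i1[uu], gf[uu])
        np.add.at(diag, i2[uu], gf[uu])

        # unknown-Dirichlet faces: diagonal plus RHS
        ud = active & u1 & d2
        np.add.at(diag, i1[ud], gf[ud])
        np.add.at(rhs, i1[ud], gf[ud] * pd2[ud])
        du = active & d1 & u2
        np.add.at(diag, i2[du], gf[du])
        np.add.at(rhs, i2[du], gf[du] * pd1[du])

    rows_a = np.concatenate(rows)
    cols_a = np.concatenate(cols)
    vals_a = np.concatenate(vals)
    A = sp.coo_matrix(
        (
            np.concatenate([vals_a, vals_a, diag]),
            (
                np.concatenate([rows_a, cols_a, np.arange(n)]),
                np.concatenate([cols_a, rows_a, np.arange(n)]),
            ),
        ),
        shape=(n, n),
    ).tocsr()

    if np.any(diag <= 0):
        raise SolverError("isolated unknown voxel with no conducting face")
    M = sp.diags(1.0 / diag)
    iters = 0

    def count(_):
        nonlocal iters
        iters += 1

    x, info = spla.cg(
        A, rhs, rtol=config.tolerance, atol=0.0,
        maxiter=config.max_iterations, M=M, callback=count,
    )
    res = float(np.linalg.norm(A @ x - rhs) / np.linalg.norm(rhs))
    if info != 0:
        raise SolverError(
            f"conjugate gradient did not converge in {config.max_iterations} "
            f"iterations (relative residual {res:.3e})"
        )

    phi = np.full(s.shape, np.nan)
    phi[unknown] = x
    phi[dirichlet] = phi_d[dirichlet]
    return PotentialField(
        grid=sigma.grid, phi=phi, anode=anode, cathode=cathode,
        residual=res, iterations=iters, voltage=config.voltage,
    )


def injected_current(
    phi: PotentialField, sigma: ConductivityVolume, electrode: np.ndarray
) -> float:
    """Net current (A) flowing out of ``electrode`` into the rest of the body.

    Sums the face fluxes g * (phi_e - phi_neighbor) over every conducting
    face between an electrode voxel and a non-electrode voxel.  Positive out
    of the anode with the solver's sign convention.
    """
    electrode = np.asarray(electrode, dtype=bool)
    if not np.isfinite(phi.phi[electrode]).all():
        raise SolverError("electrode potential undefined; field not solved")
    spacing_m = phi.grid.spacing * 1e-3
    p = np.nan_to_num(phi.phi, nan=0.0)
    defined = phi.mask
    total = 0.0
    for axis in range(3):
        g = _face_conductance(sigma.sigma, axis, spacing_m)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        e1 = electrode[tuple(lo)]
        e2 = electrode[tuple(hi)]
        ok = defined[tuple(lo)] & defined[tuple(hi)]
        dphi = p[tuple(lo)] - p[tuple(hi)]
        out12 = (e1 & ~e2 & ok) * g * dphi      # flux leaving electrode at low side
        out21 = (e2 & ~e1 & ok) * g * (-dphi)   # flux leaving electrode at high side
        total += float(out12.sum() + out21.sum())
    return total


def scale_to_target(
    phi: PotentialField, i_raw: float, i_target: float
) -> PotentialField:
    """Rescale phi by i_target / i_raw (linearity of the Laplace problem)."""
    if i_raw == 0:
        raise SolverError("raw injected current is zero (open circuit)")
    k = i_target / i_raw
    return replace(
        phi, phi=phi.phi * k, voltage=phi.voltage * k, scale=phi.scale * k
    )
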