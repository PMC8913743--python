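"""Full-domain frequency-domain Maxwell reference solver (the validation oracle).

The discretized Maxwell system on the Yee grid,

    -∇×H + (σ + iωε) E = -J^source
     ∇×E + iωμ0 H      = 0,

is assembled with the staggered edge/face curl stencils and a perfect electric
conductor (PEC) outer box: ghost edges beyond the high faces are zero, and the
phantom must keep a vacuum buffer so the box does not influence the region of
interest.  Eliminating H yields the complex-symmetric curl-curl system

    (Cᵀ C + iωμ0 diag(σ_e + iω ε_e)) E = -iωμ0 J^source

which is solved with a sparse direct factorization (the brute-force "solve the
whole domain again" reference the fast update is validated against).  The
module also materializes the explicit library matrix Z on small problems and
evaluates the Sherman-Morrison-Woodbury update with dense algebra, so the
identity underlying the matrix-free method can be checked end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import MU0
from .grid import MaterialMap, SupportSet, YeeGrid, average_to_edges

_DIRECT_LIMIT_VOX = 33**3  # direct factorization default up to ~32³ voxels


def build_curl_matrix(grid: YeeGrid) -> sp.csr_matrix:
    """Sparse edge→face curl C with ghost (PEC) zeros beyond the high faces."""
    nx, ny, nz = grid.shape
    dx, dy, dz = grid.resolution
    nv = grid.nvox
    idx = np.indices(grid.shape)
    I, J, K = (a.ravel() for a in idx)
    ones = np.ones(nv, dtype=bool)

    def eid(c, i, j, k):
        return c * nv + i + nx * (j + ny * k)

    rows, cols, vals = [], [], []

    def add(r, c, v, valid):
        rows.append(r[valid])
        cols.append(c[valid])
        vals.append(np.full(int(valid.sum()), v))

    # Hx face: dy Ez - dz Ey
    r = eid(0, I, J, K)
    add(r, eid(2, I, np.minimum(J + 1, ny - 1), K), 1 / dy, J + 1 < ny)
    add(r, eid(2, I, J, K), -1 / dy, ones)
    add(r, eid(1, I, J, np.minimum(K + 1, nz - 1)), -1 / dz, K + 1 < nz)
    add(r, eid(1, I, J, K), 1 / dz, ones)
    # Hy face: dz Ex - dx Ez
    r = eid(1, I, J, K)
    add(r, eid(0, I, J, np.minimum(K + 1, nz - 1)), 1 / dz, K + 1 < nz)
    add(r, eid(0, I, J, K), -1 / dz, ones)
    add(r, eid(2, np.minimum(I + 1, nx - 1), J, K), -1 / dx, I + 1 < nx)
    add(r, eid(2, I, J, K), 1 / dx, ones)
    # Hz face: dx Ey - dy Ex
    r = eid(2, I, J, K)
    add(r, eid(1, np.minimum(I + 1, nx - 1), J, K), 1 / dx, I + 1 < nx)
    add(r, eid(1, I, J, K), -1 / dx, ones)
    add(r, eid(0, I, np.minimum(J + 1, ny - 1), K), -1 / dy, J + 1 < ny)
    add(r, eid(0, I, J, K), 1 / dy, ones)

    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * nv, 3 * nv),
    )


@dataclass
class MaxwellOperator:
    """Assembled frequency-domain system for one grid + material map."""

    grid: YeeGrid
    curl: sp.csr_matrix  # edge→face curl C (face→edge curl is Cᵀ)
    material_diag: np.ndarray  # σ_e + iω ε_e per edge (flat, length N)
    system: sp.csc_matrix  # CᵀC + iωμ0 diag(material) — the E-only reduction

    _lu: spla.SuperLU | None = None

    def factorize(self) -> spla.SuperLU:
        if self._lu is None:
            self._lu = spla.splu(self.system)
        return self._lu

    def block_matrix(self) -> sp.csc_matrix:
        """The unreduced [[diag(σ+iωε), -Cᵀ], [C, iωμ0 I]] block system."""
        n = self.grid.edge_count
        ce = sp.diags(self.material_diag)
        return sp.bmat([[ce, -self.curl.T], [self.curl, 1j * self.grid.omega * MU0 * sp.identity(n)]]).tocsc()


def assemble(grid: YeeGrid, materials: MaterialMap) -> MaxwellOperator:
    """Assemble the curl-curl system for a material map (PEC outer box)."""
    sigma_e, eps_e = average_to_edges(materials, grid)
    omega = grid.omega
    diag = grid.ravel_edges(sigma_e + 1j * omega * eps_e)
    if not np.all(np.isfinite(diag)):
        raise ValueError("non-finite material coefficients")
    curl = build_curl_matrix(grid)
    system = (curl.T @ curl).tocsc().astype(complex) + 1j * omega * MU0 * sp.diags(diag, format="csc")
    return MaxwellOperator(grid, curl, diag, system.tocsc())


def solve_full(operator: MaxwellOperator, q: np.ndarray, tol: float = 1e-10):
    """Solve for the edge E-field (and face H-field) of a source current q.

    ``q`` is the source current density on edges [A/m²], shape (3,nx,ny,nz).
    A sparse direct factorization is used on desk-scale grids; larger systems
    fall back to preconditioned BiCGSTAB with relative tolerance ``tol``.
    """
    grid = operator.grid
    rhs = -1j * grid.omega * MU0 * grid.ravel_edges(np.asarray(q, dtype=complex))
    if not rhs.any():
        zeros = np.zeros((3, *grid.shape), dtype=complex)
        return zeros, zeros.copy()
    if grid.nvox <= _DIRECT_LIMIT_VOX:
        E_flat = operator.factorize().solve(rhs)
    else:
        ilu = spla.spilu(operator.system, drop_tol=1e-5, fill_factor=20)
        prec = spla.LinearOperator(operator.system.shape, ilu.solve)
        E_flat, info = spla.bicgstab(operator.system, rhs, rtol=tol, maxiter=5000, M=prec)
        if info != 0:
            raise RuntimeError(f"iterative full-domain solve failed (info={info})")
    H_flat = -(operator.curl @ E_flat) / (1j * grid.omega * MU0)
    return grid.unravel_edges(E_flat), grid.unravel_edges(H_flat)


def build_library_explicit(operator_bg: MaxwellOperator, support: SupportSet) -> np.ndarray:
    """Explicit N×M library matrix Z: column j is the field of a unit current
    density at support edge j (dense; tiny problems only)."""
    grid = operator_bg.grid
    N, M = grid.edge_count, support.M
    if N * M > 10**7:
        raise ValueError(f"explicit library of {N}x{M} entries exceeds the 1e7 guard; use the matrix-free path")
    if M == 0:
        return np.zeros((N, 0), dtype=complex)
    rhs = np.zeros((N, M), dtype=complex)
    rhs[support.edge_indices, np.arange(M)] = -1j * grid.omega * MU0
    return operator_bg.factorize().solve(rhs)


def smw_direct(f_bg: np.ndarray, Z: np.ndarray, C_imp, support: SupportSet) -> np.ndarray:
    """Dense Sherman-Morrison-Woodbury update f = f^bg + Z(I - C̃SᵀZ)⁻¹C̃Sᵀf^bg.

    ``C_imp`` is the implant :class:`~perturbrf.grid.ContrastOperator`; its
    admittivity form (σ + iωΔε per support edge) is the coefficient the
    low-rank identity uses.
    """
    grid = support.grid
    f_flat = grid.ravel_edges(f_bg) if f_bg.ndim == 4 else np.asarray(f_bg)
    adm = C_imp.admittivity
    M = support.M
    if M == 0 or not adm.any():
        return f_bg.copy()
    A_small = np.eye(M, dtype=complex) - adm[:, None] * Z[support.edge_indices, :]
    rhs = adm * f_flat[support.edge_indices]
    cond = np.linalg.cond(A_small)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(f"reduced SMW system is numerically singular (cond={cond:.2e})")
    u = np.linalg.solve(A_small, rhs)
    f_new = f_flat + Z @ u
    return grid.unravel_edges(f_new) if f_bg.ndim == 4 else f_new
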