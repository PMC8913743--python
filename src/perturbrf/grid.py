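"""Uniform Yee grid, edge indexing, material maps and contrast operators.

The electric field lives on voxel edges of a staggered (Yee) grid.  Each voxel
``(i, j, k)`` owns the three edges that emanate from its low corner node:

* x-edge at ``((i+1/2)dx, j dy, k dz)``
* y-edge at ``(i dx, (j+1/2)dy, k dz)``
* z-edge at ``(i dx, j dy, (k+1/2)dz)``

so the total number of E-edges is ``N = 3 * nx * ny * nz``.  Edges on the high
faces of the bounding box are ghosts held at zero (a perfect-electric-conductor
outer box); phantoms must keep their outermost voxel layer vacuum.

Edge fields are stored as complex arrays of shape ``(3, nx, ny, nz)``; the flat
index of edge ``(c, i, j, k)`` is ``c*nvox + i + nx*(j + ny*k)`` (x fastest).

Materials are isotropic and non-magnetic: conductivity σ [S/m], relative
permittivity εr, and mass density ρm [kg/m³] per voxel.  The complex contrast
coefficient used throughout the package is

    chi(e) = -iω μ0 (σ_e + iω(ε_e - ε0))

with σ_e, ε_e edge-averaged properties; ``chi`` is the coefficient that
multiplies E in the volume-integral scattering operator.  The admittivity form
``chi / (-iω μ0) = σ_e + iωΔε_e`` [S/m] is what enters the low-rank
(Sherman-Morrison-Woodbury) update, where currents are physical densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import C0, EPS0, MU0


@dataclass(frozen=True)
class YeeGrid:
    """Uniform staggered grid with derived electromagnetic constants."""

    shape: tuple[int, int, int]
    resolution: tuple[float, float, float]
    frequency: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        res = tuple(float(r) for r in self.resolution)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "resolution", res)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three positive integers, got {shape}")
        if len(res) != 3 or any(r <= 0 for r in res):
            raise ValueError(f"grid resolution must be positive, got {res}")
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")

    # -- derived constants -------------------------------------------------
    @property
    def omega(self) -> float:
        """Angular frequency ω = 2πf [rad/s]."""
        return 2.0 * np.pi * self.frequency

    @property
    def k_b(self) -> float:
        """Vacuum wavenumber ω/c [rad/m]."""
        return self.omega / C0

    @property
    def nvox(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def edge_count(self) -> int:
        """Total number of owned E-edges, N = 3 nvox."""
        return 3 * self.nvox

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.resolution
        return dx * dy * dz

    @property
    def is_uniform(self) -> bool:
        dx, dy, dz = self.resolution
        return np.isclose(dx, dy) and np.isclose(dy, dz)

    # -- edge indexing ------------------------------------------------------
    def edge_index(self, component, i, j, k):
        """Flat edge index of edge ``(component, i, j, k)`` (vectorized)."""
        component = np.asarray(component)
        i, j, k = np.asarray(i), np.asarray(j), np.asarray(k)
        nx, ny, nz = self.shape
        if np.any((component < 0) | (component > 2)):
            raise IndexError("edge component must be 0, 1 or 2")
        if np.any((i < 0) | (i >= nx) | (j < 0) | (j >= ny) | (k < 0) | (k >= nz)):
            raise IndexError("edge voxel index out of range")
        return component * self.nvox + i + nx * (j + ny * k)

    def edge_tuple(self, index):
        """Inverse of :meth:`edge_index` (vectorized)."""
        index = np.asarray(index)
        if np.any((index < 0) | (index >= self.edge_count)):
            raise IndexError("flat edge index out of range")
        nx, ny, _ = self.shape
        component, rest = divmod(index, self.nvox)
        k, rest = divmod(rest, nx * ny)
        j, i = divmod(rest, nx)
        return component, i, j, k

    def edge_positions(self, component: int) -> np.ndarray:
        """Physical positions of all edges of one component, shape (nx,ny,nz,3)."""
        dx, dy, dz = self.resolution
        half = np.zeros(3)
        half[component] = 0.5
        idx = np.indices(self.shape).astype(float)
        pos = np.stack(
            [
                (idx[0] + half[0]) * dx + self.origin[0],
                (idx[1] + half[1]) * dy + self.origin[1],
                (idx[2] + half[2]) * dz + self.origin[2],
            ],
            axis=-1,
        )
        return pos

    def voxel_centers(self) -> np.ndarray:
        dx, dy, dz = self.resolution
        idx = np.indices(self.shape).astype(float) + 0.5
        return np.stack(
            [idx[0] * dx + self.origin[0], idx[1] * dy + self.origin[1], idx[2] * dz + self.origin[2]],
            axis=-1,
        )

    def ravel_edges(self, field: np.ndarray) -> np.ndarray:
        """Flatten an edge field (3,nx,ny,nz) to length N (x fastest)."""
        if field.shape != (3, *self.shape):
            raise ValueError(f"edge field shape {field.shape} does not match grid {self.shape}")
        return field.reshape(3, -1, order="F").ravel()

    def unravel_edges(self, flat: np.ndarray) -> np.ndarray:
        if flat.shape != (self.edge_count,):
            raise ValueError(f"flat edge vector length {flat.shape} != N={self.edge_count}")
        return flat.reshape(3, self.nvox).reshape((3, *self.shape), order="F")


def build_grid(shape, resolution, frequency, origin=(0.0, 0.0, 0.0)) -> YeeGrid:
    """Validate and construct a :class:`YeeGrid`.

    ``resolution`` may be a scalar (isotropic) or a length-3 sequence [m].
    """
    if np.isscalar(resolution):
        resolution = (float(resolution),) * 3
    return YeeGrid(tuple(shape), tuple(resolution), float(frequency), tuple(origin))


@dataclass
class MaterialMap:
    """Voxelized isotropic material properties."""

    sigma: np.ndarray  # [S/m]
    eps_r: np.ndarray  # [-]
    rho_m: np.ndarray  # [kg/m^3]

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.eps_r = np.asarray(self.eps_r, dtype=float)
        self.rho_m = np.asarray(self.rho_m, dtype=float)
        if not (self.sigma.shape == self.eps_r.shape == self.rho_m.shape):
            raise ValueError("material arrays must share one voxel shape")
        if np.any(self.sigma < 0):
            raise ValueError("conductivity must be non-negative")
        if np.any(self.eps_r < 1):
            raise ValueError("relative permittivity must be >= 1")
        if np.any(self.rho_m < 0):
            raise ValueError("mass density must be non-negative")

    @property
    def shape(self):
        return self.sigma.shape

    @classmethod
    def vacuum(cls, shape) -> "MaterialMap":
        return cls(np.zeros(shape), np.ones(shape), np.zeros(shape))

    def with_implant(self, mask: np.ndarray, sigma: float, eps_r: float, rho_m: float | None = None) -> "MaterialMap":
        """Return a copy where masked voxels are replaced by the implant material."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.shape:
            raise ValueError("implant mask shape does not match material map")
        out = MaterialMap(self.sigma.copy(), self.eps_r.copy(), self.rho_m.copy())
        out.sigma[mask] = sigma
        out.eps_r[mask] = eps_r
        if rho_m is not None:
            out.rho_m[mask] = rho_m
        return out


def _edge_average(voxel: np.ndarray, component: int, fill: float) -> np.ndarray:
    """Average a voxel quantity onto edges of one component.

    The edge ``(c, i, j, k)`` is shared by the up-to-four voxels obtained by
    stepping one voxel backwards along the two directions transverse to ``c``;
    neighbours outside the domain count as vacuum (``fill``).
    """
    axes = [ax for ax in range(3) if ax != component]
    padded = np.pad(voxel, [(1, 0) if ax in axes else (0, 0) for ax in range(3)], constant_values=fill)
    acc = np.zeros(voxel.shape, dtype=voxel.dtype)
    for da in (0, 1):
        for db in (0, 1):
            sl = [slice(None)] * 3
            sl[axes[0]] = slice(da, voxel.shape[axes[0]] + da)
            sl[axes[1]] = slice(db, voxel.shape[axes[1]] + db)
            acc += padded[tuple(sl)]
    return acc / 4.0


def average_to_edges(materials: MaterialMap, grid: YeeGrid):
    """Edge-averaged (σ_e, ε_e) with ε_e the *absolute* permittivity [F/m].

    Returns two arrays of shape (3, nx, ny, nz).  The arithmetic four-voxel
    mean mirrors the dielectric edge averaging of Yee-grid FDTD solvers.
    """
    if materials.shape != grid.shape:
        raise ValueError(f"material shape {materials.shape} != grid shape {grid.shape}")
    eps_abs = materials.eps_r * EPS0
    sigma_e = np.stack([_edge_average(materials.sigma, c, 0.0) for c in range(3)])
    eps_e = np.stack([_edge_average(eps_abs, c, EPS0) for c in range(3)])
    return sigma_e, eps_e


@dataclass
class SupportSet:
    """The M implant edges; realizes the selector S / S^T as gather/scatter."""

    edge_indices: np.ndarray
    grid: YeeGrid

    def __post_init__(self):
        idx = np.asarray(self.edge_indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("edge indices must be one-dimensional")
        if idx.size and (np.any(np.diff(idx) <= 0)):
            raise ValueError("edge indices must be strictly increasing")
        if idx.size and (idx[0] < 0 or idx[-1] >= self.grid.edge_count):
            raise ValueError("edge index out of range")
        self.edge_indices = idx

    @property
    def M(self) -> int:
        return int(self.edge_indices.size)

    def gather(self, flat_field: np.ndarray) -> np.ndarray:
        """S^T f: restrict a full edge vector to the support (length M)."""
        return np.asarray(flat_field)[self.edge_indices]

    def scatter(self, values: np.ndarray) -> np.ndarray:
        """S x: embed a length-M vector into the full edge space."""
        values = np.asarray(values)
        if values.shape != (self.M,):
            raise ValueError(f"expected length-{self.M} vector, got {values.shape}")
        out = np.zeros(self.grid.edge_count, dtype=np.result_type(values.dtype, np.complex128))
        out[self.edge_indices] = values
        return out


def build_support(implant_mask: np.ndarray, grid: YeeGrid) -> SupportSet:
    """All distinct edges adjacent to masked voxels (12 per voxel, deduplicated)."""
    mask = np.asarray(implant_mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    vi, vj, vk = np.nonzero(mask)
    if vi.size == 0:
        return SupportSet(np.empty(0, dtype=np.int64), grid)
    nx, ny, nz = grid.shape
    if np.any(vi + 1 >= nx) or np.any(vj + 1 >= ny) or np.any(vk + 1 >= nz):
        raise ValueError("implant touches the high domain boundary; keep the outer voxel layer vacuum")
    chunks = []
    # 4 x-edges per voxel: (0, i, j+{0,1}, k+{0,1}); analogous for y, z
    for c, (a1, a2) in ((0, (1, 2)), (1, (0, 2)), (2, (0, 1))):
        base = [vi, vj, vk]
        for d1 in (0, 1):
            for d2 in (0, 1):
                ijk = [b.copy() for b in base]
                ijk[a1] += d1
                ijk[a2] += d2
                chunks.append(grid.edge_index(np.full(vi.shape, c), *ijk))
    return SupportSet(np.unique(np.concatenate(chunks)), grid)


@dataclass
class ContrastOperator:
    """Diagonal complex contrast coefficients chi per edge.

    ``kind='background'`` holds chi on every edge (shape (3,nx,ny,nz));
    ``kind='implant'`` holds the additive contrast (implant minus background)
    on the support edges only (length M).
    """

    values: np.ndarray
    kind: str
    support: SupportSet | None = field(default=None)

    def __post_init__(self):
        if self.kind not in ("background", "implant"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=complex)
        if self.kind == "implant":
            if self.support is None:
                raise ValueError("implant contrast requires a support set")
            if self.values.shape != (self.support.M,):
                raise ValueError("implant contrast length must equal M")

    @property
    def admittivity(self) -> np.ndarray:
        """chi / (-iωμ0) = σ_e + iωΔε_e [S/m], the SMW-update coefficient."""
        grid = self.support.grid if self.support is not None else None
        if grid is None:
            raise ValueError("admittivity scaling requires grid context (implant kind)")
        return self.values / (-1j * grid.omega * MU0)


def edge_chi(materials: MaterialMap, grid: YeeGrid) -> np.ndarray:
    """chi = -iωμ0 (σ_e + iω(ε_e - ε0)) on every edge, shape (3,nx,ny,nz)."""
    sigma_e, eps_e = average_to_edges(materials, grid)
    omega = grid.omega
    return -1j * omega * MU0 * (sigma_e + 1j * omega * (eps_e - EPS0))


def build_contrast(
    materials: MaterialMap,
    grid: YeeGrid,
    kind: str = "background",
    support: SupportSet | None = None,
    implant_materials: MaterialMap | None = None,
) -> ContrastOperator:
    """Construct the background or (additive) implant contrast operator.

    For ``kind='implant'`` pass the background map as ``materials``, the map
    with the implant rasterized in as ``implant_materials``, and the implant
    :class:`SupportSet`; the result is chi(implant) - chi(background) gathered
    onto the support edges.
    """
    if kind == "background":
        return ContrastOperator(edge_chi(materials, grid), "background")
    if kind != "implant":
        raise ValueError(f"unknown contrast kind {kind!r}")
    if support is None or implant_materials is None:
        raise ValueError("implant contrast requires support set and implant materials")
    delta = edge_chi(implant_materials, grid) - edge_chi(materials, grid)
    values = support.gather(grid.ravel_edges(delta))
    return ContrastOperator(values, "implant", support)
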