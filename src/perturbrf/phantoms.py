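"""Synthetic phantoms, coil sources and implant geometries.

Everything is parameterized in whole voxels so that runs are exactly
reproducible from a JSON spec.  Phantom bodies stand in for anatomical body
models at desk scale; implants are simple parametric shapes (rod, plate,
hollow wire cage) emulating the geometry classes of real devices — elongated
conductors are the class known to enhance fields at their tips.  Sources are
closed square current loops (discretely divergence-free) or straight dipole
segments placed in vacuum, far enough from tissue that the implant's
scattered field is negligible at the source (the small-perturbation premise:
the coil current is treated as unchanged by the implant).
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .grid import MaterialMap, YeeGrid, build_grid

TITANIUM_SIGMA = 2.4e6  # [S/m] titanium-like default implant metal
TITANIUM_RHO = 4500.0  # [kg/m³]


class MaterialSpec(BaseModel):
    sigma: float = Field(ge=0)
    eps_r: float = Field(ge=1)
    rho_m: float = Field(ge=0, default=0.0)


class BodySpec(BaseModel):
    shape: Literal["slab", "sphere", "cylinder"]
    material: MaterialSpec
    # slab: an axis-aligned layer spanning the interior transversally,
    # inset `t_margin` voxels from the domain box on the transverse axes
    axis: int = Field(default=2, ge=0, le=2)
    lo: int = 0
    hi: int = 0  # inclusive voxel range along `axis` (slab/cylinder extent)
    t_margin: int = Field(default=1, ge=1)
    center: tuple[int, int, int] | None = None  # sphere/cylinder center voxel
    radius: float = 0.0  # voxels


class GridSpec(BaseModel):
    shape: tuple[int, int, int]
    resolution_mm: float = Field(gt=0)
    frequency_mhz: float = Field(gt=0)

    def build(self) -> YeeGrid:
        return build_grid(self.shape, self.resolution_mm * 1e-3, self.frequency_mhz * 1e6)


class PhantomSpec(BaseModel):
    grid: GridSpec
    bodies: list[BodySpec] = []
    seed: int = 0


class CoilSpec(BaseModel):
    type: Literal["loop", "dipole"]
    center: tuple[int, int, int]  # node (loop) / start voxel (dipole)
    axis: int = Field(default=2, ge=0, le=2)  # loop normal / dipole direction
    radius: int = Field(default=5, ge=1)  # loop half-side [voxels]
    length: int = Field(default=1, ge=1)  # dipole length [edges]
    current: float = 1.0  # [A]


class ImplantSpec(BaseModel):
    shape: Literal["rod", "plate", "wire_cage", "mask_file"]
    start: tuple[int, int, int] = (0, 0, 0)
    axis: int = Field(default=0, ge=0, le=2)
    length: int = Field(default=10, ge=1)
    size: tuple[int, int, int] = (1, 1, 1)  # plate/wire_cage extents [voxels]
    path: str | None = None  # mask_file: HDF5 file with boolean dataset /mask
    material: MaterialSpec = MaterialSpec(sigma=TITANIUM_SIGMA, eps_r=1.0, rho_m=TITANIUM_RHO)

    @model_validator(mode="after")
    def _consistent(self):
        if any(s < 1 for s in self.size):
            raise ValueError("implant size must be positive voxels")
        if self.shape == "mask_file" and not self.path:
            raise ValueError("mask_file implants require a path")
        return self


def _check_interior(mask: np.ndarray, what: str):
    nx, ny, nz = mask.shape
    border = np.zeros_like(mask)
    border[0], border[-1] = True, True
    border[:, 0], border[:, -1] = True, True
    border[:, :, 0], border[:, :, -1] = True, True
    if np.any(mask & border):
        raise ValueError(f"{what} touches the outermost voxel layer, which must stay vacuum")


def make_phantom(spec: PhantomSpec) -> tuple[MaterialMap, YeeGrid]:
    """Rasterize the bodies (in order; overlapping bodies: last wins)."""
    grid = spec.grid.build()
    mat = MaterialMap.vacuum(grid.shape)
    idx = np.indices(grid.shape)
    for body in spec.bodies:
        if body.shape == "slab":
            inside = (idx[body.axis] >= body.lo) & (idx[body.axis] <= body.hi)
            for ax in range(3):
                if ax != body.axis:
                    inside &= (idx[ax] >= body.t_margin) & (idx[ax] <= grid.shape[ax] - 1 - body.t_margin)
        elif body.shape == "sphere":
            if body.center is None:
                raise ValueError("sphere body requires a center")
            d2 = sum((idx[a] - body.center[a]) ** 2 for a in range(3))
            inside = d2 <= body.radius**2
        else:  # cylinder
            if body.center is None:
                raise ValueError("cylinder body requires a center")
            trans = [a for a in range(3) if a != body.axis]
            d2 = sum((idx[a] - body.center[a]) ** 2 for a in trans)
            inside = (d2 <= body.radius**2) & (idx[body.axis] >= body.lo) & (idx[body.axis] <= body.hi)
        _check_interior(inside, f"{body.shape} body")
        mat.sigma[inside] = body.material.sigma
        mat.eps_r[inside] = body.material.eps_r
        mat.rho_m[inside] = body.material.rho_m
    return mat, grid


def make_source(spec: CoilSpec, grid: YeeGrid) -> np.ndarray:
    """Edge current-density array q [A/m²] for a loop or dipole source.

    Loop: a closed square circulation of half-side ``radius`` voxels in the
    plane normal to ``axis`` — its discrete node divergence vanishes exactly.
    Dipole: ``length`` collinear edges along ``axis``.
    """
    q = np.zeros((3, *grid.shape), dtype=complex)
    dx, dy, dz = grid.resolution
    areas = (dy * dz, dx * dz, dx * dy)
    if spec.type == "dipole":
        J = spec.current / areas[spec.axis]
        i, j, k = spec.center
        for step in range(spec.length):
            pos = [i, j, k]
            pos[spec.axis] += step
            if any(p < 0 or p >= n for p, n in zip(pos, grid.shape)):
                raise ValueError("dipole extends outside the grid")
            q[(spec.axis, *pos)] = J
        return q
    # loop
    n_ax = spec.axis
    t1, t2 = (a for a in range(3) if a != n_ax)
    c = list(spec.center)
    R = spec.radius
    lo1, hi1 = c[t1] - R, c[t1] + R
    lo2, hi2 = c[t2] - R, c[t2] + R
    if lo1 < 0 or lo2 < 0 or hi1 >= grid.shape[t1] or hi2 >= grid.shape[t2]:
        raise ValueError("loop extends outside the grid")
    if c[n_ax] < 0 or c[n_ax] >= grid.shape[n_ax]:
        raise ValueError("loop plane outside the grid")
    J1 = spec.current / areas[t1]
    J2 = spec.current / areas[t2]
    # circulate: +t1 along lo2, +t2 along hi1, -t1 along hi2, -t2 along lo1
    for p in range(lo1, hi1):
        pos = [0, 0, 0]
        pos[n_ax] = c[n_ax]
        pos[t2] = lo2
        pos[t1] = p
        q[(t1, *pos)] += J1
        pos[t2] = hi2
        q[(t1, *pos)] -= J1
    for p in range(lo2, hi2):
        pos = [0, 0, 0]
        pos[n_ax] = c[n_ax]
        pos[t1] = hi1
        pos[t2] = p
        q[(t2, *pos)] += J2
        pos[t1] = lo1
        q[(t2, *pos)] -= J2
    return q


def source_tissue_distance(q: np.ndarray, materials: MaterialMap) -> float:
    """Minimum voxel-index distance between source edges and tissue voxels."""
    src = np.argwhere(np.any(q != 0, axis=0))
    tissue = np.argwhere((materials.sigma > 0) | (materials.eps_r > 1))
    if src.size == 0 or tissue.size == 0:
        return np.inf
    d2min = np.inf
    for s in src:
        d2 = np.sum((tissue - s) ** 2, axis=1).min()
        d2min = min(d2min, d2)
    return float(np.sqrt(d2min))


def make_implant(spec: ImplantSpec, grid: YeeGrid) -> tuple[np.ndarray, MaterialSpec]:
    """Boolean implant voxel mask + material."""
    if spec.shape == "mask_file":
        import h5py

        with h5py.File(spec.path, "r") as fh:
            mask = fh["mask"][()].astype(bool)
        if mask.shape != grid.shape:
            raise ValueError(f"mask file shape {mask.shape} != grid shape {grid.shape}")
        _check_interior(mask, "implant")
        return mask, spec.material
    mask = np.zeros(grid.shape, dtype=bool)
    i0, j0, k0 = spec.start
    if spec.shape == "rod":
        ext = [1, 1, 1]
        ext[spec.axis] = spec.length
    else:
        ext = list(spec.size)
    sl = tuple(slice(s, s + e) for s, e in zip(spec.start, ext))
    if any(s < 0 for s in spec.start) or any(s + e > n for s, e, n in zip(spec.start, ext, grid.shape)):
        raise ValueError("implant extends outside the grid")
    if spec.shape in ("rod", "plate"):
        mask[sl] = True
    else:  # wire_cage: hollow box shell
        mask[sl] = True
        inner = tuple(slice(s + 1, s + e - 1) for s, e in zip(spec.start, ext))
        if all(e > 2 for e in ext):
            mask[inner] = False
    _check_interior(mask, "implant")
    return mask, spec.material


# -- canonical study setups -------------------------------------------------


def standard_test_phantom():
    """The package's canonical desk-scale validation setup.

    A 24³ grid at 5 mm / 64 MHz (1.5 T): a two-voxel-thick lossy tissue slab
    (σ = 0.5 S/m, εr = 50, ρm = 1000 kg/m³) kept three voxels clear of the
    outer box (the reference solver's conducting boundary must not touch
    tissue), a 10-voxel titanium rod embedded in the upper slab layer, and a
    square current loop 9 voxels above the tissue (normal z, 1 A).  Returns a
    dict with grid, materials, source q, implant mask and implant material.
    """
    spec = PhantomSpec(
        grid=GridSpec(shape=(24, 24, 24), resolution_mm=5.0, frequency_mhz=64.0),
        bodies=[
            BodySpec(
                shape="slab",
                axis=2,
                lo=6,
                hi=7,
                t_margin=3,
                material=MaterialSpec(sigma=0.5, eps_r=50.0, rho_m=1000.0),
            )
        ],
    )
    materials, grid = make_phantom(spec)
    coil = CoilSpec(type="loop", center=(12, 12, 17), axis=2, radius=5, current=1.0)
    q = make_source(coil, grid)
    # the rod lies in the top slab layer directly beneath one loop leg, i.e.
    # parallel to the strongest tangential E — the elongated-conductor
    # configuration whose tip fields the update method must capture
    implant = ImplantSpec(
        shape="rod",
        start=(7, 7, 7),
        axis=0,
        length=10,
        material=MaterialSpec(sigma=TITANIUM_SIGMA, eps_r=1.0, rho_m=TITANIUM_RHO),
    )
    mask, metal = make_implant(implant, grid)
    assert source_tissue_distance(q, materials) >= 8.0
    return {
        "grid": grid,
        "materials": materials,
        "q": q,
        "implant_mask": mask,
        "implant_material": metal,
        "phantom_spec": spec,
        "coil_spec": coil,
        "implant_spec": implant,
    }


def tiny_test_phantom():
    """A fast 12³ setup for matrix-free vs explicit-library cross checks."""
    spec = PhantomSpec(
        grid=GridSpec(shape=(12, 12, 12), resolution_mm=5.0, frequency_mhz=64.0),
        bodies=[
            BodySpec(
                shape="sphere",
                center=(6, 6, 5),
                radius=3.2,
                material=MaterialSpec(sigma=0.3, eps_r=20.0, rho_m=1000.0),
            )
        ],
    )
    materials, grid = make_phantom(spec)
    coil = CoilSpec(type="dipole", center=(5, 6, 10), axis=0, length=2, current=1.0)
    q = make_source(coil, grid)
    implant = ImplantSpec(
        shape="rod",
        start=(5, 6, 5),
        axis=0,
        length=2,
        material=MaterialSpec(sigma=1e4, eps_r=1.0, rho_m=TITANIUM_RHO),
    )
    mask, metal = make_implant(implant, grid)
    return {
        "grid": grid,
        "materials": materials,
        "q": q,
        "implant_mask": mask,
        "implant_material": metal,
        "phantom_spec": spec,
        "coil_spec": coil,
        "implant_spec": implant,
    }


def random_phantom(seed: int, max_shape: int = 14):
    """A randomized small phantom + implant + source for property-based checks.

    Deterministic given ``seed``; implants stay small (a few voxels) so the
    explicit library matrix is cheap to build.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, max_shape + 1))
    shape = (n, n, n)
    grid = build_grid(shape, 5e-3, float(rng.uniform(40e6, 130e6)))
    materials = MaterialMap.vacuum(shape)
    # one random lossy block in the interior
    lo = rng.integers(2, n - 6, size=3)
    ext = rng.integers(3, 5, size=3)
    hi = np.minimum(lo + ext, n - 2)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    materials.sigma[sl] = rng.uniform(0.1, 0.8)
    materials.eps_r[sl] = rng.uniform(2.0, 60.0)
    materials.rho_m[sl] = 1000.0
    # implant: 1-3 voxel rod inside the block
    length = int(rng.integers(1, 4))
    axis = int(rng.integers(0, 3))
    start = [int(np.clip(rng.integers(lo[a], hi[a]), 1, n - 3)) for a in range(3)]
    start[axis] = int(np.clip(start[axis], 1, n - 2 - length))
    mask = np.zeros(shape, dtype=bool)
    pos = list(start)
    for s in range(length):
        pos[axis] = start[axis] + s
        mask[tuple(pos)] = True
    implant_material = MaterialSpec(
        sigma=float(10 ** rng.uniform(2, 6)), eps_r=1.0, rho_m=TITANIUM_RHO
    )
    # dipole source in the vacuum above the block
    src = (int(rng.integers(2, n - 3)), int(rng.integers(2, n - 3)), n - 2)
    q = make_source(CoilSpec(type="dipole", center=src, axis=int(rng.integers(0, 2)), length=1, current=1.0), grid)
    return {
        "grid": grid,
        "materials": materials,
        "q": q,
        "implant_mask": mask,
        "implant_material": implant_material,
    }
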