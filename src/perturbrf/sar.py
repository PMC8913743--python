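"""Local and mass-averaged specific absorption rate (SAR) post-processing.

Local SAR is the dissipated RF power per unit tissue mass,

    SAR = σ |E|² / (2 ρm)    [W/kg]

under the peak-amplitude phasor convention (|E| is the peak, hence the ½).
The edge-based E-field is first interpolated to voxel centers by averaging
the parallel edge pairs of each voxel.  Mass-averaged SAR follows a
simplified cube-growing scheme: for each tissue voxel, the smallest centered
cube (grown in whole voxels, clipped at the domain box) whose tissue mass
reaches the target is used for a mass-weighted mean — a reproducible stand-in
for regulatory-grade IEC 62704 averaging, which is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import MaterialMap, YeeGrid


@dataclass
class SARMap:
    values: np.ndarray  # [W/kg], voxel array
    grid: YeeGrid
    averaged_mass_g: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("SAR array shape must equal the grid shape")
        if np.any(self.values < 0):
            raise ValueError("SAR must be non-negative")


def edge_to_centers(E: np.ndarray) -> np.ndarray:
    """Interpolate an edge field to voxel centers (mean of parallel edge pairs)."""
    out = np.empty_like(E)
    for c in range(3):
        acc = E[c]
        for ax in (a for a in range(3) if a != c):
            rolled = np.roll(acc, -1, axis=ax)
            sl = [slice(None)] * 3
            sl[ax] = -1
            rolled[tuple(sl)] = 0.0  # ghost edges beyond the high faces
            acc = 0.5 * (acc + rolled)
        out[c] = acc
    return out


def local_sar(E: np.ndarray, materials: MaterialMap, grid: YeeGrid) -> SARMap:
    """Per-voxel local SAR from an edge E-field (peak phasor convention)."""
    if E.shape != (3, *grid.shape):
        raise ValueError("E must be a full-grid edge field")
    if materials.shape != grid.shape:
        raise ValueError("material map does not match grid")
    conductive = materials.sigma > 0
    if np.any(conductive & (materials.rho_m <= 0)):
        raise ValueError("conductive voxels with zero mass density")
    Ec = edge_to_centers(E)
    mag2 = np.sum(np.abs(Ec) ** 2, axis=0)
    sar = np.zeros(grid.shape)
    sar[conductive] = materials.sigma[conductive] * mag2[conductive] / (2.0 * materials.rho_m[conductive])
    return SARMap(sar, grid, 0.0)


def _box_sums(arr: np.ndarray) -> np.ndarray:
    """3D summed-area table with a zero layer in front (inclusive prefix sums)."""
    s = np.zeros(tuple(n + 1 for n in arr.shape))
    s[1:, 1:, 1:] = arr
    return s.cumsum(0).cumsum(1).cumsum(2)


def _box_sum(table: np.ndarray, lo, hi) -> float:
    (x0, y0, z0), (x1, y1, z1) = lo, hi
    return (
        table[x1, y1, z1]
        - table[x0, y1, z1]
        - table[x1, y0, z1]
        - table[x1, y1, z0]
        + table[x0, y0, z1]
        + table[x0, y1, z0]
        + table[x1, y0, z0]
        - table[x0, y0, z0]
    )


def sar_1g(sar: SARMap, materials: MaterialMap, target_mass_g: float = 1.0) -> SARMap:
    """Mass-averaged SAR over the smallest centered cube holding the target mass."""
    grid = sar.grid
    if materials.shape != grid.shape:
        raise ValueError("material map does not match SAR grid")
    mass = materials.rho_m * grid.voxel_volume * 1e3  # grams per voxel
    if mass.sum() < target_mass_g:
        raise ValueError(f"total phantom mass {mass.sum():.3f} g is below the {target_mass_g} g target")
    mass_tab = _box_sums(mass)
    power_tab = _box_sums(sar.values * mass)
    out = np.zeros(grid.shape)
    shape = grid.shape
    max_half = max(shape)
    tissue = np.argwhere(mass > 0)
    for i, j, k in tissue:
        for half in range(max_half + 1):
            lo = (max(i - half, 0), max(j - half, 0), max(k - half, 0))
            hi = (min(i + half + 1, shape[0]), min(j + half + 1, shape[1]), min(k + half + 1, shape[2]))
            m = _box_sum(mass_tab, lo, hi)
            if m >= target_mass_g or (hi == shape and lo == (0, 0, 0)):
                out[i, j, k] = _box_sum(power_tab, lo, hi) / m
                break
    return SARMap(out, grid, target_mass_g)


def mip(sar: SARMap, axis) -> np.ndarray:
    """Maximum-intensity projection along one axis ('x'|'y'|'z' or 0|1|2)."""
    names = {"x": 0, "y": 1, "z": 2}
    ax = names.get(axis, axis)
    if ax not in (0, 1, 2):
        raise ValueError(f"axis must be x, y or z, got {axis!r}")
    return sar.values.max(axis=ax)


def error_stats(reference: SARMap, test: SARMap, mask: np.ndarray) -> dict:
    """Signed percent-error distribution of ``test`` against ``reference``.

    Positive errors are overestimates by the test map.  Returns quantiles,
    the fraction of masked voxels beyond ±5 %, and the extreme values.
    """
    if reference.values.shape != test.values.shape:
        raise ValueError("SAR maps must share a grid")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != reference.values.shape:
        raise ValueError("mask shape mismatch")
    mask = mask & (reference.values > 0)
    if not mask.any():
        raise ValueError("empty comparison mask")
    ref = reference.values[mask]
    err = 100.0 * (test.values[mask] - ref) / ref
    q = np.percentile(err, [0, 5, 25, 50, 75, 95, 100])
    return {
        "n_voxels": int(mask.sum()),
        "quantiles": {"min": q[0], "p5": q[1], "p25": q[2], "median": q[3], "p75": q[4], "p95": q[5], "max": q[6]},
        "fraction_beyond_5pct": float(np.mean(np.abs(err) > 5.0)),
        "max_overestimate_pct": float(err.max()),
        "max_underestimate_pct": float(err.min()),
        "errors_pct": err,
    }
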