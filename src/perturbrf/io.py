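"""HDF5 containers for materials/fields/SAR and JSON specs with provenance.

The on-disk layout is frozen in ``data_schema.json`` shipped with the
package: complex fields are split into re/im float64 datasets, and every file
carries the grid metadata (resolution, frequency, origin) as attributes plus
the package version.  Round trips are bitwise lossless for float64 payloads.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from importlib import resources

import h5py
import numpy as np

from . import __version__
from .grid import MaterialMap, YeeGrid
from .perturbation import SolverConfig
from .phantoms import CoilSpec, ImplantSpec, PhantomSpec
from .sar import SARMap

FORMAT_VERSION = 1


def load_schema() -> dict:
    with resources.files("perturbrf").joinpath("data_schema.json").open() as fh:
        return json.load(fh)


def _write_grid_attrs(group: h5py.Group, grid: YeeGrid):
    group.attrs["resolution_m"] = np.asarray(grid.resolution, dtype=float)
    group.attrs["frequency_hz"] = float(grid.frequency)
    group.attrs["origin_m"] = np.asarray(grid.origin, dtype=float)
    group.attrs["format_version"] = FORMAT_VERSION
    group.attrs["package_version"] = __version__


def _read_grid_attrs(group: h5py.Group, shape) -> YeeGrid:
    for key in ("resolution_m", "frequency_hz", "origin_m"):
        if key not in group.attrs:
            raise ValueError(f"missing required attribute {key!r} in {group.name}")
    return YeeGrid(
        tuple(shape),
        tuple(group.attrs["resolution_m"]),
        float(group.attrs["frequency_hz"]),
        tuple(group.attrs["origin_m"]),
    )


def write_materials(path, materials: MaterialMap, grid: YeeGrid):
    if materials.shape != grid.shape:
        raise ValueError("material map does not match grid")
    with h5py.File(path, "w") as fh:
        g = fh.create_group("materials")
        g.create_dataset("sigma", data=materials.sigma)
        g.create_dataset("eps_r", data=materials.eps_r)
        g.create_dataset("rho_m", data=materials.rho_m)
        _write_grid_attrs(g, grid)


def read_materials(path) -> tuple[MaterialMap, YeeGrid]:
    with h5py.File(path, "r") as fh:
        g = fh["materials"]
        mat = MaterialMap(g["sigma"][()], g["eps_r"][()], g["rho_m"][()])
        grid = _read_grid_attrs(g, mat.shape)
    return mat, grid


def _split_complex(group: h5py.Group, name: str, arr: np.ndarray):
    group.create_dataset(f"{name}_re", data=np.ascontiguousarray(arr.real))
    group.create_dataset(f"{name}_im", data=np.ascontiguousarray(arr.imag))


def _join_complex(group: h5py.Group, name: str):
    if f"{name}_re" not in group:
        return None
    return group[f"{name}_re"][()] + 1j * group[f"{name}_im"][()]


def provenance_block(config: SolverConfig | None = None, seed: int | None = None, **extra) -> str:
    """JSON provenance string: config hash, seed, tolerances, extras."""
    payload = dict(extra)
    if config is not None:
        cfg = asdict(config)
        payload["config"] = cfg
        payload["config_sha256"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
    if seed is not None:
        payload["seed"] = int(seed)
    payload["package_version"] = __version__
    return json.dumps(payload, sort_keys=True)


def write_fields(path, grid: YeeGrid, E: np.ndarray | None = None, H: np.ndarray | None = None,
                 residuals=None, provenance: str | None = None):
    with h5py.File(path, "w") as fh:
        g = fh.create_group("fields")
        _write_grid_attrs(g, grid)
        if E is not None:
            _split_complex(g, "E", np.asarray(E, dtype=complex))
        if H is not None:
            _split_complex(g, "H", np.asarray(H, dtype=complex))
        s = fh.create_group("solver")
        if residuals is not None:
            s.create_dataset("residuals", data=np.asarray(residuals, dtype=float))
        if provenance is not None:
            s.attrs["provenance"] = provenance


def read_fields(path) -> dict:
    with h5py.File(path, "r") as fh:
        g = fh["fields"]
        E = _join_complex(g, "E")
        H = _join_complex(g, "H")
        if E is None and H is None:
            raise ValueError("fields file contains neither E nor H")
        shape = (E if E is not None else H).shape[1:]
        grid = _read_grid_attrs(g, shape)
        out = {"grid": grid, "E": E, "H": H, "residuals": None, "provenance": None}
        if "solver" in fh:
            s = fh["solver"]
            if "residuals" in s:
                out["residuals"] = s["residuals"][()]
            out["provenance"] = s.attrs.get("provenance")
    return out


def write_sar(path, sar: SARMap, mips: dict | None = None, provenance: str | None = None):
    with h5py.File(path, "w") as fh:
        g = fh.create_group("sar")
        g.create_dataset("values", data=sar.values)
        g.attrs["averaged_mass_g"] = float(sar.averaged_mass_g)
        _write_grid_attrs(g, sar.grid)
        for name, img in (mips or {}).items():
            g.create_dataset(f"mip_{name}", data=np.asarray(img, dtype=float))
        if provenance is not None:
            g.attrs["provenance"] = provenance


def read_sar(path) -> SARMap:
    with h5py.File(path, "r") as fh:
        g = fh["sar"]
        values = g["values"][()]
        grid = _read_grid_attrs(g, values.shape)
        return SARMap(values, grid, float(g.attrs["averaged_mass_g"]))


_SPEC_TYPES = {"phantom": PhantomSpec, "coil": CoilSpec, "implant": ImplantSpec}


def save_spec(path, spec):
    with open(path, "w") as fh:
        fh.write(spec.model_dump_json(indent=2))


def load_spec(path, kind: str):
    try:
        cls = _SPEC_TYPES[kind]
    except KeyError:
        raise ValueError(f"unknown spec kind {kind!r}; choose from {sorted(_SPEC_TYPES)}")
    with open(path) as fh:
        return cls.model_validate_json(fh.read())


def save_config(path, config: SolverConfig):
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2)


def load_config(path) -> SolverConfig:
    with open(path) as fh:
        return SolverConfig(**json.load(fh))
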