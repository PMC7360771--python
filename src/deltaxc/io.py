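"""File formats: Gaussian cube, XYZ, config documents, archives, tables.

Conventions follow the common cube dialect: a positive voxel count in the
header means the axes are given in Bohr, a negative count means Angstrom.
Files are always *written* in Bohr with positive counts.  XYZ files are in
Angstrom on disk and converted to Bohr on read.

Model and descriptor archives are HDF5 containers carrying the basis hash
and the configuration hash that produced them, so downstream commands can
refuse silently mixed provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .density import DensityField
from .grids import Grid, uniform_grid
from .model import EnergyModel, Pipeline
from .network import AtomicNetwork
from .symmetry import DescriptorSet
from .system import ATOMIC_NUMBER, SYMBOL_OF, AtomicSystem
from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM


class ParseError(ValueError):
    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


# ---------------------------------------------------------------------------
# Gaussian cube
# ---------------------------------------------------------------------------

def read_cube(path) -> tuple[DensityField, AtomicSystem]:
    """Read a Gaussian cube file into a density on a uniform grid."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(path, len(lines), "truncated cube header")
    try:
        natoms_field = lines[2].split()
        natoms = int(natoms_field[0])
        origin = np.array([float(x) for x in natoms_field[1:4]])
    except (ValueError, IndexError):
        raise ParseError(path, 3, "malformed atom-count/origin record") \
            from None
    axes, shape, unit = [], [], 1.0
    for i in range(3):
        try:
            rec = lines[3 + i].split()
            n = int(rec[0])
            vec = np.array([float(x) for x in rec[1:4]])
        except (ValueError, IndexError):
            raise ParseError(path, 4 + i, "malformed voxel-axis record") \
                from None
        if n < 0:      # negative count: Angstrom dialect
            n, vec = -n, vec * BOHR_PER_ANGSTROM
            unit = BOHR_PER_ANGSTROM
        shape.append(n)
        axes.append(vec)
    if unit != 1.0:
        origin = origin * BOHR_PER_ANGSTROM
    species, positions = [], []
    for a in range(abs(natoms)):
        try:
            rec = lines[6 + a].split()
            z = int(rec[0])
            pos = [float(x) for x in rec[2:5]]
        except (ValueError, IndexError):
            raise ParseError(path, 7 + a, "malformed atom record") from None
        species.append(SYMBOL_OF.get(z, f"Z{z}"))
        positions.append(np.asarray(pos) * unit)
    data = []
    for ln in lines[6 + abs(natoms):]:
        data.extend(float(x) for x in ln.split())
    values = np.array(data)
    if values.size != np.prod(shape):
        raise ParseError(path, len(lines),
                         f"expected {np.prod(shape)} values, found "
                         f"{values.size}")
    grid = uniform_grid(origin, np.array(axes), shape)
    system = AtomicSystem(species, np.array(positions).reshape(-1, 3))
    return DensityField(grid, values, kind="full"), system


def write_cube(path, density: DensityField, system: AtomicSystem,
               comment: str = "deltaxc density") -> None:
    """Write a density on a uniform grid as a Bohr-dialect cube file."""
    grid = density.grid
    meta = grid.meta
    if "shape" not in meta:
        raise ValueError("cube output requires a uniform grid")
    nx, ny, nz = meta["shape"]
    lines = [comment, "outer loop x, middle y, inner z"]
    o = meta["origin"]
    lines.append(f"{system.natoms:5d} {o[0]:12.6f} {o[1]:12.6f} {o[2]:12.6f}")
    for n, ax in zip((nx, ny, nz), meta["axes"]):
        lines.append(f"{n:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}")
    for sym, pos in zip(system.species, system.positions):
        z = ATOMIC_NUMBER.get(sym, 0)
        lines.append(f"{z:5d} {float(z):12.6f} "
                     f"{pos[0]:12.6f} {pos[1]:12.6f} {pos[2]:12.6f}")
    vals = density.values.reshape(nx, ny, nz)
    for i in range(nx):
        for j in range(ny):
            row = vals[i, j]
            for k0 in range(0, nz, 6):
                lines.append(" ".join(f"{v:16.8E}"
                                      for v in row[k0:k0 + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path) -> AtomicSystem:
    """Read an XYZ file (Angstrom on disk -> Bohr in memory)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(path, 1, "missing atom count") from None
    species, positions = [], []
    for i in range(n):
        try:
            rec = lines[2 + i].split()
            species.append(rec[0])
            positions.append([float(x) for x in rec[1:4]])
        except (ValueError, IndexError):
            raise ParseError(path, 3 + i, "malformed atom line") from None
    return AtomicSystem(species,
                        np.array(positions) * BOHR_PER_ANGSTROM)


def write_xyz(path, system: AtomicSystem, comment: str = "") -> None:
    lines = [str(system.natoms), comment]
    for sym, pos in zip(system.species, system.positions):
        x, y, z = pos * ANGSTROM_PER_BOHR
        lines.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# configs & provenance
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def config_hash(cfg: dict) -> str:
    payload = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_config_snapshot(path, cfg: dict) -> str:
    """Write the resolved config next to a run's outputs; returns its hash."""
    h = config_hash(cfg)
    snap = dict(cfg)
    snap["_config_hash"] = h
    with open(path, "w") as fh:
        yaml.safe_dump(snap, fh, sort_keys=True)
    return h


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------

def write_energy_table(path, rows) -> None:
    """Tab-separated (id, E_base, E_ref) table, Hartree."""
    lines = ["id\tE_base\tE_ref"]
    for rid, e_base, e_ref in rows:
        lines.append(f"{rid}\t{e_base:.12f}\t{e_ref:.12f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_energy_table(path):
    rows = []
    lines = Path(path).read_text().splitlines()
    for ln in lines[1:]:
        rid, e_base, e_ref = ln.split("\t")
        rows.append((rid, float(e_base), float(e_ref)))
    return rows


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------

def save_model(path, model: EnergyModel, config_hash_: str = "") -> None:
    """Serialize an energy model to a single HDF5 archive."""
    with h5py.File(path, "w") as f:
        f.attrs["basis_hash"] = model.basis_hash
        f.attrs["use_delta"] = model.use_delta
        f.attrs["config_hash"] = config_hash_ or model.meta.get(
            "config_hash", "")
        for sym in model.species:
            g = f.create_group(f"species/{sym}")
            pipe = model.pipelines[sym]
            g.create_dataset("mask", data=pipe.mask)
            g.create_dataset("mean", data=pipe.mean)
            g.create_dataset("scale", data=pipe.scale)
            g.create_dataset("components", data=pipe.components)
            net = model.networks[sym]
            g.attrs["n_in"] = net.n_in
            g.attrs["hidden"] = net.hidden
            g.attrs["head_bias"] = net.head_bias
            g.attrs["n_frozen"] = net.n_frozen
            for i, (W, b) in enumerate(zip(net.weights, net.biases)):
                g.create_dataset(f"W{i}", data=W)
                g.create_dataset(f"b{i}", data=b)


def load_model(path) -> EnergyModel:
    pipelines, networks = {}, {}
    with h5py.File(path, "r") as f:
        basis_hash = str(f.attrs["basis_hash"])
        use_delta = bool(f.attrs["use_delta"])
        cfg_hash = str(f.attrs.get("config_hash", ""))
        for sym in f["species"]:
            g = f[f"species/{sym}"]
            pipelines[sym] = Pipeline(mask=g["mask"][...].astype(bool),
                                      mean=g["mean"][...],
                                      scale=g["scale"][...],
                                      components=g["components"][...])
            net = object.__new__(AtomicNetwork)
            net.n_in = int(g.attrs["n_in"])
            net.hidden = [int(h) for h in g.attrs["hidden"]]
            net.head_bias = bool(g.attrs["head_bias"])
            net.n_frozen = int(g.attrs["n_frozen"])
            net.weights, net.biases = [], []
            for i in range(len(net.hidden) + 1):
                net.weights.append(g[f"W{i}"][...])
                net.biases.append(g[f"b{i}"][...])
            networks[sym] = net
    model = EnergyModel(pipelines=pipelines, networks=networks,
                        basis_hash=basis_hash, use_delta=use_delta)
    model.meta["config_hash"] = cfg_hash
    return model


# ---------------------------------------------------------------------------
# descriptor archive
# ---------------------------------------------------------------------------

def save_descriptors(path, sets: list[DescriptorSet],
                     config_hash_: str = "") -> None:
    """One group per structure, one dataset per atom, basis hash alongside."""
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash_
        if sets:
            f.attrs["basis_hash"] = sets[0].basis_hash
        for i, ds in enumerate(sets):
            g = f.create_group(f"structure_{i:06d}")
            g.attrs["species"] = ds.species
            for a in range(ds.natoms):
                ga = g.create_group(f"atom_{a}")
                ga.create_dataset("coeffs", data=ds.coeffs[a])
                ga.create_dataset("invariants", data=ds.invariants[a])
                ga.attrs["nl"] = np.array(ds.nl_shapes[a])


def load_descriptors(path) -> list[DescriptorSet]:
    out = []
    with h5py.File(path, "r") as f:
        basis_hash = str(f.attrs.get("basis_hash", ""))
        for key in sorted(k for k in f if k.startswith("structure_")):
            g = f[key]
            species = [s for s in g.attrs["species"]]
            coeffs, invars, layouts = [], [], []
            for a in range(len(species)):
                ga = g[f"atom_{a}"]
                coeffs.append(ga["coeffs"][...])
                invars.append(ga["invariants"][...])
                layouts.append([tuple(int(v) for v in nl)
                                for nl in ga.attrs["nl"]])
            out.append(DescriptorSet(species, coeffs, invars, layouts,
                                     basis_hash=basis_hash))
    return out
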