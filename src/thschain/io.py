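"""File formats: extended-XYZ configurations, PDB export, run configs.

Extended XYZ is the primary configuration format: exact float
round-trip, arbitrary metadata on the comment line, and a per-sphere
chain tag.  The comment line carries the cell edge, the confinement
level, per-axis boundary types and both packing densities, e.g.::

    1200
    Lattice="18.45 0 0 0 18.45 0 0 0 18.45" Properties=species:S:1:pos:R:3:mol:I:1 pbc="T T F" dconf=1 phi=0.1 phi_eff=0.106
    S 1.25 3.50 9.75 0
    ...

Run configurations are TOML key-value files; a run is reproducible from
its config alone (the PRNG seed is part of it).
"""

from __future__ import annotations

import json
import re
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    ChainSystem,
    ModelParams,
    SimulationCell,
    effective_packing_density,
    packing_density,
)

__all__ = [
    "RunConfig",
    "write_configuration",
    "read_configuration",
    "write_pdb",
    "read_config_file",
    "write_config_file",
]

FORMAT_VERSION = 1


# --------------------------------------------------------------------------
# extended XYZ
# --------------------------------------------------------------------------

def write_configuration(system: ChainSystem, cell: SimulationCell,
                        path: str | Path, params: ModelParams | None = None,
                        extra: dict | None = None) -> None:
    """Write one configuration as extended XYZ with chain tags."""
    path = Path(path)
    L = cell.L
    pbc = " ".join("T" if ax in cell.periodic_axes else "F"
                   for ax in range(3))
    fields = {
        "Lattice": f'"{L:.17g} 0 0 0 {L:.17g} 0 0 0 {L:.17g}"',
        "Properties": "species:S:1:pos:R:3:mol:I:1",
        "pbc": f'"{pbc}"',
        "dconf": str(cell.dconf),
        "phi": f"{packing_density(system.n_atoms, cell):.17g}",
        "phi_eff": f"{effective_packing_density(system.n_atoms, cell):.17g}",
        "format_version": str(FORMAT_VERSION),
    }
    if params is not None:
        fields["n_min"] = str(params.n_min)
        fields["n_max"] = str(params.n_max)
        fields["k_bend"] = f"{params.k_bend:.17g}"
    if extra:
        for k, v in extra.items():
            fields[k] = str(v)
    comment = " ".join(f"{k}={v}" for k, v in fields.items())
    chain_ids = system.chain_ids
    with path.open("w") as fh:
        fh.write(f"{system.n_atoms}\n{comment}\n")
        for (x, y, z), mol in zip(system.positions, chain_ids):
            fh.write(f"S {x:.17g} {y:.17g} {z:.17g} {int(mol)}\n")


_KV_RE = re.compile(r'(\w[\w.]*)=("(?:[^"]*)"|\S+)')


def _parse_comment(line: str) -> dict[str, str]:
    return {m.group(1): m.group(2).strip('"')
            for m in _KV_RE.finditer(line)}


def read_configuration(path: str | Path
                       ) -> tuple[ChainSystem, SimulationCell, dict]:
    """Read an extended-XYZ configuration written by this package.

    Returns the system, the cell, and the parsed comment-line metadata.
    Raises ValueError with a line number on malformed input.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}:1: truncated file")
    try:
        n_atoms = int(lines[0].strip())
    except ValueError as e:
        raise ValueError(f"{path}:1: bad atom count: {lines[0]!r}") from e
    meta = _parse_comment(lines[1])
    if "Lattice" not in meta or "dconf" not in meta:
        raise ValueError(f"{path}:2: missing Lattice/dconf metadata")
    lat = [float(v) for v in meta["Lattice"].split()]
    if len(lat) != 9 or lat[0] != lat[4] or lat[4] != lat[8]:
        raise ValueError(f"{path}:2: cell must be cubic, got {meta['Lattice']}")
    cell = SimulationCell(L=lat[0], dconf=int(meta["dconf"]))
    if len(lines) < 2 + n_atoms:
        raise ValueError(f"{path}: expected {n_atoms} records, "
                         f"found {len(lines) - 2}")
    pos = np.empty((n_atoms, 3))
    mol = np.empty(n_atoms, dtype=np.int64)
    for i in range(n_atoms):
        parts = lines[2 + i].split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{3 + i}: expected 5 fields, "
                             f"got {len(parts)}")
        try:
            pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            mol[i] = int(parts[4])
        except ValueError as e:
            raise ValueError(f"{path}:{3 + i}: bad record") from e
    # chain tags must partition the records contiguously
    starts = [0]
    seen = {int(mol[0])}
    for i in range(1, n_atoms):
        if mol[i] != mol[i - 1]:
            tag = int(mol[i])
            if tag in seen:
                raise ValueError(
                    f"{path}:{3 + i}: chain tag {tag} is not contiguous")
            seen.add(tag)
            starts.append(i)
    starts.append(n_atoms)
    return ChainSystem(pos, np.array(starts)), cell, meta


# --------------------------------------------------------------------------
# PDB export (for molecular viewers)
# --------------------------------------------------------------------------

def write_pdb(system: ChainSystem, cell: SimulationCell,
              path: str | Path) -> None:
    """Minimal PDB export: one HETATM per sphere, chains as residues."""
    path = Path(path)
    chain_ids = system.chain_ids
    with path.open("w") as fh:
        L = cell.L
        fh.write(f"CRYST1{L:9.3f}{L:9.3f}{L:9.3f}"
                 f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        for i, ((x, y, z), mol) in enumerate(
                zip(system.positions, chain_ids), start=1):
            serial = i % 100000
            res = (int(mol) + 1) % 10000
            fh.write(f"HETATM{serial:5d}  S   CHN A{res:4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           S\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a run, serializable as TOML."""

    # model
    k_bend: float = 9.0
    theta0: float = 0.0
    dl: float = 6.5e-4
    n_min: int = 6
    n_max: int = 18
    # system
    n_chains: int = 100
    phi0: float = 0.001
    dconf: int = 0
    # moves
    move_probabilities: dict = field(default_factory=dict)
    # compression
    shrink: float = 0.999
    sweeps_on_reject: int = 10
    # scan
    grid: list = field(default_factory=list)
    equil_sweeps: int = 200
    max_equil_sweeps: int = 800
    production_sweeps: int = 200
    snapshot_stride: int = 10
    # bookkeeping
    seed: int = 0
    out_dir: str = "run"

    def model_params(self) -> ModelParams:
        return ModelParams(k_bend=self.k_bend, theta0=self.theta0,
                           dl=self.dl, n_min=self.n_min, n_max=self.n_max)

    def config_hash(self) -> str:
        import hashlib
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def write_config_file(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    lines = []
    d = asdict(config)
    moves = d.pop("move_probabilities")
    for k, v in d.items():
        lines.append(f"{k} = {_toml_value(v)}")
    if moves:
        lines.append("")
        lines.append("[move_probabilities]")
        for k, v in moves.items():
            lines.append(f"{k} = {_toml_value(v)}")
    path.write_text("\n".join(lines) + "\n")


def read_config_file(path: str | Path) -> RunConfig:
    with Path(path).open("rb") as fh:
        data = tomllib.load(fh)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
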