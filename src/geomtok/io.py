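"""Structure/trajectory I/O and run provenance.

PDB/DCD/XTC files go through mdtraj (converted to Å internally; mdtraj
works in nm).  Multi-frame XYZ — the plain-text format the synthetic
generators emit — is read and written directly, since the element column
of an XYZ file is its own topology.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import InputError

__all__ = ["read_structure", "read_trajectory", "write_xyz", "read_xyz",
           "RunConfig", "SYMBOL_TO_Z", "Z_TO_SYMBOL"]

SYMBOL_TO_Z = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11, "Mg": 12, "P": 15,
    "S": 16, "Cl": 17, "K": 19, "Ca": 20, "Fe": 26, "Zn": 30, "Br": 35,
    "I": 53,
}
Z_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_Z.items()}


def write_xyz(path, coords: np.ndarray, atom_numbers, comment: str = ""):
    """Multi-frame XYZ in Å; coords [T, N, 3] or [N, 3]."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    symbols = [Z_TO_SYMBOL.get(int(z), "X") for z in atom_numbers]
    with open(path, "w") as fh:
        for t, frame in enumerate(coords):
            fh.write(f"{len(symbols)}\n{comment} frame {t}\n")
            for s, (x, y, z) in zip(symbols, frame):
                fh.write(f"{s} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path):
    """Returns (coords [T, N, 3] Å, atom_numbers [N])."""
    frames, numbers = [], None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        try:
            n = int(lines[i].strip())
        except ValueError as e:
            raise InputError(f"malformed XYZ at line {i + 1}: {lines[i]!r}") from e
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise InputError(f"truncated XYZ frame at line {i + 1}")
        syms, xyz = [], []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise InputError(f"malformed XYZ record at line {i + 3 + j}")
            syms.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        nums = np.array([SYMBOL_TO_Z.get(s, 0) for s in syms])
        if numbers is None:
            numbers = nums
        elif not np.array_equal(numbers, nums):
            raise InputError("XYZ frames disagree on atom identities")
        frames.append(xyz)
        i += 2 + n
    if not frames:
        raise InputError("empty XYZ file")
    return np.asarray(frames, dtype=np.float64), numbers


def _topology_from_mdtraj(top):
    return {
        "atom_numbers": np.array(
            [a.element.number if a.element is not None else 0
             for a in top.atoms], dtype=np.intp),
        "residue_ids": np.array([a.residue.index for a in top.atoms],
                                dtype=np.intp),
        "chain_ids": np.array([a.residue.chain.index for a in top.atoms],
                              dtype=np.intp),
        "mdtraj_topology": top,
    }


def read_structure(path):
    """Read a structure file → (topology dict, coords [N, 3] Å).

    Topology dict keys: atom_numbers, residue_ids, chain_ids (and the
    original mdtraj topology for PDB input).  XYZ input yields one
    residue per atom.
    """
    path = Path(path)
    if path.suffix == ".xyz":
        coords, numbers = read_xyz(path)
        n = len(numbers)
        top = {"atom_numbers": numbers,
               "residue_ids": np.arange(n, dtype=np.intp),
               "chain_ids": np.zeros(n, dtype=np.intp)}
        return top, coords[0]
    import mdtraj
    try:
        traj = mdtraj.load(str(path))
    except Exception as e:
        raise InputError(f"could not parse {path}: {e}") from e
    return _topology_from_mdtraj(traj.topology), traj.xyz[0] * 10.0


def read_trajectory(path, topology_path=None):
    """Read trajectory frames → (coords [T, N, 3] Å, topology dict).

    PDB and XYZ are self-describing; DCD/XTC need ``topology_path``.
    """
    path = Path(path)
    if path.suffix == ".xyz":
        coords, numbers = read_xyz(path)
        n = len(numbers)
        top = {"atom_numbers": numbers,
               "residue_ids": np.arange(n, dtype=np.intp),
               "chain_ids": np.zeros(n, dtype=np.intp)}
        return coords, top
    import mdtraj
    try:
        if path.suffix in (".dcd", ".xtc"):
            if topology_path is None:
                raise InputError(f"{path.suffix} trajectories need a topology")
            traj = mdtraj.load(str(path), top=str(topology_path))
        else:
            traj = mdtraj.load(str(path))
    except InputError:
        raise
    except Exception as e:
        raise InputError(f"could not parse {path}: {e}") from e
    return traj.xyz * 10.0, _topology_from_mdtraj(traj.topology)


@dataclass
class RunConfig:
    """Fully serializable description of one CLI run; a run can be
    reconstructed from its persisted config and seed."""

    task: str
    seed: int
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def save(self, path) -> None:
        payload = asdict(self)
        payload["config_hash"] = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        Path(path).write_text(json.dumps(payload, indent=2, default=str))

    @classmethod
    def load(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload.pop("config_hash", None)
        return cls(**payload)
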