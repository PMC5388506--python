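"""On-disk formats: PDB structures, XYZ trajectories, CSV energy logs,
JSON topologies/manifests, TOML/JSON run configuration.

Structures are one CA bead per residue, chain A/B per molecule, 1-based
per-chain residue numbering.  The PDB/XYZ writers and readers are
deliberately small fixed-width implementations so that malformed or
duplicate records can be reported with their line numbers.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import ENERGY_COLUMNS, Trajectory
from .errors import FormatError
from .topology import (THREE_LETTER, ONE_LETTER, Conformation,
                       ResidueSequence, BetaRollTopology)

_CHAINS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def write_pdb(path, conformation: Conformation,
              sequence: ResidueSequence) -> None:
    """CA-only PDB, one chain per molecule, TER separated."""
    coords = conformation.coordinates
    if len(sequence) != len(coords):
        raise FormatError("sequence and coordinates differ in length")
    per = sequence.residues_per_molecule
    lines = []
    serial = 0
    for i, (res, mol) in enumerate(zip(sequence.residues,
                                       sequence.molecule_id)):
        serial += 1
        resseq = i % per + 1
        name = THREE_LETTER.get(res, "UNK")
        x, y, z = coords[i]
        lines.append(
            f"ATOM  {serial:5d}  CA  {name:<3s} {_CHAINS[mol]}{resseq:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
        if resseq == per:
            lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure(path) -> tuple[Conformation, ResidueSequence]:
    """Parse a CA-only PDB back into beads.

    Raises :class:`FormatError` naming the line for malformed ATOM records,
    duplicate residue numbers within a chain, or a file with no CA records.
    """
    coords, residues, molecules = [], [], []
    seen: set[tuple[str, int]] = set()
    chain_order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(),
                                  start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise FormatError("ATOM record too short", line=lineno)
        atom_name = line[12:16].strip()
        if atom_name != "CA":
            continue
        try:
            resname = line[17:20].strip()
            chain = line[21]
            resseq = int(line[22:26])
            xyz = [float(line[30:38]), float(line[38:46]),
                   float(line[46:54])]
        except ValueError as exc:
            raise FormatError(f"malformed ATOM record: {exc}",
                              line=lineno) from None
        if (chain, resseq) in seen:
            raise FormatError(
                f"duplicate residue {resseq} in chain {chain}", line=lineno)
        seen.add((chain, resseq))
        if chain not in chain_order:
            chain_order.append(chain)
        coords.append(xyz)
        residues.append(ONE_LETTER.get(resname, "G"))
        molecules.append(chain_order.index(chain))
    if not coords:
        raise FormatError("no CA records found")
    return (Conformation(np.asarray(coords)),
            ResidueSequence(residues=tuple(residues),
                            molecule_id=tuple(molecules)))


def write_xyz(path, trajectory: Trajectory,
              sequence: ResidueSequence | None = None) -> None:
    """Multi-frame XYZ; the comment line carries the frame time in ps."""
    n = trajectory.frames.shape[1]
    labels = (list(sequence.residues) if sequence is not None
              else ["C"] * n)
    with open(path, "w") as fh:
        for frame, t in zip(trajectory.frames, trajectory.times):
            fh.write(f"{n}\n")
            fh.write(f"time_ps={float(t)!r}\n")
            for lab, (x, y, z) in zip(labels, frame):
                fh.write(f"{lab} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz(path) -> Trajectory:
    """Read a trajectory written by :func:`write_xyz`."""
    frames, times = [], []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        try:
            n = int(lines[i])
        except ValueError:
            raise FormatError("expected atom count", line=i + 1) from None
        comment = lines[i + 1]
        t = 0.0
        for tok in comment.split():
            if tok.startswith("time_ps="):
                t = float(tok.split("=", 1)[1])
        frame = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise FormatError("short coordinate record",
                                  line=i + 3 + k)
            frame[k] = [float(p) for p in parts[1:4]]
        frames.append(frame)
        times.append(t)
        i += n + 2
    if not frames:
        raise FormatError("no frames found")
    times = np.asarray(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        dt = 1.0
        times = np.arange(len(frames), dtype=float)
    else:
        dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    return Trajectory(frames=np.asarray(frames), times=times,
                      steps=np.arange(len(frames)), dt=dt, save_interval=1)


def write_energy_log(path, trajectory: Trajectory) -> None:
    """Per-frame energy/boost CSV (exact round trip via repr floats)."""
    if trajectory.energies is None:
        raise FormatError("trajectory carries no energy records")
    df = pd.DataFrame({c: trajectory.energies[c] for c in ENERGY_COLUMNS})
    df.to_csv(path, index=False)


def read_energy_log(path) -> pd.DataFrame:
    """Energy log back as a DataFrame; missing columns are named errors."""
    df = pd.read_csv(path)
    missing = [c for c in ENERGY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"energy log missing columns {missing}")
    return df


def topology_to_json(path, topology: BetaRollTopology,
                     fixed_atoms=()) -> None:
    payload = {
        "residues": "".join(topology.sequence.residues),
        "molecule_id": list(topology.sequence.molecule_id),
        "n_repeats": topology.n_repeats,
        "geometry": asdict(topology.geometry),
        "strand_of_residue": list(topology.strand_of_residue),
        "omega_pairs": [list(p) for p in topology.omega_pairs],
        "lateral_pairs": [list(p) for p in topology.lateral_pairs],
        "vertical_intra_pairs": [list(p) for p in
                                 topology.vertical_intra_pairs],
        "vertical_inter_pairs": [list(p) for p in
                                 topology.vertical_inter_pairs],
        "fixed_atoms": list(fixed_atoms),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_config(path) -> dict:
    """JSON or TOML run configuration as a plain dict."""
    p = Path(path)
    if p.suffix == ".toml":
        with open(p, "rb") as fh:
            return tomllib.load(fh)
    return json.loads(p.read_text())


def config_hash(config: dict) -> str:
    """sha256 of the canonical JSON form of a config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class Manifest:
    """Provenance record emitted next to every run's outputs."""

    version: str
    config: dict
    seed: int | None
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""
    hash: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.hash:
            self.hash = config_hash(self.config)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def read(cls, path) -> "Manifest":
        return cls(**json.loads(Path(path).read_text()))
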