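"""End-to-end runs of the three studied simulation regimes.

The study design: conventional MD fixes the energy averages that
prescribe the dual-boost parameters, then three accelerated runs probe
unfolding of the two-molecule stack —

  (i)   no restraints, threshold multiplier n = 2;
  (ii)  partially-fixed bottom template, n = 2;
  (iii) partially-fixed bottom template, n = 2.5.

The original simulations span 100–400 ns; the defaults here are desk-scale
step counts (roughly two orders of magnitude shorter) with the same
structure.  Every run writes its artifacts plus a manifest carrying the
resolved configuration, its hash, and the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amd import prescribe_parameters, run_amd
from .analysis import omega_series, segment_plateaus
from .dynamics import run_cmd
from .io import (Manifest, topology_to_json, write_energy_log, write_pdb,
                 write_xyz)
from .model import EnergyModel, ForceField
from .topology import (GeometryParams, build_ideal_stack,
                       select_fixed_atoms)

#: the three regimes of the study design
REGIMES = {
    "i": {"restraints": "none", "n": 2.0},
    "ii": {"restraints": "partial_template", "n": 2.0},
    "iii": {"restraints": "partial_template", "n": 2.5},
}


@dataclass
class RunConfig:
    """Resolved configuration of one experiment run."""

    mode: str = "amd"                       # cmd | amd
    n: float = 2.0                          # threshold multiplier
    restraints: str = "none"                # none | partial_template
    steps: int = 30000
    cmd_steps: int = 20000                  # prescription run length
    equil_steps: int = 5000
    save_interval: int = 20
    dt: float = 0.01                        # ps
    friction: float = 1.0                   # 1/ps
    temperature: float = 300.0              # K
    seed: int = 0
    outdir: str = "results/run"
    geometry: dict = field(default_factory=dict)
    energy_model: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def regime(cls, which: str, **overrides) -> "RunConfig":
        base = dict(REGIMES[which])
        base.update(overrides)
        return cls(mode="amd", **base)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_experiment(config: RunConfig) -> Manifest:
    """Build, simulate, analyse, and write one regime end to end."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def emit(name: str) -> Path:
        outputs.append(name)
        return out / name

    seeds = np.random.SeedSequence(config.seed).generate_state(3)

    try:
        conf, top = build_ideal_stack(
            GeometryParams(**config.geometry) if config.geometry else None)
        model = EnergyModel(**config.energy_model) \
            if config.energy_model else EnergyModel()
        write_pdb(emit("stack.pdb"), conf, top.sequence)
        fixed = select_fixed_atoms(top, config.restraints)
        topology_to_json(emit("topology.json"), top, fixed)
    except Exception as exc:
        raise type(exc)(f"[build] {exc}") from exc

    try:
        ff_cmd = ForceField.from_topology(model, top, conf)
        cmd = run_cmd(ff_cmd, conf, n_steps=config.cmd_steps,
                      equil_steps=min(config.equil_steps,
                                      config.cmd_steps // 2),
                      save_interval=config.save_interval, dt=config.dt,
                      friction=config.friction,
                      temperature=config.temperature,
                      seed=int(seeds[0]))
        write_energy_log(emit("cmd_energies.csv"), cmd.trajectory)
    except Exception as exc:
        raise type(exc)(f"[cmd] {exc}") from exc

    if config.mode == "cmd":
        main = cmd
        ff = ff_cmd
    else:
        try:
            params = prescribe_parameters(
                cmd.v_avg_total, cmd.v_avg_dihedral,
                n_res=top.n_residues, n_atoms=top.n_residues, n=config.n)
            params.to_json(emit("boost_parameters.json"))
            ff = ForceField.from_topology(model, top, conf,
                                          fixed_atoms=tuple(fixed))
            main = run_amd(ff, conf, params, n_steps=config.steps,
                           equil_steps=0,
                           save_interval=config.save_interval,
                           dt=config.dt, friction=config.friction,
                           temperature=config.temperature,
                           seed=int(seeds[1]))
        except Exception as exc:
            raise type(exc)(f"[amd] {exc}") from exc

    try:
        write_energy_log(emit("energies.csv"), main.trajectory)
        write_xyz(emit("trajectory.xyz"), main.trajectory, top.sequence)
        rows = []
        for mol in range(top.n_molecules):
            om = omega_series(main.trajectory, top.omega_pairs_of(mol),
                              molecule=mol)
            for t, o in zip(om.time, om.omega):
                rows.append({"molecule": mol, "time_ps": t, "omega": o})
        omega_df = pd.DataFrame(rows)
        omega_df.to_csv(emit("omega.csv"), index=False)
        top_om = omega_df[omega_df.molecule == top.n_molecules - 1]
        segs = segment_plateaus(top_om.omega.to_numpy(), tolerance=2.0)
        pd.DataFrame([{"start_frame": s.start, "end_frame": s.end,
                       "level": s.level} for s in segs]
                     ).to_csv(emit("plateaus.csv"), index=False)
    except Exception as exc:
        raise type(exc)(f"[analyze] {exc}") from exc

    manifest = Manifest(version=__version__, config=config.as_dict(),
                        seed=config.seed, outputs=sorted(outputs))
    manifest.write(out / "manifest.json")
    return manifest
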