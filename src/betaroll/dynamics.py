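"""Langevin dynamics for the coarse-grained stack.

BAOAB splitting of the Langevin equation (velocity Verlet in the
zero-friction limit).  Units: A, ps, kcal/mol, amu, K.  One force
evaluation per step; a per-channel force transform hook lets the
accelerated-MD layer scale the dihedral and total-energy channels
without the integrator knowing about boosts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import EmptyTrajectoryError, NonFiniteCoordinateError
from .model import ForceField, FrameEnergies
from .topology import Conformation

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041
#: (kcal/mol/A)/amu in A/ps^2
F_CONV = 418.4

#: columns of a per-frame energy log
ENERGY_COLUMNS = ("step", "time_ps", "v_total", "v_dihedral",
                  "v_non_dihedral", "dv_total", "dv_dihedral", "e_kinetic")


@dataclass
class MDState:
    """Positions (A) and velocities (A/ps)."""

    positions: np.ndarray
    velocities: np.ndarray


@dataclass
class Trajectory:
    """Time-ordered saved frames plus optional per-frame energy records.

    ``energies`` maps the non-index :data:`ENERGY_COLUMNS` to arrays of one
    value per saved frame; cMD logs carry all-zero ``dv_*`` columns.
    """

    frames: np.ndarray                     # (n_frames, n_residues, 3)
    times: np.ndarray                      # ps
    steps: np.ndarray
    dt: float                              # ps
    save_interval: int
    seed: int | None = None
    temperature: float | None = None
    friction: float | None = None
    energies: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise EmptyTrajectoryError("trajectory must hold at least one frame")
        if np.any(np.diff(self.times) <= 0):
            raise EmptyTrajectoryError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def conformation(self, frame: int) -> Conformation:
        return Conformation(self.frames[frame])


@dataclass
class SimulationResult:
    """A trajectory plus post-equilibration energy averages (kcal/mol)."""

    trajectory: Trajectory
    v_avg_total: float
    v_avg_dihedral: float
    se_total: float
    se_dihedral: float
    n_average_frames: int


def maxwell_velocities(masses: np.ndarray, temperature: float,
                       rng: np.random.Generator) -> np.ndarray:
    scale = np.sqrt(KB * max(temperature, 0.0) * F_CONV / masses)
    return rng.normal(size=(len(masses), 3)) * scale[:, None]


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in kcal/mol."""
    return float(0.5 * np.sum(masses[:, None] * velocities**2) / F_CONV)


#: hook signature: (energies, f_dihedral, f_other) -> (total force, dv_dih, dv_tot)
ForceTransform = Callable[[FrameEnergies, np.ndarray, np.ndarray],
                          tuple[np.ndarray, float, float]]


def _plain_forces(energies: FrameEnergies, f_dih: np.ndarray,
                  f_other: np.ndarray) -> tuple[np.ndarray, float, float]:
    return f_dih + f_other, 0.0, 0.0


class LangevinIntegrator:
    """BAOAB Langevin integrator over a :class:`ForceField`."""

    def __init__(self, forcefield: ForceField, dt: float = 0.01,
                 friction: float = 1.0, temperature: float = 300.0,
                 rng: np.random.Generator | None = None,
                 force_transform: ForceTransform = _plain_forces):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.ff = forcefield
        self.dt = dt
        self.friction = friction
        self.temperature = temperature
        self.rng = rng or np.random.default_rng()
        self.force_transform = force_transform
        self.masses = forcefield.masses
        self._c1 = np.exp(-friction * dt)
        self._c2 = np.sqrt(max(0.0, 1.0 - self._c1**2) * KB * temperature
                           * F_CONV / self.masses)[:, None]
        self._inv_m = (F_CONV / self.masses)[:, None]
        self._cached = None  # (force, energies, dv_dih, dv_tot)
        self._step_count = 0

    def _eval(self, x: np.ndarray):
        energies, f_dih, f_other = self.ff.evaluate(x)
        force, dv_dih, dv_tot = self.force_transform(energies, f_dih, f_other)
        return force, energies, dv_dih, dv_tot

    def step(self, state: MDState) -> tuple[FrameEnergies, float, float]:
        """Advance one step in place; returns the post-step energy record."""
        if self._cached is None:
            self._cached = self._eval(state.positions)
        force = self._cached[0]
        half = 0.5 * self.dt
        v = state.velocities
        v += half * force * self._inv_m
        state.positions += half * v
        if self.friction > 0:
            v *= self._c1
            v += self._c2 * self.rng.standard_normal(v.shape)
        state.positions += half * v
        if not np.all(np.isfinite(state.positions)):
            raise NonFiniteCoordinateError(self._step_count)
        self._cached = self._eval(state.positions)
        v += half * self._cached[0] * self._inv_m
        self._step_count += 1
        _, energies, dv_dih, dv_tot = self._cached
        return energies, dv_dih, dv_tot


def langevin_step(state: MDState, forcefield: ForceField, dt: float,
                  friction: float, temperature: float,
                  rng: np.random.Generator) -> MDState:
    """One BAOAB step as a pure-ish convenience wrapper."""
    integ = LangevinIntegrator(forcefield, dt, friction, temperature, rng)
    integ.step(state)
    return state


def _run(forcefield: ForceField, initial: Conformation, n_steps: int,
         equil_steps: int, save_interval: int, dt: float, friction: float,
         temperature: float, seed: int | None,
         force_transform: ForceTransform) -> SimulationResult:
    if equil_steps >= n_steps:
        raise ValueError("equilibration length must be < n_steps")
    rng = np.random.default_rng(seed)
    state = MDState(positions=initial.coordinates.copy(),
                    velocities=maxwell_velocities(
                        forcefield.masses, temperature, rng))
    integ = LangevinIntegrator(forcefield, dt, friction, temperature, rng,
                               force_transform)

    frames, log = [], {c: [] for c in ENERGY_COLUMNS}

    def record(step: int, energies: FrameEnergies, dv_dih: float,
               dv_tot: float) -> None:
        frames.append(state.positions.copy())
        log["step"].append(step)
        log["time_ps"].append(step * dt)
        log["v_total"].append(energies.v_total)
        log["v_dihedral"].append(energies.v_dihedral)
        log["v_non_dihedral"].append(energies.v_non_dihedral)
        log["dv_dihedral"].append(dv_dih)
        log["dv_total"].append(dv_tot)
        log["e_kinetic"].append(kinetic_energy(state.velocities,
                                               forcefield.masses))

    e0, fd0, fo0 = forcefield.evaluate(state.positions)
    _, d0, t0 = force_transform(e0, fd0, fo0)
    record(0, e0, d0, t0)
    for step in range(1, n_steps + 1):
        energies, dv_dih, dv_tot = integ.step(state)
        if step % save_interval == 0:
            record(step, energies, dv_dih, dv_tot)

    energy_log = {k: np.asarray(v, dtype=float) for k, v in log.items()}
    trajectory = Trajectory(
        frames=np.asarray(frames), times=energy_log["time_ps"],
        steps=energy_log["step"].astype(int), dt=dt,
        save_interval=save_interval, seed=seed, temperature=temperature,
        friction=friction, energies=energy_log)

    post = energy_log["step"] > equil_steps
    vt = energy_log["v_total"][post]
    vd = energy_log["v_dihedral"][post]
    return SimulationResult(
        trajectory=trajectory,
        v_avg_total=float(vt.mean()),
        v_avg_dihedral=float(vd.mean()),
        se_total=float(vt.std(ddof=1) / np.sqrt(len(vt))) if len(vt) > 1 else 0.0,
        se_dihedral=float(vd.std(ddof=1) / np.sqrt(len(vd))) if len(vd) > 1 else 0.0,
        n_average_frames=int(post.sum()),
    )


def run_cmd(forcefield: ForceField, initial: Conformation, n_steps: int,
            equil_steps: int = 0, save_interval: int = 10, dt: float = 0.01,
            friction: float = 1.0, temperature: float = 300.0,
            seed: int | None = None) -> SimulationResult:
    """Conventional (unboosted) Langevin run.

    Returns the trajectory and the post-equilibration time averages of the
    total and dihedral potential energies — the inputs of the dual-boost
    parameter prescription — with naive standard errors over logged frames.
    """
    return _run(forcefield, initial, n_steps, equil_steps, save_interval,
                dt, friction, temperature, seed, _plain_forces)
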