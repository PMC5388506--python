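"""Scripted step-wise unfolding trajectories.

Engine-independent emulation of the step-wise unfolding traces seen in
accelerated-MD runs of the stack: the top molecule loses strands in
discrete stages (mainly from the C terminus, with an early N-terminal
strand), producing plateaus in Omega(t).  Each plateau level L is realised
exactly by peeling 64 - L residues from the molecule ends into extended
tails, so the schedule round-trips through the Omega/plateau analysis.
"""

from __future__ import annotations

import numpy as np

from .dynamics import Trajectory
from .errors import ScheduleError
from .topology import (OMEGA_OFFSET, BetaRollTopology, ideal_conformation)

#: plateau levels and durations (ps) echoing the staged unfolding of the
#: reference aMD trace: 52, 38, 30, 24, 2
DEFAULT_SCHEDULE = ((52, 270.0), (38, 160.0), (30, 140.0),
                    (24, 40.0), (2, 120.0))
#: one strand peels from the N terminus first, the rest from the C terminus
DEFAULT_PEEL_ORDER = "N" * 8 + "C" * 72


def scripted_unfolding_generator(
    topology: BetaRollTopology,
    plateau_schedule=DEFAULT_SCHEDULE,
    peel_order: str = DEFAULT_PEEL_ORDER,
    noise_amplitude: float = 0.1,
    seed: int | None = None,
    frame_interval: float = 1.0,
    molecule: int | None = None,
    tail_spacing: float = 3.8,
) -> Trajectory:
    """Synthetic trajectory whose Omega(t) trace follows the schedule.

    ``plateau_schedule`` is a sequence of (Omega level, duration ps) with
    non-increasing levels; ``peel_order`` assigns each peeled residue to the
    'N' or 'C' terminus.  Peeled residues extend away from the stack in a
    straight tail (``tail_spacing`` per residue), unpeeled residues stay at
    the ideal build; Gaussian positional noise of ``noise_amplitude`` A per
    coordinate is added to every frame.
    """
    per = topology.residues_per_molecule
    n_pairs = per - OMEGA_OFFSET
    if molecule is None:
        molecule = topology.n_molecules - 1
    levels = [lv for lv, _ in plateau_schedule]
    for lv in levels:
        if not (0 <= lv <= n_pairs):
            raise ScheduleError(
                f"plateau level {lv} outside [0, {n_pairs}]")
    if any(b > a for a, b in zip(levels, levels[1:], strict=False)):
        raise ScheduleError("plateau levels must be non-increasing")
    if any(dur <= 0 for _, dur in plateau_schedule):
        raise ScheduleError("plateau durations must be positive")

    rng = np.random.default_rng(seed)
    ideal = ideal_conformation(topology).coordinates
    off = molecule * per

    frames, times = [], []
    t = 0.0
    for level, duration in plateau_schedule:
        n_peel = n_pairs - level
        order = peel_order[:n_peel]
        if len(order) < n_peel:
            raise ScheduleError("peel_order shorter than required peeling")
        n_from_n = order.count("N")
        n_from_c = n_peel - n_from_n
        base = ideal.copy()
        if n_from_n:
            anchor = ideal[off + n_from_n]     # first unpeeled residue
            for k in range(n_from_n):          # local residues 1..n_from_n
                base[off + k] = anchor + np.array(
                    [0.0, 0.0, tail_spacing * (n_from_n - k)])
        if n_from_c:
            anchor = ideal[off + per - n_from_c - 1]
            for k in range(n_from_c):
                base[off + per - n_from_c + k] = anchor + np.array(
                    [0.0, 0.0, tail_spacing * (k + 1)])
        n_frames = max(1, int(round(duration / frame_interval)))
        for _ in range(n_frames):
            frames.append(base + rng.normal(0.0, noise_amplitude,
                                            base.shape))
            times.append(t)
            t += frame_interval
    return Trajectory(
        frames=np.asarray(frames), times=np.asarray(times),
        steps=np.arange(len(frames)), dt=frame_interval, save_interval=1,
        seed=seed)
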