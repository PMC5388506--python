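"""Trajectory measurement machinery.

All the observables used to characterise beta-roll (un)folding:

* the unfolding order parameter Omega — the count of (i, i+16) residue
  pairs within the 4.0–6.0 A native window;
* hydrogen-bond indicator series, lifetimes and occupancies;
* unweighted (and exponentially reweighted) potentials of mean force over
  pair distances, F(A_j) = -kB T ln p(A_j), and the first-peak bond
  strength read off them;
* out-of-plane backbone-vector autocorrelation and relaxation times;
* plateau segmentation of step-wise unfolding traces;
* leader-style RMSD clustering with medoid representatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .dynamics import KB, Trajectory
from .errors import (DegenerateHistogramError, EmptyTrajectoryError,
                     NoPeakError)
from .topology import OMEGA_WINDOW, Conformation


@dataclass(frozen=True)
class OmegaSeries:
    """Omega(t): native-window pair count per frame for one molecule."""

    time: np.ndarray
    omega: np.ndarray
    molecule: int | None = None

    @property
    def mean(self) -> float:
        return float(self.omega.mean())


def omega_series(trajectory: Trajectory, omega_pairs,
                 d_min: float = OMEGA_WINDOW[0],
                 d_max: float = OMEGA_WINDOW[1],
                 molecule: int | None = None) -> OmegaSeries:
    """Count pairs with d_min <= d <= d_max (inclusive) per frame."""
    if trajectory.n_frames < 1:
        raise EmptyTrajectoryError("omega_series needs at least one frame")
    pairs = np.asarray(list(omega_pairs), dtype=int).reshape(-1, 2) - 1
    if pairs.size and pairs.max() >= trajectory.frames.shape[1]:
        raise IndexError("omega pair index outside trajectory")
    d = np.linalg.norm(trajectory.frames[:, pairs[:, 1]] -
                       trajectory.frames[:, pairs[:, 0]], axis=2)
    om = ((d >= d_min) & (d <= d_max)).sum(axis=1)
    return OmegaSeries(time=trajectory.times.copy(),
                       omega=om.astype(int), molecule=molecule)


def pair_distance_series(trajectory: Trajectory, pairs) -> np.ndarray:
    """Distances (n_frames, n_pairs) for 1-based residue pairs."""
    p = np.asarray(list(pairs), dtype=int).reshape(-1, 2) - 1
    return np.linalg.norm(trajectory.frames[:, p[:, 1]] -
                          trajectory.frames[:, p[:, 0]], axis=2)


def hbond_indicator(distances, cutoff: float) -> np.ndarray:
    """1 where d <= cutoff (inclusive), else 0."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = np.asarray(distances, dtype=float)
    return (d <= cutoff).astype(int)


@dataclass(frozen=True)
class LifetimeStats:
    """Continuous hydrogen-bond event statistics.

    ``event_count * mean_lifetime`` equals the total occupancy time exactly.
    """

    event_count: int
    mean_lifetime: float     # ps
    max_lifetime: float      # ps
    occupancy: float         # fraction of frames bonded
    has_events: bool = True


def lifetime_stats(indicator, frame_interval: float = 1.0) -> LifetimeStats:
    """Run-length statistics of a binary bonded/unbonded series.

    An event is a maximal run of 1s; runs touching either boundary count.
    """
    ind = np.asarray(indicator, dtype=int).ravel()
    if ind.size == 0:
        return LifetimeStats(0, 0.0, 0.0, 0.0, has_events=False)
    padded = np.concatenate([[0], ind, [0]])
    starts = np.flatnonzero(np.diff(padded) == 1)
    ends = np.flatnonzero(np.diff(padded) == -1)
    runs = (ends - starts) * frame_interval
    if len(runs) == 0:
        return LifetimeStats(0, 0.0, 0.0, 0.0, has_events=False)
    return LifetimeStats(
        event_count=int(len(runs)),
        mean_lifetime=float(runs.mean()),
        max_lifetime=float(runs.max()),
        occupancy=float(ind.mean()),
    )


@dataclass(frozen=True)
class PMFProfile:
    """Binned free-energy profile over a distance coordinate.

    ``f`` is shifted so the lowest finite value is 0; empty bins hold NaN.
    """

    bin_edges: np.ndarray    # A, len n_bins + 1
    f: np.ndarray            # kcal/mol, len n_bins
    counts: np.ndarray       # samples (or total weight) per bin
    bin_size: float          # A
    temperature: float       # K

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _pmf_from_histogram(counts: np.ndarray, edges: np.ndarray,
                        bin_size: float, temperature: float) -> PMFProfile:
    total = counts.sum()
    if total <= 0:
        raise DegenerateHistogramError("no samples in histogram")
    with np.errstate(divide="ignore"):
        f = -KB * temperature * np.log(counts / total)
    f = np.where(counts > 0, f, np.nan)
    f = f - np.nanmin(f)
    return PMFProfile(bin_edges=edges, f=f, counts=counts,
                      bin_size=bin_size, temperature=temperature)


def _aligned_edges(samples: np.ndarray, bin_size: float) -> np.ndarray:
    # edges on multiples of the bin size, so profiles with different bin
    # sizes describe the same axis
    lo = np.floor(samples.min() / bin_size) * bin_size
    hi = np.ceil(samples.max() / bin_size) * bin_size
    if hi <= lo + 0.5 * bin_size:
        hi = lo + bin_size
    n = int(round((hi - lo) / bin_size))
    if n > 1_000_000:
        raise DegenerateHistogramError(
            f"{n} bins of {bin_size} A needed to span the samples; "
            "series looks unphysical for a distance histogram")
    return lo + bin_size * np.arange(n + 1)


def unweighted_pmf(distances, bin_size: float,
                   temperature: float = 300.0) -> PMFProfile:
    """F(A_j) = -kB T ln p(A_j) from a distance histogram, min shifted to 0."""
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise EmptyTrajectoryError("empty distance series")
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    if np.ptp(d) < 1e-12:
        raise DegenerateHistogramError("all samples identical")
    edges = _aligned_edges(d, bin_size)
    counts, _ = np.histogram(d, bins=edges)
    return _pmf_from_histogram(counts.astype(float), edges, bin_size,
                               temperature)


def reweight_pmf(distances, dv, bin_size: float,
                 temperature: float = 300.0) -> PMFProfile:
    """PMF with per-frame Boltzmann weights exp(dV / kB T) for the boost.

    With dV identically zero this reduces exactly to :func:`unweighted_pmf`.
    """
    d = np.asarray(distances, dtype=float).ravel()
    w = np.asarray(dv, dtype=float).ravel()
    if d.size != w.size:
        raise ValueError("distance and dV series differ in length")
    if d.size == 0:
        raise EmptyTrajectoryError("empty distance series")
    if np.ptp(d) < 1e-12:
        raise DegenerateHistogramError("all samples identical")
    weights = np.exp((w - w.max()) / (KB * temperature))
    edges = _aligned_edges(d, bin_size)
    counts, _ = np.histogram(d, bins=edges, weights=weights)
    return _pmf_from_histogram(counts, edges, bin_size, temperature)


def bond_strength(pmf: PMFProfile) -> float:
    """PMF value at the first peak past the global minimum.

    The profile is normalised to min 0, so the first discrete local maximum
    at a distance greater than the global-minimum distance is the bond
    strength; single-bin plateaus break ties toward the smaller distance.
    """
    f = pmf.f
    finite = np.flatnonzero(np.isfinite(f))
    if len(finite) < 3:
        raise NoPeakError("profile too short for a peak")
    imin = finite[np.argmin(f[finite])]
    for j in range(imin + 1, len(f) - 1):
        if not np.isfinite(f[j]):
            continue
        prev = f[j - 1] if np.isfinite(f[j - 1]) else -np.inf
        nxt = f[j + 1] if np.isfinite(f[j + 1]) else np.inf
        if f[j] > prev and f[j] >= nxt:
            return float(f[j])
    raise NoPeakError("no local maximum beyond the global minimum")


def out_of_plane_vectors(trajectory: Trajectory,
                         triples=None) -> np.ndarray:
    """Unit normals of consecutive-bead triples, (n_frames, n_triples, 3).

    The normal of beads (i, i+1, i+2) is the normalised cross product of the
    two bond vectors; collinear triples yield NaN rows (undefined flag).
    """
    frames = trajectory.frames
    n = frames.shape[1]
    if n < 3:
        raise EmptyTrajectoryError("need at least three residues")
    if triples is None:
        triples = [(i, i + 1, i + 2) for i in range(n - 2)]
    t = np.asarray(triples, dtype=int)
    b1 = frames[:, t[:, 1]] - frames[:, t[:, 0]]
    b2 = frames[:, t[:, 2]] - frames[:, t[:, 1]]
    cr = np.cross(b1, b2)
    norm = np.linalg.norm(cr, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = cr / norm[:, :, None]
    unit[norm < 1e-8] = np.nan
    return unit


@dataclass(frozen=True)
class AcfProfile:
    """Orientation autocorrelation with its first-zero relaxation time."""

    lag: np.ndarray                  # ps
    c: np.ndarray                    # dimensionless, c[0] == 1
    relaxation_time: float           # ps
    lower_bound: bool = False        # True if C never crossed zero


def relaxation_time(vectors: np.ndarray, max_lag: int,
                    frame_interval: float = 1.0) -> AcfProfile:
    """C(t) averaged over triples and time origins; first zero crossing.

    ``vectors`` is an (n_frames, n_triples, 3) unit-vector series (NaN rows
    ignored).  If C(t) never reaches zero the relaxation time is reported
    as the max-lag lower bound with ``lower_bound=True``.
    """
    v = np.asarray(vectors, dtype=float)
    n_frames = v.shape[0]
    if n_frames <= max_lag:
        raise ValueError("series must be longer than max_lag")
    c = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        dots = np.einsum("ftk,ftk->ft", v[:n_frames - lag],
                         v[lag:])
        c[lag] = np.nanmean(dots)
    c = c / c[0]
    lags_ps = np.arange(max_lag + 1) * frame_interval
    below = np.flatnonzero(c <= 0)
    if len(below) == 0:
        return AcfProfile(lag=lags_ps, c=c,
                          relaxation_time=float(max_lag * frame_interval),
                          lower_bound=True)
    k = below[0]
    if k == 0:
        tau = 0.0
    else:
        # linear interpolation between the bracketing lags
        tau = lags_ps[k - 1] + frame_interval * c[k - 1] / (c[k - 1] - c[k])
    return AcfProfile(lag=lags_ps, c=c, relaxation_time=float(tau))


@dataclass(frozen=True)
class PlateauSegment:
    start: int          # frame index, inclusive
    end: int            # frame index, inclusive
    level: float        # segment median


def segment_plateaus(values, min_duration: int | None = None,
                     tolerance: float = 2.0) -> list[PlateauSegment]:
    """Maximal runs staying within +/- tolerance of their running median.

    Segments shorter than ``min_duration`` frames (default 10% of the
    trace) are treated as transitions and dropped.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise EmptyTrajectoryError("empty series")
    if min_duration is None:
        min_duration = max(1, len(x) // 10)
    segments: list[PlateauSegment] = []
    start = 0
    current = [x[0]]
    for i in range(1, len(x)):
        candidate = current + [x[i]]
        med = np.median(candidate)
        if np.all(np.abs(np.asarray(candidate) - med) <= tolerance):
            current = candidate
        else:
            if len(current) >= min_duration:
                segments.append(PlateauSegment(
                    start=start, end=i - 1,
                    level=float(np.median(current))))
            start = i
            current = [x[i]]
    if len(current) >= min_duration:
        segments.append(PlateauSegment(start=start, end=len(x) - 1,
                                       level=float(np.median(current))))
    return segments


# -- RMSD clustering --------------------------------------------------------

def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Best-fit RMSD after optimal superposition (Kabsch)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(len(a)))


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray                       # cluster id per frame
    medoid_frames: tuple[int, ...]           # frame index of each medoid
    representatives: tuple[Conformation, ...] = field(hash=False)

    @property
    def n_clusters(self) -> int:
        return len(self.medoid_frames)


def cluster_representative(frames: np.ndarray,
                           rmsd_cutoff: float = 2.0) -> ClusterResult:
    """Leader-style RMSD clustering; representatives are cluster medoids.

    Frames join the first leader within the cutoff, else found a new
    cluster; each cluster's representative minimises the summed RMSD to
    its members.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or len(frames) < 1:
        raise EmptyTrajectoryError("need at least one frame to cluster")
    leaders: list[int] = []
    labels = np.empty(len(frames), dtype=int)
    for i, fr in enumerate(frames):
        for ci, li in enumerate(leaders):
            if rmsd(fr, frames[li]) <= rmsd_cutoff:
                labels[i] = ci
                break
        else:
            labels[i] = len(leaders)
            leaders.append(i)
    medoids = []
    for ci in range(len(leaders)):
        members = np.flatnonzero(labels == ci)
        if len(members) == 1:
            medoids.append(int(members[0]))
            continue
        sums = np.zeros(len(members))
        for a_pos, a_idx in enumerate(members):
            for b_pos in range(a_pos + 1, len(members)):
                r = rmsd(frames[a_idx], frames[members[b_pos]])
                sums[a_pos] += r
                sums[b_pos] += r
        medoids.append(int(members[np.argmin(sums)]))
    reps = tuple(Conformation(frames[i]) for i in medoids)
    return ClusterResult(labels=labels, medoid_frames=tuple(medoids),
                         representatives=reps)
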