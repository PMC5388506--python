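"""Measurement operators: Omega, H-bond lifetimes, PMFs, autocorrelation,
plateau segmentation, RMSD clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import betaroll as br
from betaroll.analysis import PlateauSegment, rmsd
from betaroll.dynamics import KB, Trajectory
from betaroll.errors import (DegenerateHistogramError, EmptyTrajectoryError,
                             NoPeakError)


def _traj(frames, dt=1.0):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(frames=frames,
                      times=dt * np.arange(len(frames), dtype=float),
                      steps=np.arange(len(frames)), dt=dt, save_interval=1)


class TestOmega:
    def test_ideal_stack_saturates(self, stack):
        conf, top = stack
        tr = _traj([conf.coordinates])
        for mol in (0, 1):
            om = br.omega_series(tr, top.omega_pairs_of(mol), molecule=mol)
            assert list(om.omega) == [64]

    def test_extended_chain_is_zero(self, topology):
        # 10 A per-residue spacing: every (i, i+16) pair is 160 A apart
        n = topology.n_residues
        coords = np.zeros((n, 3))
        coords[:, 0] = 10.0 * np.arange(n)
        om = br.omega_series(_traj([coords]), topology.omega_pairs_of(0))
        assert list(om.omega) == [0]

    def test_isometry_invariance(self, stack, rng):
        conf, top = stack
        x = conf.coordinates + rng.normal(0, 0.5, conf.coordinates.shape)
        rot = Rotation.random(random_state=7).as_matrix()
        x2 = x @ rot.T + np.array([3.0, -4.0, 9.0])
        pairs = top.omega_pairs_of(1)
        a = br.omega_series(_traj([x]), pairs).omega
        b = br.omega_series(_traj([x2]), pairs).omega
        assert np.array_equal(a, b)

    def test_window_bounds_inclusive(self):
        coords0 = np.zeros((17, 3))
        coords0[:, 0] = np.arange(17) * 100.0
        for d, expect in [(4.0, 1), (6.0, 1), (3.999, 0), (6.001, 0)]:
            c = coords0.copy()
            c[16] = [d, 0.0, 0.0]  # pair (1, 17) at exactly d
            om = br.omega_series(_traj([c]), [(1, 17)])
            assert om.omega[0] == expect

    def test_empty_trajectory_rejected(self):
        with pytest.raises(EmptyTrajectoryError):
            _traj(np.empty((0, 5, 3)))


class TestHbondIndicator:
    def test_thresholding(self):
        out = br.hbond_indicator([1.8, 2.6, 2.4], 2.5)
        assert list(out) == [1, 0, 1]

    def test_cutoff_inclusive(self):
        assert br.hbond_indicator([2.5], 2.5)[0] == 1

    def test_empty(self):
        assert br.hbond_indicator([], 2.5).size == 0


class TestLifetimes:
    def test_hand_counted_runs(self):
        st_ = br.lifetime_stats([1, 1, 1, 0, 1, 1], frame_interval=1.0)
        assert st_.event_count == 2
        assert st_.mean_lifetime == pytest.approx(2.5)
        assert st_.max_lifetime == pytest.approx(3.0)
        assert st_.occupancy == pytest.approx(5 / 6)

    def test_all_zeros_flagged(self):
        st_ = br.lifetime_stats([0, 0, 0])
        assert st_.event_count == 0
        assert st_.mean_lifetime == 0.0 and st_.max_lifetime == 0.0
        assert not st_.has_events

    def test_all_ones_single_event(self):
        st_ = br.lifetime_stats([1] * 7, frame_interval=2.0)
        assert st_.event_count == 1
        assert st_.max_lifetime == pytest.approx(14.0)

    @settings(derandomize=True, max_examples=80)
    @given(series=st.lists(st.integers(min_value=0, max_value=1),
                           min_size=1, max_size=60),
           interval=st.floats(min_value=0.1, max_value=10.0))
    def test_occupancy_identity(self, series, interval):
        """Sum of event lifetimes equals occupancy x total time, exactly."""
        st_ = br.lifetime_stats(series, frame_interval=interval)
        total = st_.event_count * st_.mean_lifetime
        assert total == pytest.approx(st_.occupancy * len(series) * interval)
        assert st_.mean_lifetime <= st_.max_lifetime + 1e-12


class TestPMF:
    def test_two_state_free_energy_difference(self):
        # p = 0.8 / 0.2 in two bins: dF = kB T ln 4
        d = np.array([1.0] * 800 + [2.0] * 200) + 0.05
        pmf = br.unweighted_pmf(d, bin_size=1.0, temperature=300.0)
        finite = pmf.f[np.isfinite(pmf.f)]
        assert finite.min() == 0.0
        df = finite.max()
        assert df == pytest.approx(KB * 300.0 * np.log(4.0), rel=1e-9)
        assert df == pytest.approx(0.8266, abs=5e-4)

    def test_uniform_profile_is_flat(self, rng):
        d = rng.uniform(2.0, 3.0, 200000)
        pmf = br.unweighted_pmf(d, bin_size=0.25, temperature=300.0)
        assert np.nanmax(pmf.f) < 0.02

    def test_degenerate_series_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            br.unweighted_pmf(np.full(100, 2.5), 0.1)
        with pytest.raises(EmptyTrajectoryError):
            br.unweighted_pmf([], 0.1)

    def test_bin_size_robustness(self, rng):
        """Well-sampled data: three bin sizes give matching profiles."""
        d = np.abs(rng.normal(3.0, 0.5, 400000))
        profiles = {b: br.unweighted_pmf(d, b, 300.0)
                    for b in (0.1, 0.2, 0.4)}
        grid = np.linspace(2.0, 4.0, 21)
        curves = []
        for pmf in profiles.values():
            ok = np.isfinite(pmf.f)
            curves.append(np.interp(grid, pmf.bin_centers[ok], pmf.f[ok]))
        for other in curves[1:]:
            np.testing.assert_allclose(curves[0], other, atol=0.05)

    def test_sample_counts_retained(self):
        pmf = br.unweighted_pmf([1.0, 1.1, 2.0], 1.0)
        assert pmf.counts.sum() == 3


class TestBondStrength:
    @staticmethod
    def _profile(f, lo=1.0, bs=0.5):
        f = np.asarray(f, dtype=float)
        edges = lo + bs * np.arange(len(f) + 1)
        return br.PMFProfile(bin_edges=edges, f=f,
                             counts=np.ones_like(f), bin_size=bs,
                             temperature=300.0)

    def test_constructed_first_peak(self):
        # min 0 at ~1.9, local max 2.5 at ~3.0, second basin after
        pmf = self._profile([3.0, 0.0, 1.0, 2.5, 1.5, 1.0],
                            lo=1.4, bs=0.55)
        assert br.bond_strength(pmf) == pytest.approx(2.5)

    def test_monotone_profile_has_no_peak(self):
        with pytest.raises(NoPeakError):
            br.bond_strength(self._profile([0.0, 0.5, 1.0, 1.5, 2.0]))

    def test_plateau_breaks_tie_to_smaller_distance(self):
        pmf = self._profile([0.0, 1.0, 2.0, 2.0, 1.0, 0.5])
        assert br.bond_strength(pmf) == pytest.approx(2.0)


class TestReweight:
    def test_zero_bias_equals_unweighted(self, rng):
        d = rng.uniform(1.0, 4.0, 5000)
        a = br.unweighted_pmf(d, 0.2, 300.0)
        b = br.reweight_pmf(d, np.zeros_like(d), 0.2, 300.0)
        np.testing.assert_array_equal(a.f, b.f)

    def test_constant_bias_cancels(self, rng):
        d = rng.uniform(1.0, 4.0, 5000)
        a = br.unweighted_pmf(d, 0.2, 300.0)
        b = br.reweight_pmf(d, np.full_like(d, 7.3), 0.2, 300.0)
        np.testing.assert_allclose(a.f, b.f, atol=1e-10)

    def test_harmonic_boost_reweights_to_boltzmann(self):
        """Boosted harmonic-well sampling, reweighted, matches the
        analytic Boltzmann profile from quadrature."""
        from betaroll.amd import langevin_1d
        k = 2.0

        def u(x):
            return k * (x - 3.0) ** 2

        def g(x):
            return 2.0 * k * (x - 3.0)

        xs, dv = langevin_1d(u, g, x0=3.0, n_steps=400000, dt=0.02,
                             friction=1.0, temperature=300.0, mass=50.0,
                             seed=8, e_threshold=2.0, alpha=0.5)
        pmf = br.reweight_pmf(xs, dv, 0.2, 300.0)
        kt = KB * 300.0
        ok = np.isfinite(pmf.f) & (pmf.counts > 200)
        expected = u(pmf.bin_centers[ok])
        expected -= expected.min()
        np.testing.assert_allclose(pmf.f[ok], expected, atol=0.12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            br.reweight_pmf([1.0, 2.0], [0.0], 0.1)


class TestOutOfPlane:
    def test_hand_cross_product(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0]])
        v = br.out_of_plane_vectors(_traj([coords]))
        assert v.shape == (1, 1, 3)
        assert abs(v[0, 0, 2]) == pytest.approx(1.0)
        assert v[0, 0, :2] == pytest.approx([0.0, 0.0])

    def test_collinear_flagged_nan(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        v = br.out_of_plane_vectors(_traj([coords]))
        assert np.all(np.isnan(v[0, 0]))

    def test_unit_norm_where_defined(self, stack):
        conf, _ = stack
        v = br.out_of_plane_vectors(_traj([conf.coordinates]))
        norms = np.linalg.norm(v[0], axis=1)
        defined = ~np.isnan(norms)
        np.testing.assert_allclose(norms[defined], 1.0, atol=1e-12)


class TestRelaxation:
    def test_static_structure_never_decays(self, stack):
        conf, _ = stack
        frames = np.repeat(conf.coordinates[None], 30, axis=0)
        v = br.out_of_plane_vectors(_traj(frames))
        acf = br.relaxation_time(v, max_lag=10, frame_interval=1.0)
        assert acf.c[0] == pytest.approx(1.0)
        assert np.all(acf.c > 0.99)
        assert acf.lower_bound
        assert acf.relaxation_time == pytest.approx(10.0)

    def test_independent_vectors_decay_immediately(self, rng):
        v = rng.normal(size=(400, 50, 3))
        v /= np.linalg.norm(v, axis=2, keepdims=True)
        acf = br.relaxation_time(v, max_lag=20, frame_interval=0.5)
        assert acf.c[0] == pytest.approx(1.0)
        assert not acf.lower_bound
        # decorrelated after one interval up to sampling noise, so the
        # interpolated zero crossing sits within the first few lags
        assert acf.relaxation_time <= 4 * 0.5
        assert np.abs(acf.c[1:]).max() < 0.05


class TestPlateaus:
    def test_noiseless_steps_exact(self):
        x = [64.0] * 30 + [52.0] * 30 + [38.0] * 30
        segs = br.segment_plateaus(x, min_duration=10, tolerance=2.0)
        assert [(s.start, s.end, s.level) for s in segs] == [
            (0, 29, 64.0), (30, 59, 52.0), (60, 89, 38.0)]

    def test_constant_series_single_segment(self):
        segs = br.segment_plateaus([5.0] * 40)
        assert segs == [PlateauSegment(start=0, end=39, level=5.0)]

    def test_short_transitions_dropped(self):
        x = [10.0] * 40 + [7.0, 4.0] + [0.0] * 40
        segs = br.segment_plateaus(x, min_duration=10, tolerance=1.0)
        assert [s.level for s in segs] == [10.0, 0.0]


class TestClustering:
    def test_identical_frames_one_cluster(self, stack):
        conf, _ = stack
        frames = np.repeat(conf.coordinates[None], 6, axis=0)
        res = br.cluster_representative(frames, rmsd_cutoff=2.0)
        assert res.n_clusters == 1
        assert rmsd(res.representatives[0].coordinates, frames[0]) < 1e-9

    def test_two_separated_groups(self, stack, rng):
        conf, _ = stack
        a = conf.coordinates
        b = a.copy()
        b[80:] += np.array([0.0, 0.0, 40.0])  # top molecule displaced
        frames = np.array([a + rng.normal(0, 0.05, a.shape)
                           for _ in range(4)]
                          + [b + rng.normal(0, 0.05, a.shape)
                             for _ in range(4)])
        res = br.cluster_representative(frames, rmsd_cutoff=2.0)
        assert res.n_clusters == 2
        assert len(set(res.labels[:4])) == 1
        assert len(set(res.labels[4:])) == 1

    def test_medoid_minimises_summed_rmsd(self, rng):
        """Brute-force oracle over a small random frame set."""
        frames = rng.normal(0, 1.0, (12, 20, 3)).cumsum(axis=1)
        res = br.cluster_representative(frames, rmsd_cutoff=1e9)
        assert res.n_clusters == 1
        sums = [sum(rmsd(frames[i], frames[j]) for j in range(len(frames)))
                for i in range(len(frames))]
        assert res.medoid_frames[0] == int(np.argmin(sums))
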