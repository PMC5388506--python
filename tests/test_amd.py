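"""Dual-boost machinery: boost algebra, prescription, composition,
boosted dynamics, and exponential reweighting against quadrature."""

import numpy as np
import pytest
from scipy.integrate import quad

import betaroll as br
from betaroll.amd import langevin_1d, make_dual_boost_transform
from betaroll.dynamics import KB
from betaroll.errors import InvalidBoostParameterError
from betaroll.model import FrameEnergies


class TestBoostDelta:
    @pytest.mark.parametrize("v,e,alpha,expected", [
        (10.0, 10.0, 5.0, 0.0),          # at threshold
        (12.0, 10.0, 5.0, 0.0),          # above threshold
        (0.0, 10.0, 5.0, 100.0 / 15.0),  # (E-V)^2/(a+E-V)
    ])
    def test_values(self, v, e, alpha, expected):
        assert br.boost_delta(v, e, alpha) == pytest.approx(expected)

    def test_alpha_must_be_positive(self):
        with pytest.raises(InvalidBoostParameterError):
            br.boost_delta(0.0, 10.0, 0.0)
        with pytest.raises(InvalidBoostParameterError):
            br.boost_force_factor(0.0, 10.0, -1.0)


class TestBoostFactor:
    @pytest.mark.parametrize("v,e,alpha,expected", [
        (10.0, 10.0, 5.0, 1.0),
        (0.0, 10.0, 5.0, 25.0 / 225.0),
        (5.0, 10.0, 1e9, 1.0),           # vanishing-boost limit
    ])
    def test_values(self, v, e, alpha, expected):
        assert br.boost_force_factor(v, e, alpha) == pytest.approx(
            expected, rel=1e-6)

    def test_continuity_at_threshold(self):
        eps = 1e-9
        assert br.boost_force_factor(10.0 - eps, 10.0, 5.0) == pytest.approx(
            1.0, abs=1e-8)
        assert br.boost_delta(10.0 - eps, 10.0, 5.0) == pytest.approx(
            0.0, abs=1e-8)


def test_boost_invariants_over_parameter_grid():
    """dV >= 0, V <= V* <= E, factor in (0, 1], order preservation."""
    vs = np.linspace(-50.0, 30.0, 41)
    for e in (-10.0, 0.0, 10.0, 25.0):
        for alpha in (0.5, 5.0, 50.0):
            dv = br.boost_delta(vs, e, alpha)
            fac = br.boost_force_factor(vs, e, alpha)
            vstar = vs + dv
            assert np.all(dv >= 0)
            assert np.all(vstar >= vs)
            below = vs < e
            assert np.all(vstar[below] <= e + 1e-12)
            assert np.all(dv[~below] == 0)
            assert np.all((fac > 0) & (fac <= 1))
            # order preservation: boosting never swaps energy ordering,
            # so minima stay where they were
            assert np.all(np.diff(vstar) > 0)
            # analytic derivative matches finite differences of V*
            h = 1e-6
            num = (br.boost_delta(vs + h, e, alpha)
                   - br.boost_delta(vs - h, e, alpha)) / (2 * h) + 1.0
            inner = np.abs(vs - e) > 1e-3  # away from the kink
            np.testing.assert_allclose(num[inner], fac[inner], atol=1e-5)


class TestPrescription:
    def test_dihedral_factor_from_residue_count(self):
        p = br.prescribe_parameters(0.0, 0.0, n_res=160, n_atoms=100, n=2)
        assert p.alpha_dihedral == pytest.approx(112.0)
        assert p.e_dihedral == pytest.approx(560.0)

    def test_total_channel_from_atom_count(self):
        p = br.prescribe_parameters(-30000.0, 0.0, n_res=10,
                                    n_atoms=10000, n=2)
        assert p.alpha_total == pytest.approx(2000.0)
        assert p.e_total == pytest.approx(-26000.0)

    @pytest.mark.parametrize("n", [2.0, 2.5])
    def test_study_thresholds_supported(self, n):
        p = br.prescribe_parameters(-100.0, 5.0, 160, 160, n=n)
        assert p.n == n
        assert p.e_total == pytest.approx(-100.0 + n * 32.0)

    def test_counts_must_be_positive(self):
        with pytest.raises(InvalidBoostParameterError):
            br.prescribe_parameters(0.0, 0.0, 0, 10)


class TestDualBoost:
    params = br.BoostParameters(e_total=10.0, e_dihedral=4.0,
                                alpha_total=5.0, alpha_dihedral=2.0,
                                n=2.0, n_res=10, n_atoms=10)

    def test_above_both_thresholds_is_identity(self):
        fe = FrameEnergies(v_dihedral=6.0, v_non_dihedral=10.0)
        vstar, entry = br.dual_boost(fe, self.params)
        assert vstar == fe.v_total
        assert entry.dv_dihedral == 0 and entry.dv_total == 0
        assert not entry.dihedral_boosted and not entry.total_boosted

    def test_only_dihedral_boost_applied(self):
        # dihedral below its threshold, total above E_total
        fe = FrameEnergies(v_dihedral=2.0, v_non_dihedral=10.0)
        dv_d = br.boost_delta(2.0, 4.0, 2.0)  # = 4/(2+2) = 1
        vstar, entry = br.dual_boost(fe, self.params)
        assert entry.dv_dihedral == pytest.approx(dv_d)
        assert entry.dv_total == 0.0
        assert vstar == pytest.approx(fe.v_total + dv_d)

    def test_bookkeeping_identity(self):
        fe = FrameEnergies(v_dihedral=1.0, v_non_dihedral=2.0)
        vstar, entry = br.dual_boost(fe, self.params)
        assert vstar - fe.v_total == pytest.approx(
            entry.dv_dihedral + entry.dv_total)

    def test_raised_threshold_never_lowers_total_boost(self):
        fe = FrameEnergies(v_dihedral=1.0, v_non_dihedral=2.0)
        dv = []
        for n in (1.0, 2.0, 2.5, 3.0):
            p = br.prescribe_parameters(-5.0, 0.5, 10, 10, n=n)
            _, entry = br.dual_boost(fe, p)
            dv.append(entry.dv_total)
        assert np.all(np.diff(dv) >= 0)


def test_zero_boost_limit_matches_cmd(stack, forcefield):
    """Thresholds below every visited energy: aMD == cMD bitwise."""
    conf, _ = stack
    params = br.BoostParameters(e_total=-1e9, e_dihedral=-1e9,
                                alpha_total=1.0, alpha_dihedral=1.0,
                                n=2.0, n_res=160, n_atoms=160)
    a = br.run_amd(forcefield, conf, params, n_steps=1500,
                   save_interval=10, seed=3)
    c = br.run_cmd(forcefield, conf, n_steps=1500, save_interval=10, seed=3)
    assert np.array_equal(a.trajectory.frames, c.trajectory.frames)
    assert np.all(a.trajectory.energies["dv_total"] == 0)
    assert np.all(a.trajectory.energies["dv_dihedral"] == 0)


def test_boost_record_nonnegative_and_logged(amd_template_run):
    log = amd_template_run.trajectory.energies
    assert np.all(log["dv_total"] >= 0)
    assert np.all(log["dv_dihedral"] >= 0)
    assert log["dv_dihedral"].mean() > 0


_DW_H = 3.0


def _dw(x):
    return _DW_H * (x * x - 1.0) ** 2


def _dw_grad(x):
    return 4.0 * _DW_H * x * (x * x - 1.0)


def test_boosted_crossings_exceed_unboosted():
    """Flattened barriers: boosted double-well crossing count is higher."""
    def crossings(x):
        s = np.sign(x)
        s = s[s != 0]
        return int((np.diff(s) != 0).sum())

    common = dict(x0=-1.0, n_steps=150000, dt=0.02, friction=1.0,
                  temperature=300.0, mass=50.0, seed=4)
    xs_u, dv_u = langevin_1d(_dw, _dw_grad, **common)
    xs_b, dv_b = langevin_1d(_dw, _dw_grad, e_threshold=_DW_H,
                             alpha=1.0, **common)
    assert np.all(dv_u == 0)
    assert np.all(dv_b >= 0)
    assert crossings(xs_b) >= crossings(xs_u)
    assert crossings(xs_b) > 5 * crossings(xs_u)  # strongly accelerated


def test_reweighting_recovers_boltzmann_populations():
    """exp(dV/kBT) reweighting of a boosted asymmetric double well
    reproduces the quadrature Boltzmann population split."""
    kt = KB * 300.0

    def u(x):
        return _dw(x) + 0.5 * x

    def g(x):
        return _dw_grad(x) + 0.5

    xs, dv = langevin_1d(u, g, x0=-1.0, n_steps=400000, dt=0.02,
                         friction=1.0, temperature=300.0, mass=50.0,
                         seed=5, e_threshold=_DW_H, alpha=1.0)
    w = np.exp((dv - dv.max()) / kt)
    p_right = float(w[xs > 0].sum() / w.sum())
    z = quad(lambda x: np.exp(-u(x) / kt), -3, 3)[0]
    p_exact = quad(lambda x: np.exp(-u(x) / kt), 0, 3)[0] / z
    # raw boosted populations are far off; reweighted agree within MC error
    assert abs((xs > 0).mean() - p_exact) > 0.1
    assert p_right == pytest.approx(p_exact, abs=0.05)


def test_dual_boost_transform_consistent_with_record(stack, forcefield,
                                                     boost_params):
    conf, _ = stack
    energies, f_dih, f_other = forcefield.evaluate(conf.coordinates)
    transform = make_dual_boost_transform(boost_params)
    force, dv_dih, dv_tot = transform(energies, f_dih, f_other)
    _, entry = br.dual_boost(energies, boost_params)
    assert dv_dih == pytest.approx(entry.dv_dihedral)
    assert dv_tot == pytest.approx(entry.dv_total)
    assert force.shape == f_dih.shape
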