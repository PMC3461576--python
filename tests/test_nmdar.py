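"""NMDAR: Woodhull Mg block, sigmoidal conductance, current, desensitization."""

import numpy as np
import pytest

import tripsyn as ts
from tripsyn.kinetics import integrate_scheme


@pytest.fixture(scope="module")
def params():
    return ts.NMDARParams()


@pytest.fixture(scope="module")
def scheme(params):
    return params.scheme()


def open_state(scheme, o):
    x = np.zeros(scheme.n)
    x[scheme.index("R0G2")] = 1.0 - o
    x[scheme.index("O")] = o
    return x


class TestMgBlock:
    def test_no_magnesium_no_block(self):
        p = ts.NMDARParams(mg_out=0.0)
        for v in (-90.0, -20.0, 40.0):
            assert ts.mg_block_factor(v, p) == 1.0

    def test_half_block_at_k0(self):
        p = ts.NMDARParams(mg_out=ts.NMDARParams().K0)
        assert ts.mg_block_factor(0.0, p) == pytest.approx(0.5)

    def test_strictly_increasing_in_voltage(self, params):
        vs = np.linspace(-100, 60, 33)
        f = [ts.mg_block_factor(v, params) for v in vs]
        assert np.all(np.diff(f) > 0)
        assert ts.mg_block_factor(-70, params) < ts.mg_block_factor(0, params)
        assert ts.mg_block_factor(0, params) < ts.mg_block_factor(40, params)

    def test_calibration_point(self, params):
        """Default K0 gives ~10% unblocked at -70 mV in 1 mM Mg."""
        assert ts.mg_block_factor(-70.0, params) == pytest.approx(0.1, abs=0.005)


class TestConductance:
    def test_plateaus(self, params):
        assert ts.nmdar_conductance(-2000.0, params) == pytest.approx(247.0, abs=0.1)
        assert ts.nmdar_conductance(2000.0, params) == pytest.approx(40.0, abs=0.1)

    def test_midpoint_at_zero(self, params):
        assert ts.nmdar_conductance(0.0, params) == pytest.approx((40 + 247) / 2)

    def test_flat_limit(self):
        p = ts.NMDARParams(alpha=1e-12)
        assert ts.nmdar_conductance(-70.0, p) == pytest.approx(143.5)

    def test_bounded(self, params):
        for v in np.linspace(-150, 150, 31):
            g = ts.nmdar_conductance(v, params)
            assert 40.0 <= g <= 247.0


class TestCurrent:
    def test_closed_is_zero(self, params, scheme):
        assert ts.nmdar_current(open_state(scheme, 0.0), -70.0, params) == 0.0

    def test_reversal(self, params, scheme):
        assert ts.nmdar_current(open_state(scheme, 0.3), 0.0, params) == 0.0

    def test_hand_computed_no_mg(self, scheme):
        p = ts.NMDARParams(mg_out=0.0)
        x = open_state(scheme, 0.05)
        g = ts.nmdar_conductance(-70.0, p)
        expected = 20 * g * (-70.0) * 0.05 * 1e-3
        assert ts.nmdar_current(x, -70.0, p) == pytest.approx(expected)

    def test_j_shaped_iv(self, params, scheme):
        """Mg block produces a negative-slope region between -90 and 0 mV."""
        x = open_state(scheme, 0.2)
        vs = np.linspace(-90, 0, 46)
        i = np.array([ts.nmdar_current(x, v, params) for v in vs])
        slopes = np.diff(i) / np.diff(vs)
        assert slopes.min() < 0
        # and the current is inward (negative) throughout this range
        assert np.all(i[1:-1] < 0)


class TestIntegration:
    def test_resting_is_stationary(self, params, scheme):
        t = np.linspace(0, 100, 11)
        x0 = ts.stationary_distribution(scheme.generator(0.0))
        traj = ts.integrate_nmdar(lambda t: 0.0, t, params, initial=x0)
        assert np.allclose(traj, traj[0], atol=1e-9)

    def test_piecewise_constant_matches_expm(self, params, scheme):
        x = ts.stationary_distribution(scheme.generator(0.0))
        segs = [(1.0, 1.0), (0.0, 30.0)]
        ref = ts.propagate_expm(scheme, x, segs)
        for glu, d in segs:
            x = integrate_scheme(
                scheme, lambda t: glu, np.array([0.0, d]), x, rtol=1e-10, atol=1e-12
            )[-1]
        assert np.allclose(x, ref, rtol=1e-6, atol=1e-9)

    def test_desensitization_grows_with_interval(self, params, scheme):
        """Desensitized occupancy just before a 2nd pulse rises from 10 to
        300 ms intervals (slow accumulation from long-lived bound states)."""
        d_idx = [scheme.index(s) for s in scheme.meta["desensitized_states"]]
        x0 = ts.stationary_distribution(scheme.generator(0.0))

        def des_before_second(interval):
            def glu(t):
                return 1.0 if t < 1.0 else 0.0

            t = np.linspace(0, 1.0 + interval, 400)
            traj = ts.integrate_nmdar(glu, t, params, initial=x0)
            return traj[-1, d_idx].sum()

        assert des_before_second(10.0) < des_before_second(300.0)
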