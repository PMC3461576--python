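"""EAAT2/EAAT3 transporter counts, flux equation and uptake bookkeeping."""

import numpy as np
import pytest
from scipy.linalg import expm

import tripsyn as ts
from tripsyn.kinetics import integrate_scheme
from tripsyn.transporters import A_EFF_UM2, apply_uptake, cleft_volume_um3


class TestCounts:
    def test_full_density_half_coverage(self):
        assert ts.transporter_count(13000, 0.5, A_EFF_UM2) == 650

    def test_half_density(self):
        assert ts.transporter_count(6500, 0.5, A_EFF_UM2) == 325

    def test_zero_density(self):
        assert ts.transporter_count(0, 0.7, 12.0) == 0

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            ts.transporter_count(-1, 0.5, 1.0)

    def test_param_objects_expose_counts(self):
        assert ts.EAAT2Params().count == 650
        assert ts.EAAT2Params(density=6500).count == 325
        # 90 um^-2 over the 100-400 nm annulus
        assert ts.EAAT3Params().count == round(90 * np.pi * (0.4**2 - 0.1**2))

    def test_coverage_bounds(self):
        with pytest.raises(ValueError):
            ts.EAAT2Params(coverage=1.5)


class TestFlux:
    def setup_method(self):
        self.scheme = ts.EAAT2Params().scheme()

    def _state(self, **occ):
        x = np.zeros(self.scheme.n)
        rest = 1.0 - sum(occ.values())
        x[self.scheme.index("Na2ToH")] = rest
        for name, v in occ.items():
            x[self.scheme.index(name)] = v
        return x

    def test_zero_glu_zero_bound_is_zero(self):
        x = self._state()
        assert ts.glutamate_flux(x, 0.0, self.scheme) == 0.0

    def test_unbinding_only(self):
        """With glu=0 and 10% in each glu-bound state, flux = -0.5*0.1*2."""
        x = self._state(Na2ToGH=0.1, Na2ToG=0.1)
        assert ts.glutamate_flux(x, 0.0, self.scheme) == pytest.approx(-0.1)

    def test_positive_on_binding(self):
        x = self._state()
        assert ts.glutamate_flux(x, 1.0, self.scheme) > 0

    def test_square_pulse_integral_matches_expm(self):
        """Time-integrated flux over a 1-ms 1-mM pulse: expm oracle.

        The cumulative flux is appended as an auxiliary quadrature state and
        cross-checked against the integral of the flux along the matrix-
        exponential trajectory of the fixed-glu generator.
        """
        s = self.scheme
        glu = 1.0
        x0 = ts.stationary_distribution(s.generator(0.0))
        t_grid = np.linspace(0.0, 1.0, 201)
        traj = integrate_scheme(s, lambda t: glu, t_grid, x0, rtol=1e-10, atol=1e-12)
        flux_traj = [ts.glutamate_flux(x, glu, s) for x in traj]
        integral_ode = np.trapezoid(flux_traj, t_grid)

        G = s.generator(glu)
        xs = [expm(G * t) @ x0 for t in t_grid]
        integral_expm = np.trapezoid([ts.glutamate_flux(x, glu, s) for x in xs], t_grid)
        assert integral_ode == pytest.approx(integral_expm, rel=1e-6)

    def test_invalid_state_raises(self):
        with pytest.raises(ValueError):
            ts.glutamate_flux(np.full(self.scheme.n, 0.5), 1.0, self.scheme)


class TestRateMatrices:
    def test_glu_zero_disables_binding(self):
        s = ts.EAAT2Params().scheme()
        G = ts.eaat2_rate_matrix(0.0)
        i, j = s.index("Na2To"), s.index("Na2ToG")
        assert G[j, i] == 0.0

    def test_eaat3_matrix_valid(self):
        G = ts.eaat3_rate_matrix(0.5)
        assert np.allclose(G.sum(axis=0), 0.0, atol=1e-12)


class TestApplyUptake:
    def setup_method(self):
        self.t = np.linspace(0, 10, 101)
        self.glu = 0.5 * np.exp(-self.t / 3.0)
        self.cum = np.linspace(0, 0.8, 101)  # per-transporter molecules

    def test_zero_transporters_identity(self):
        dep, rec = apply_uptake(self.t, self.glu, 0, self.cum)
        assert np.array_equal(dep, self.glu)
        assert rec.n_transporters == 0

    def test_clamped_at_zero(self):
        dep, _ = apply_uptake(self.t, self.glu, 10000, self.cum)
        assert np.all(dep >= 0.0)
        assert dep[-1] == 0.0

    def test_monotone_in_transporter_count(self):
        deps = [
            apply_uptake(self.t, self.glu, n, self.cum)[0]
            for n in (0, 100, 200, 400)
        ]
        for a, b in zip(deps, deps[1:]):
            assert np.all(b <= a + 1e-15)

    def test_mismatched_grids_raise(self):
        with pytest.raises(ValueError):
            apply_uptake(self.t, self.glu[:-1], 10, self.cum)

    def test_volume_default_is_ensheathment_cylinder(self):
        assert cleft_volume_um3() == pytest.approx(np.pi * 0.4**2 * 0.02)


class TestRecovery:
    def test_hgn3to_recovery_is_slow(self, default_config):
        """The loaded outward state returns to baseline only after >100 ms."""
        import dataclasses

        cfg = dataclasses.replace(default_config, tail=900.0, eaat3=None)
        tr = ts.run_synapse(ts.single_pulse(), cfg)
        h = tr["eaat2_HGN3To"]
        t = tr.t
        pk = int(np.argmax(h))
        dev = np.abs(h - h[0])
        rec = np.where(dev[pk:] <= 0.05 * (h[pk] - h[0]))[0]
        t95 = t[pk + rec[0]] - 1.0
        assert t95 > 100.0
        dev50 = dev[np.searchsorted(t, 51.0)]
        dev500 = dev[np.searchsorted(t, 501.0)]
        assert dev500 < dev50
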