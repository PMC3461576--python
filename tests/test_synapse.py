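"""Coupled synapse runs: composition, depletion identities, PPR mechanics."""

import dataclasses

import numpy as np
import pytest

import tripsyn as ts
from tripsyn.synapse import TraceSet


class TestRunSynapse:
    def test_empty_protocol_all_quiet(self, default_config):
        proto = ts.StimulusProtocol(kind="empty", events=())
        tr = ts.run_synapse(proto, default_config)
        for ch in ("I_AMPA", "I_NMDA", "I_syn", "glu_free", "glu_depleted"):
            assert np.allclose(tr[ch], 0.0, atol=1e-12)

    def test_additivity_exact(self, single_pulse_traces):
        for tr in single_pulse_traces.values():
            assert np.array_equal(tr["I_syn"], tr["I_AMPA"] + tr["I_NMDA"])

    def test_no_uptake_identity(self, single_pulse_traces):
        tr = single_pulse_traces["off"]
        assert np.array_equal(tr["glu_depleted"], tr["glu_free"])

    def test_uptake_reduces_ampar_peak(self, single_pulse_traces):
        on, off = single_pulse_traces["on"], single_pulse_traces["off"]
        assert abs(on["I_AMPA"].min()) < abs(off["I_AMPA"].min())

    def test_uptake_reduces_desensitization(self, single_pulse_traces):
        """Uptake shortens the glutamate exposure, so receptors desensitize
        less — the mechanistic root of the facilitation reversal."""
        on, off = single_pulse_traces["on"], single_pulse_traces["off"]
        assert on["ampar_desensitized_total"].max() < off[
            "ampar_desensitized_total"
        ].max()

    def test_determinism_bit_identical(self, default_config):
        proto = ts.paired_pulse(30.0)
        a = ts.run_synapse(proto, default_config)
        b = ts.run_synapse(proto, default_config)
        assert np.array_equal(a.t, b.t)
        for ch in a.channels:
            assert np.array_equal(a[ch], b[ch])

    def test_currents_are_inward_at_negative_holding(self, single_pulse_traces):
        tr = single_pulse_traces["off"]
        assert tr["I_AMPA"].min() < 0
        assert tr["I_NMDA"].min() < 0
        assert tr["I_AMPA"].max() <= 1e-12


class TestPpr:
    def _bump_trace(self, ratio):
        t = np.arange(0.0, 120.0, 0.1)
        bump = lambda t0, a: -a * np.exp(-((t - t0) ** 2) / 2.0) * (t > t0 - 5)
        i = bump(10.0, 1.0) + bump(60.0, ratio)
        return TraceSet(t=t, channels={"I_syn": i})

    def test_identical_responses_give_unity(self):
        proto = ts.paired_pulse(50.0, t0=5.0)
        tr = self._bump_trace(1.0)
        assert ts.ppr(tr, proto) == pytest.approx(1.0, abs=1e-6)

    def test_scaled_second_response(self):
        proto = ts.paired_pulse(50.0, t0=5.0)
        assert ts.ppr(self._bump_trace(1.3), proto) == pytest.approx(1.3, abs=1e-6)

    def test_requires_two_events(self):
        with pytest.raises(ValueError):
            ts.ppr(self._bump_trace(1.0), ts.single_pulse())

    def test_reversal_at_50ms(self, default_config):
        """Headline effect: facilitation with uptake, depression without."""
        proto = ts.paired_pulse(50.0)
        on = ts.ppr(ts.run_synapse(proto, default_config), proto)
        off = ts.ppr(ts.run_synapse(proto, default_config.without_uptake()), proto)
        assert on > 1.0
        assert off < 1.0


class TestDesensitizationReadout:
    def test_baseline_before_release(self, single_pulse_traces):
        tr = single_pulse_traces["off"]
        assert ts.desensitization_readout(tr, "ampar", 0.5) == pytest.approx(
            0.0, abs=1e-9
        )
        assert 0.0 <= ts.desensitization_readout(tr, "nmdar", 0.5) <= 1e-9

    def test_short_interval_more_ampar_desensitization(self, default_config):
        tr10 = ts.run_synapse(ts.paired_pulse(10.0), default_config)
        tr500 = ts.run_synapse(ts.paired_pulse(500.0), default_config)
        d10 = ts.desensitization_readout(tr10, "ampar", 1.0 + 10.0 - 0.1)
        d500 = ts.desensitization_readout(tr500, "ampar", 1.0 + 500.0 - 0.1)
        assert d10 > d500

    def test_unknown_receptor_raises(self, single_pulse_traces):
        with pytest.raises(ValueError):
            ts.desensitization_readout(single_pulse_traces["off"], "gaba", 1.0)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        from tripsyn.config import load_config

        p = tmp_path / "cfg.yaml"
        p.write_text(
            "synapse:\n"
            "  eaat2: {density: 6500}\n"
            "  eaat3: null\n"
            "  ampar: {nb_ampa: 40}\n"
            "  nmdar: {mg_out: 2.0}\n"
            "  v_hold: -60.0\n"
        )
        cfg = load_config(p)
        assert cfg.eaat2.density == 6500
        assert cfg.eaat3 is None
        assert cfg.ampar.nb_ampa == 40
        assert cfg.nmdar.mg_out == 2.0
        assert cfg.v_hold == -60.0

    def test_unknown_key_rejected(self, tmp_path):
        from tripsyn.config import load_config

        p = tmp_path / "bad.yaml"
        p.write_text("synapse:\n  ampar: {nb_gaba: 1}\n")
        with pytest.raises(KeyError):
            load_config(p)

    def test_rate_override_through_config(self):
        from tripsyn.config import synapse_config_from_dict

        cfg = synapse_config_from_dict(
            {"ampar": {"rate_overrides": {"C2->O2": 1.0}}}
        )
        default = ts.AMPARParams().scheme()
        assert not np.allclose(
            cfg.ampar.scheme().generator(1.0), default.generator(1.0)
        )
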