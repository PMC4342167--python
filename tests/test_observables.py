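"""Derived read-outs: baselines, mixtures, rates, sign conventions."""

import numpy as np
import pytest

import ngvsim as ngv
from ngvsim.engine import Trajectory
from ngvsim.observables import (
    bold_signal,
    firing_rate,
    lactate_transports,
    metabolic_rates,
    nadh_transients,
    tissue_mix,
)


def synthetic_trajectory(params, base_state, factor_by_name=None, n=5):
    """A hand-built constant (or scaled) trajectory for mixture algebra tests."""
    states = np.tile(base_state, (n, 1))
    if factor_by_name:
        for name, factors in factor_by_name.items():
            states[:, ngv.STATE_INDEX[name]] = base_state[ngv.STATE_INDEX[name]] * factors
    return Trajectory(
        t=np.arange(n, dtype=float),
        states=states,
        spike_times=np.empty(0),
        scenario=ngv.make_scenario(
            "in_vivo_rodent", stim_duration=1.0, total_duration=float(n)
        ),
        params=params,
        rtol=1e-6,
    )


class TestBold:
    def test_zero_at_baseline(self, params, steady):
        traj = synthetic_trajectory(params, steady.state)
        assert np.all(bold_signal(traj).values == 0.0)

    def test_deoxygenation_decreases_signal(self, params, steady):
        up = np.array([1.0, 1.02, 1.05, 1.05, 1.05])
        traj = synthetic_trajectory(params, steady.state, {"dHb": up})
        vals = bold_signal(traj).values
        assert vals[0] == 0.0
        assert np.all(vals[1:] < 0.0)

    def test_washout_increases_signal(self, params, steady):
        down = np.array([1.0, 0.95, 0.9, 0.9, 0.9])
        traj = synthetic_trajectory(params, steady.state, {"dHb": down})
        assert np.all(bold_signal(traj).values[1:] > 0.0)


class TestTissueMix:
    def test_baseline_mixture_is_zero(self, params, steady):
        traj = synthetic_trajectory(params, steady.state)
        for q in ("NADH", "LAC", "O2"):
            np.testing.assert_allclose(tissue_mix(traj, q).values, 0.0, atol=1e-12)

    def test_uniform_deviation_passes_through(self, params, steady):
        factors = np.array([1.0, 1.1, 1.1, 1.1, 1.1])  # first row is baseline
        names = ["LAC_n", "LAC_g", "LAC_e", "LAC_c"]
        traj = synthetic_trajectory(params, steady.state, {n: factors for n in names})
        np.testing.assert_allclose(tissue_mix(traj, "LAC").values[1:], 10.0, rtol=1e-9)

    def test_mixture_inside_compartment_envelope(self, invitro_traj):
        mix = tissue_mix(invitro_traj, "O2").values
        comp = np.stack([
            100.0 * (invitro_traj.state(n) / invitro_traj.baseline[ngv.STATE_INDEX[n]] - 1.0)
            for n in ("O2_n", "O2_g")
        ])
        assert np.all(mix <= comp.max(axis=0) + 1e-9)
        assert np.all(mix >= comp.min(axis=0) - 1e-9)

    def test_unknown_quantity_rejected(self, params, steady):
        traj = synthetic_trajectory(params, steady.state)
        with pytest.raises(ngv.ModelDomainError):
            tissue_mix(traj, "GLYCOGEN")


class TestMetabolicRates:
    def test_rest_partition_follows_the_imposed_compartmentalization(self, params, steady):
        """At rest astrocytes take the larger glucose share and neurons the
        larger oxygen share."""
        traj = synthetic_trajectory(params, steady.state)
        rates = metabolic_rates(traj)
        assert rates["CMRglc_g"].baseline > rates["CMRglc_n"].baseline
        assert rates["CMRO2_n"].baseline > rates["CMRO2_g"].baseline

    def test_rest_ogi_in_physiological_range(self, params, steady):
        traj = synthetic_trajectory(params, steady.state)
        ogi = metabolic_rates(traj)["OGI"].baseline
        assert 4.5 < ogi < 6.5

    def test_total_oxygen_consumption_matches_blood_supply_at_rest(self, params, steady):
        traj = synthetic_trajectory(params, steady.state)
        cmro2 = metabolic_rates(traj)["CMRO2"].baseline
        o2_c = steady.state_dict()["O2_c"]
        supply = 2.0 * params.f_0 * (params.o2_a - o2_c)
        assert cmro2 == pytest.approx(supply, rel=1e-6)


class TestLactateTransports:
    def test_rest_sign_structure_is_astrocyte_to_neuron(self, params, steady):
        """At rest the astrocyte exports lactate, the neuron imports it (net
        import negative by convention) and a small surplus leaves to the
        capillary."""
        traj = synthetic_trajectory(params, steady.state)
        trans = lactate_transports(traj)
        assert trans["J_LAC_ge"].baseline > 0.0
        assert trans["J_LAC_ne"].baseline < 0.0
        assert trans["J_LAC_ec"].baseline > 0.0
        # LDH direction mirrors the transports
        assert trans["J_LDH_n"].baseline < 0.0
        assert trans["J_LDH_g"].baseline > 0.0

    def test_uniform_concentrations_kill_all_net_transports(self, params, steady):
        y = steady.state.copy()
        for name in ("LAC_n", "LAC_g", "LAC_e", "LAC_c"):
            y[ngv.STATE_INDEX[name]] = 0.6
        traj = synthetic_trajectory(params, y)
        trans = lactate_transports(traj)
        for key in ("J_LAC_ge", "J_LAC_ne", "J_LAC_ec", "J_LAC_gc"):
            assert trans[key].baseline == pytest.approx(0.0, abs=1e-15)


class TestFiringRate:
    def _traj(self, params, steady, spikes):
        traj = synthetic_trajectory(params, steady.state)
        traj.spike_times = np.asarray(spikes, dtype=float)
        return traj

    def test_no_spikes_empty_series(self, params, steady):
        series = firing_rate(self._traj(params, steady, []))
        assert series.t.size == 0

    def test_uniform_train(self, params, steady):
        series = firing_rate(self._traj(params, steady, [0.0, 0.25, 0.5, 0.75]))
        np.testing.assert_allclose(series.values, 4.0)

    def test_decelerating_train_has_decreasing_rate(self, params, steady):
        spikes = np.cumsum([0.0, 0.1, 0.2, 0.4, 0.8])
        series = firing_rate(self._traj(params, steady, spikes))
        assert np.all(np.diff(series.values) < 0.0)


class TestNADHTransients:
    def test_constant_run_has_identically_zero_transients(self, params, steady):
        traj = synthetic_trajectory(params, steady.state)
        for series in nadh_transients(traj).values():
            np.testing.assert_allclose(series.values, 0.0, atol=1e-12)
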