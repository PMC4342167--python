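"""Steady states, stability classification and integrator guarantees."""

import numpy as np
import pytest

import ngvsim as ngv
from ngvsim.engine import stability_check
from ngvsim.errors import SolverError


class TestSteadyState:
    def test_residual_is_tiny(self, steady):
        assert steady.residual_norm < 1e-9

    def test_resting_voltage_near_published(self, steady):
        assert steady.state_dict()["psi_n"] == pytest.approx(-73.0, rel=0.02)

    def test_extracellular_glucose_near_published(self, steady):
        assert steady.state_dict()["GLC_e"] == pytest.approx(2.48, rel=0.02)

    def test_all_states_close_to_published_resting_values(self, steady):
        rest = ngv.resting_state()
        got = steady.state.copy()
        # the published table prints a single rounded value for the GAP and
        # PEP rows of both cell types; the astrocytic fixed point of the
        # rounded parameter set settles elsewhere, so those two are excluded
        for name in ("GAP_g", "PEP_g"):
            got[ngv.STATE_INDEX[name]] = rest[ngv.STATE_INDEX[name]]
        np.testing.assert_allclose(got, rest, rtol=0.15)

    def test_fixed_point_is_stable(self, steady):
        assert steady.stable
        assert stability_check(steady).max_real_part < 0.0

    def test_enlarged_nad_pool_still_converges(self, params):
        """Well-posedness smoke test: scaling the total NAD pool (with the
        NADH seeds rescaled into it) still yields a tight, stable fixed
        point.  The factor stays at 1.5: beyond that the astrocytic
        glycolytic balance loses its fixed point (GAP grows without bound),
        a genuine property of the rate laws, not a solver limitation."""
        p2 = params.replace(n_tot=1.5 * params.n_tot)
        seed = ngv.resting_state()
        for name in ("NADH_cyto_n", "NADH_cyto_g", "NADH_mito_n", "NADH_mito_g"):
            seed[ngv.STATE_INDEX[name]] *= 1.5
        report = ngv.find_steady_state(p2, seed=seed)
        assert report.residual_norm < 1e-9
        assert report.stable

    def test_clamped_solve_keeps_clamped_values(self, params):
        clamp = ("O2_c", "GLC_c", "LAC_c", "Vv", "dHb")
        report = ngv.find_steady_state(params, clamp_mask=clamp)
        rest = ngv.resting_state()
        for name in clamp:
            assert report.state[ngv.STATE_INDEX[name]] == rest[ngv.STATE_INDEX[name]]


class TestStabilityCheck:
    def test_pure_rotation_is_flagged_unstable_by_convention(self):
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        verdict = stability_check(rot)
        assert not verdict.stable
        assert verdict.max_real_part == pytest.approx(0.0, abs=1e-12)

    def test_negative_diagonal_is_stable(self):
        verdict = stability_check(np.diag([-1.0, -2.5]))
        assert verdict.stable

    def test_one_positive_eigenvalue_is_unstable(self):
        verdict = stability_check(np.array([0.1 + 0j, -3.0 + 0j]))
        assert not verdict.stable


class TestIntegrator:
    def test_zero_stimulus_run_preserves_the_fixed_point(self, params, steady):
        sc = ngv.make_scenario(
            "in_vivo_rodent", stimulus={"f_0": 0.0, "f_inf": 0.0},
            flow={"profile_kind": "constant"}, total_duration=100.0,
        )
        traj = ngv.integrate(sc, params, y0=steady.state, rtol=1e-10,
                             atol_scale=1e-12, max_step_spiking=np.inf)
        drift = np.max(np.abs(traj.states / steady.state - 1.0))
        assert drift < 1e-6
        assert traj.spike_times.size == 0

    def test_bit_identical_determinism(self, params, steady):
        sc = ngv.make_scenario("in_vitro", total_duration=25.0)
        a = ngv.integrate(sc, params, y0=steady.state)
        b = ngv.integrate(sc, params, y0=steady.state)
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_clamped_states_constant_to_machine_precision(self, invitro_traj):
        for name in invitro_traj.scenario.clamped_states:
            col = invitro_traj.state(name)
            assert np.all(col == col[0])

    def test_spike_count_invariant_under_tolerance_refinement(self, params, steady):
        sc = ngv.make_scenario("in_vitro", total_duration=22.0)
        coarse = ngv.integrate(sc, params, y0=steady.state, rtol=1e-6)
        fine = ngv.integrate(sc, params, y0=steady.state, rtol=5e-7)
        assert coarse.spike_times.size == fine.spike_times.size
        np.testing.assert_allclose(coarse.spike_times, fine.spike_times, atol=5e-3)

    def test_refinement_convergence_of_headline_observables(self, params, steady):
        sc = ngv.make_scenario("in_vitro", total_duration=22.0)
        dips = []
        for rtol in (1e-6, 5e-7):
            traj = ngv.integrate(sc, params, y0=steady.state, rtol=rtol)
            dips.append(ngv.nadh_transients(traj)["neuron_mito"].min())
        assert abs(dips[0] / dips[1] - 1.0) < 0.005

    def test_time_grid_strictly_increasing(self, invitro_traj):
        assert np.all(np.diff(invitro_traj.t) > 0.0)


class TestTrajectoryIO:
    def test_csv_round_trip(self, params, steady, tmp_path):
        sc = ngv.make_scenario("in_vitro", stim_duration=1.0, total_duration=3.0)
        traj = ngv.integrate(sc, params, y0=steady.state)
        csv = tmp_path / "run.csv"
        traj.save(csv)
        back = ngv.Trajectory.load(csv)
        np.testing.assert_array_equal(back.t, traj.t)
        np.testing.assert_array_equal(back.states, traj.states)
        np.testing.assert_array_equal(back.spike_times, traj.spike_times)
        assert back.scenario == traj.scenario
        assert back.params == traj.params

    def test_manifest_reproducibility_fields(self, invitro_traj):
        doc = invitro_traj.manifest()
        assert doc["params_digest"] == invitro_traj.params.digest()
        assert doc["scenario"]["kind"] == "in_vitro"
        assert doc["rtol"] == invitro_traj.rtol
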