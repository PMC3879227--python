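"""Integration, dose events, stress protocols, in-vitro read-outs."""

import numpy as np
import pytest

import hpaxis as h
from hpaxis.models import extended_model
from hpaxis.simulate import PROTOCOL_DOSES, invitro_variant


class TestProtocolAndDoseValidation:
    def test_pulse_validation(self):
        with pytest.raises(ValueError):
            h.StressProtocol(pulses=((10.0, 5.0, 1.0),))
        with pytest.raises(ValueError):
            h.StressProtocol(pulses=((0.0, 10.0, 1.0), (5.0, 15.0, 1.0)))
        with pytest.raises(ValueError):
            h.StressProtocol(pulses=((0.0, 10.0, -1.0),))

    def test_stress_lookup(self):
        p = h.StressProtocol(baseline=0.1, pulses=((10.0, 20.0, 0.8),))
        assert p.stress(5.0) == 0.1
        assert p.stress(15.0) == 0.8
        assert p.stress(25.0) == 0.1

    def test_dose_validation(self):
        with pytest.raises(ValueError):
            h.DoseEvent(0.0, "CRH", -1.0)

    def test_trajectory_invariants(self):
        with pytest.raises(ValueError):
            h.Trajectory(times=[0.0, 1.0, 1.0], states=np.zeros((3, 15)))
        with pytest.raises(ValueError):
            h.Trajectory(times=[0.0, 1.0], states=np.zeros((3, 15)))


class TestIntegrate:
    def test_zero_production_zero_state_stays_zero(self, zero_production_params):
        traj = h.integrate(
            extended_model, zero_production_params, np.zeros(15),
            protocol=h.StressProtocol(baseline=0.0),
            t_grid=np.linspace(0, 60, 61),
        )
        assert np.allclose(traj.states, 0.0, atol=1e-12)

    def test_dose_jump_is_exact(self, default_params):
        """A 10 nM CRH bolus at t=0 appears in full in the t=0 output."""
        traj = h.integrate(
            extended_model, default_params, np.zeros(15),
            doses=[h.DoseEvent(0.0, "CRH", 10.0)],
            t_grid=np.linspace(0, 10, 21),
        )
        assert traj.states[0, 1] == pytest.approx(10.0)

    def test_mid_run_dose_conserves_other_states(self, default_params):
        """Integrating across a dose event leaves all states continuous up
        to the event time (recorded pre-dose) and applies the bolus as a
        jump immediately after."""
        grid = np.linspace(0, 30, 301)
        t_dose = 15.0
        x0 = np.full(15, 0.5)
        with_dose = h.integrate(
            extended_model, default_params, x0,
            doses=[h.DoseEvent(t_dose, "COR_ex", 50.0)], t_grid=grid,
        )
        without = h.integrate(extended_model, default_params, x0, t_grid=grid)
        i = np.searchsorted(grid, t_dose)
        # at the event time every state matches the undosed run
        for j in range(15):
            assert with_dose.states[i, j] == pytest.approx(
                without.states[i, j], rel=1e-6, abs=1e-10
            )
        # one step later the dosed species carries the bolus
        jump = with_dose.states[i + 1, 0] - without.states[i + 1, 0]
        assert jump == pytest.approx(50.0, rel=2e-2)

    def test_tolerance_self_convergence(self, default_params):
        """Halving rtol/atol changes the trajectory by < 1e-5 relative."""
        grid = np.linspace(0, 60, 61)
        x0 = np.full(15, 0.5)
        doses = list(PROTOCOL_DOSES["B"])
        a = h.integrate(extended_model, default_params, x0, doses=doses,
                        t_grid=grid, rtol=1e-8, atol=1e-10)
        b = h.integrate(extended_model, default_params, x0, doses=doses,
                        t_grid=grid, rtol=5e-9, atol=5e-11)
        scale = np.maximum(np.abs(a.states), 1e-6)
        assert np.max(np.abs(a.states - b.states) / scale) < 1e-5

    def test_grid_refinement_consistency(self, default_params):
        """Doubling output resolution does not change shared points."""
        x0 = np.full(15, 0.5)
        coarse = h.integrate(extended_model, default_params, x0,
                             t_grid=np.linspace(0, 30, 31))
        fine = h.integrate(extended_model, default_params, x0,
                           t_grid=np.linspace(0, 30, 61))
        scale = np.maximum(np.abs(coarse.states), 1e-6)
        diff = np.abs(coarse.states - fine.states[::2]) / scale
        assert np.max(diff) < 1e-5

    def test_nonnegativity_under_simulation(self, default_params):
        traj = h.integrate(
            extended_model, default_params, np.full(15, 0.2),
            protocol=h.StressProtocol(baseline=0.5),
            t_grid=np.linspace(0, 500, 101),
        )
        assert np.min(traj.states) > -1e-8

    def test_dose_outside_grid_rejected(self, default_params):
        with pytest.raises(ValueError):
            h.integrate(
                extended_model, default_params, np.zeros(15),
                doses=[h.DoseEvent(100.0, "CRH", 1.0)],
                t_grid=np.linspace(0, 60, 61),
            )

    def test_dose_species_must_be_extracellular(self, default_params):
        with pytest.raises(ValueError):
            h.integrate(
                extended_model, default_params, np.zeros(15),
                doses=[h.DoseEvent(0.0, "GR", 1.0)],
                t_grid=np.linspace(0, 10, 11),
            )


class TestDoseExperiment:
    def test_sample_time_window_enforced(self, default_params):
        with pytest.raises(ValueError):
            h.run_dose_experiment(default_params, "A", [70.0])
        with pytest.raises(ValueError):
            h.run_dose_experiment(default_params, "C", [10.0])

    def test_initial_readout_equals_initial_value(self, default_params):
        acth = h.run_dose_experiment(default_params, "A", [0.0])
        assert acth[0] == pytest.approx(0.0, abs=1e-9)

    def test_invitro_variant_removes_source_terms(self, default_params):
        """Without hypothalamus/adrenals the only CRH and cortisol present
        are the boluses; their production terms are absent."""
        var = invitro_variant(extended_model)
        x = np.full(15, 0.5)
        dx_vitro = var.rhs(0.0, x, default_params, 0.0)
        dx_vivo = extended_model.rhs(0.0, x, default_params, 0.0)
        p = default_params
        assert dx_vivo[1] - dx_vitro[1] == pytest.approx(
            p.ks * p.ksb / (1 + x[0] / p.K3), rel=1e-12
        )
        assert dx_vivo[0] - dx_vitro[0] == pytest.approx(
            p.v1 * x[2] / (p.K1 + x[2]), rel=1e-12
        )


class TestProtocolFile:
    def test_yaml_round_trip(self, tmp_path):
        from hpaxis.simulate import load_protocol

        path = tmp_path / "proto.yaml"
        path.write_text(
            "baseline: 0.1\n"
            "pulses:\n  - {t_start: 10.0, t_end: 20.0, level: 0.8}\n"
            "doses:\n  - {time: 0.0, species: CRH, amount_nM: 10.0}\n"
        )
        proto, doses = load_protocol(path)
        assert proto.baseline == 0.1
        assert proto.stress(15.0) == 0.8
        assert doses == [h.DoseEvent(0.0, "CRH", 10.0)]


class TestStressResponse:
    def test_zero_amplitude_pulse_stays_at_equilibrium(self, default_params):
        proto = h.StressProtocol(baseline=0.1, pulses=((50.0, 100.0, 0.1),))
        traj, post = h.simulate_stress_response(default_params, proto, 300.0)
        drift = np.abs(traj.states[-1] - traj.states[0]) / np.maximum(
            np.abs(traj.states[0]), 1e-9
        )
        assert np.max(drift) < 1e-5

    def test_post_pulse_state_is_equilibrium(self, default_params):
        proto = h.StressProtocol(baseline=0.1, pulses=((50.0, 150.0, 0.9),))
        traj, post = h.simulate_stress_response(default_params, proto, 400.0)
        res = h.rhs_extended(0.0, post, default_params, 0.1)
        assert np.max(np.abs(res)) < 1e-6
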