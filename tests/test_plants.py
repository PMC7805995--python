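"""Surrogate plants: actuator pieces, closed loops, reference fixtures."""

import math
from dataclasses import replace

import numpy as np
import pytest

from ctrleffort.codec import SignalSpec
from ctrleffort.plants import (
    DelayLine,
    MuscleController,
    MuscleParams,
    PlantConfig,
    TorqueController,
    build_periodic_torque_config,
    default_periodic_config,
    default_pointing_config,
    extract_reference_ranges,
    muscle_actuator_step,
    muscle_force,
    passive_elastic_energy,
    pd_torque_controller,
    simulate,
)

P = MuscleParams()


class TestMuscleActuator:
    def test_silent_muscle_produces_only_passive_force(self):
        a, force = muscle_actuator_step(0.0, 0.0, P.l_opt * 1.05, 0.0, P, 0.001)
        assert a == 0.0
        assert force == pytest.approx(muscle_force(0.0, P.l_opt * 1.05, 0.0, P))
        assert force > 0  # stretched beyond slack

    def test_full_activation_at_optimum_gives_maximal_active_force(self):
        _, force = muscle_actuator_step(1.0, 1.0, P.l_opt, 0.0, P, 1e-9)
        passive = muscle_force(0.0, P.l_opt, 0.0, P)
        assert force == pytest.approx(P.F_max + passive, rel=1e-6)

    def test_activation_step_response_has_the_first_order_time_constant(self):
        a = 0.0
        steps = int(round(P.tau_act / 0.001))
        for _ in range(steps):
            a, _ = muscle_actuator_step(a, 1.0, P.l_opt, 0.0, P, 0.001)
        assert a == pytest.approx(1 - math.exp(-1), rel=1e-9)

    def test_force_velocity_shape(self):
        iso = muscle_force(1.0, P.l_opt, 0.0, P)
        shortening = muscle_force(1.0, P.l_opt, -0.5 * P.v_max, P)
        lengthening = muscle_force(1.0, P.l_opt, 0.5 * P.v_max, P)
        assert shortening < iso < lengthening
        assert muscle_force(1.0, P.l_opt, -2 * P.v_max, P) == pytest.approx(
            muscle_force(0.0, P.l_opt, 0.0, P))  # active part vanishes
        assert lengthening <= P.f_ecc * P.F_max + muscle_force(0.0, P.l_opt, 0.0, P)


class TestPDController:
    def test_zero_error_zero_torque(self):
        assert pd_torque_controller(0.3, 0.1, 0.3, 0.1, -50.0, -5.0, 20.0) == 0.0

    def test_proportional_arithmetic(self):
        assert pd_torque_controller(0.5, 0.0, 0.4, 0.0, -50.0, 0.0, 20.0) == \
            pytest.approx(-5.0)

    def test_saturation_is_exact(self):
        assert pd_torque_controller(10.0, 0.0, 0.0, 0.0, -50.0, 0.0, 20.0) == -20.0
        assert pd_torque_controller(-10.0, 0.0, 0.0, 0.0, -50.0, 0.0, 20.0) == 20.0


class TestDelayLine:
    def test_zero_delay_is_identity(self):
        line = DelayLine(0, 7.0)
        assert [line.push_pop(v) for v in (1, 2, 3)] == [1, 2, 3]

    def test_constant_input_unchanged(self):
        line = DelayLine(5, 4.0)
        assert [line.push_pop(4.0) for _ in range(12)] == [4.0] * 12

    def test_unit_step_is_shifted_by_the_delay(self):
        line = DelayLine(3, 0.0)   # 30 ms at 10 ms steps
        out = [line.push_pop(1.0) for _ in range(6)]
        assert out == [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]


class TestClosedLoop:
    def test_pointing_reference_reaches_and_holds_the_goal(self):
        res = simulate(default_pointing_config("muscle"), seed=0)
        gx, gy = res.goal_xy()
        assert math.hypot(gx - res.x_end, gy - res.y_end) < 0.025
        assert abs(res.dq_end) < 0.15
        assert res.completed

    def test_same_config_and_seed_is_bit_identical(self):
        cfg = default_pointing_config("muscle")
        a = simulate(cfg, seed=3)
        b = simulate(cfg, seed=3)
        assert np.array_equal(a.q, b.q)
        assert np.array_equal(a.signals["stim_flex"], b.signals["stim_flex"])
        assert a.t_stop == b.t_stop

    def test_single_level_stimulation_is_the_constant_midpoint(self):
        cfg = default_pointing_config("muscle")
        spec = SignalSpec("stim_flex", 0.0, 1.0, 1.0)
        spec2 = SignalSpec("stim_ext", 0.0, 1.0, 1.0)
        res = simulate(cfg, discretization={"stim_flex": (spec, 1, 1),
                                            "stim_ext": (spec2, 1, 1)},
                       scenario="STIM", seed=0)
        assert np.all(res.applied["stim_flex"] == 0.5)
        assert np.all(res.applied["stim_ext"] == 0.5)

    def test_scenario_plant_compatibility_is_enforced(self):
        with pytest.raises(ValueError, match="requires the muscle plant"):
            simulate(default_pointing_config("torque"), scenario="STIM")

    def test_passive_mechanical_energy_never_increases(self):
        cfg = default_pointing_config("muscle", noise_std=0.0)
        cfg = replace(cfg, muscle_ctrl=MuscleController(u0=0.0, kp=0.0, kv=0.0,
                                                        latency_model=0.0))
        res = simulate(cfg, seed=0)
        p = cfg.muscle
        l_ref0 = p.l_ref_frac * p.l_opt
        l1 = l_ref0 - p.rho * res.q
        l2 = l_ref0 + p.rho * res.q
        E = (0.5 * cfg.arm.inertia * res.dq ** 2
             + np.array([passive_elastic_energy(l, p) for l in l1])
             + np.array([passive_elastic_energy(l, p) for l in l2]))
        assert np.all(np.diff(E) <= 1e-9)

    def test_fine_discretization_converges_to_the_reference(self):
        cfg = default_pointing_config("muscle", noise_std=0.0)
        ref = simulate(cfg, seed=0)
        specs = {
            "stim_flex": (SignalSpec("stim_flex", 0.0, 1.0, 1.0), 1024, 1024),
            "stim_ext": (SignalSpec("stim_ext", 0.0, 1.0, 1.0), 1024, 1024),
        }
        fine = simulate(cfg, discretization=specs, scenario="STIM", seed=0)
        assert np.abs(fine.q - ref.q).max() < 0.02
        assert any("saturates" in w for w in fine.warnings)


class TestPeriodicPlant:
    def test_periodic_reference_oscillates_and_progresses(self):
        res = simulate(default_periodic_config("muscle"), seed=0)
        assert res.x_hat[-1] > 5.0           # walked forward
        assert res.y_hat.min() > 1.24        # never "fell"
        eval_q = res.q[res.times >= 1.0]
        assert eval_q.max() > 0.15 and eval_q.min() < -0.15

    def test_torque_twin_limit_is_1_5x_the_reference_peak(self):
        ref = simulate(default_periodic_config("muscle"), seed=0)
        cfg = build_periodic_torque_config(ref)
        from ctrleffort.plants import muscle_joint_torque
        peak = np.abs(muscle_joint_torque(ref)).max()
        assert cfg.torque_ctrl.limit == pytest.approx(1.5 * peak)

    def test_torque_twin_tracks_the_recorded_kinematics(self):
        ref = simulate(default_periodic_config("muscle"), seed=0)
        cfg = build_periodic_torque_config(ref)
        res = simulate(cfg, seed=0)
        err = np.abs(res.q - np.array(cfg.ref_q)[:res.q.size])
        assert err.max() < 0.15


class TestReferenceRanges:
    def test_ranges_are_exact_extrema_over_the_window(self):
        res = simulate(default_pointing_config("muscle", noise_std=0.0), seed=0)
        (spec,) = extract_reference_ranges(res, ["sens_q"])
        assert spec.u_min == res.signals["sens_q"].min()
        assert spec.u_max == res.signals["sens_q"].max()
        assert spec.role == "controller-input"

    def test_empty_signal_list_gives_empty_specs(self):
        res = simulate(default_pointing_config("muscle"), seed=0)
        assert extract_reference_ranges(res, []) == []

    def test_hdf5_export_round_trips_trajectories(self, tmp_path):
        import h5py
        res = simulate(default_pointing_config("muscle"), seed=0)
        path = tmp_path / "run.h5"
        res.to_hdf5(path)
        with h5py.File(path) as fh:
            assert np.array_equal(fh["q"][...], res.q)
            assert fh.attrs["stop_reason"] == "completed"
            assert np.array_equal(fh["signals/sens_q"][...],
                                  res.signals["sens_q"])

    def test_discretized_run_is_rejected_as_reference(self):
        cfg = default_pointing_config("muscle")
        spec = SignalSpec("stim_flex", 0.0, 1.0, 1.0)
        res = simulate(cfg, discretization={"stim_flex": (spec, 2, 2)},
                       scenario="STIM", seed=0)
        with pytest.raises(ValueError, match="undiscretized"):
            extract_reference_ranges(res, ["sens_q"])
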