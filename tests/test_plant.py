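"""Synthetic plant: demonstrations, kinematics, faults, follow-through data."""

import numpy as np
import pytest

from neural_asm import plant
from neural_asm.data import ChannelNormaliser, SensorimotorSequence, save_trials, load_trials, zscore_normalise


class TestPickPlaceDemos:
    def test_generators_are_pure_functions_of_seed(self):
        a1 = plant.make_pick_place_demos("A", n_reps=3, seed=9)
        a2 = plant.make_pick_place_demos("A", n_reps=3, seed=9)
        for t1, t2 in zip(a1, a2):
            np.testing.assert_array_equal(t1.values, t2.values)

    def test_zero_noise_repetitions_identical(self):
        demos = plant.make_pick_place_demos("A", n_reps=4, noise_scale=0.0, seed=0)
        for d in demos[1:]:
            np.testing.assert_array_equal(d.values, demos[0].values)

    def test_end_effector_consistent_with_forward_kinematics(self):
        nom = plant.pick_place_nominal("B")
        ee = plant.forward_kinematics(nom.values[:, plant.JOINT_IDX])
        np.testing.assert_allclose(nom.values[:, plant.EE_IDX], ee, atol=1e-9)

    def test_skills_are_separated_well_above_noise(self):
        a = plant.pick_place_nominal("A").values
        b = plant.pick_place_nominal("B").values
        sd = plant.channel_noise_sd()
        separation = ((a - b) ** 2).mean()
        assert separation > 10 * (sd**2).mean()

    def test_default_layout_is_25_channels_15_steps(self):
        nom = plant.pick_place_nominal("A")
        assert nom.values.shape == (15, 25)
        assert nom.dt == 0.5
        assert len(nom.role_indices("joint")) == 7
        assert len(nom.role_indices("end_effector")) == 3
        assert len(nom.role_indices("gripper")) == 3
        assert len(nom.role_indices("force_torque")) == 12
        assert len(nom.role_indices("cue")) == 0


class TestJointLock:
    def test_steps_before_fault_untouched(self):
        nom = plant.pick_place_nominal("A")
        for t_fault in (1.0, 3.0, 5.5):
            k = int(round(t_fault / nom.dt))
            faulted = plant.inject_joint_lock(nom, 4, t_fault, 10.0)
            np.testing.assert_array_equal(faulted.values[:k], nom.values[:k])

    def test_locked_joint_holds_offset_value(self):
        nom = plant.pick_place_nominal("A")
        faulted = plant.inject_joint_lock(nom, 5, 3.0, 10.0)
        locked = faulted.values[6:, 4]
        np.testing.assert_allclose(locked, nom.values[6, 4] + 10.0, atol=1e-12)

    def test_zero_overshoot_differs_only_where_nominal_moves(self):
        nom = plant.pick_place_nominal("A")
        faulted = plant.inject_joint_lock(nom, 3, 3.0, 0.0)
        d = faulted.values[:, 2] - nom.values[:, 2]
        assert np.all(d[:7] == 0)  # fault step itself keeps the commanded value
        assert np.any(d[7:] != 0)  # nominal keeps moving, the locked joint not

    def test_severe_joint2_lock_adds_floor_collision_spike(self):
        nom = plant.pick_place_nominal("A")
        faulted = plant.inject_joint_lock(nom, 2, 3.0, 10.0)
        assert faulted.values[:, 9].min() < plant.ArmSpec().floor_height
        ft = np.abs(faulted.values[:, 13:25]) - np.abs(nom.values[:, 13:25])
        assert ft.max() > 5 * plant.GRASP_LOAD_AMPLITUDE

    def test_minor_joint5_lock_stays_above_floor(self):
        faulted = plant.inject_joint_lock(plant.pick_place_nominal("A"), 5, 3.0, 10.0)
        assert faulted.values[:, 9].min() > plant.ArmSpec().floor_height


class TestCollision:
    def test_zero_impulse_is_identity(self):
        nom = plant.pick_place_nominal("A")
        out = plant.inject_collision(nom, 3.0, np.zeros(7))
        np.testing.assert_array_equal(out.values, nom.values)

    def test_impulse_peaks_at_onset_and_decays_monotonically(self):
        nom = plant.pick_place_nominal("A")
        imp = np.zeros(7)
        imp[2] = 8.0
        out = plant.inject_collision(nom, 3.0, imp, decay=0.6)
        dev = np.abs(out.values[:, 2] - nom.values[:, 2])
        assert np.argmax(dev) == 6
        assert np.all(np.diff(dev[6:]) < 0)


class TestFollowThrough:
    def test_execution_only_cue_silent_at_movement_onset(self):
        ds = plant.make_followthrough_dataset("execution_only", n_trials=2, seed=0)
        assert ds.cue_onset == 5
        for t in ds.trials:
            assert np.all(t.values[: ds.cue_onset, plant.FT_CUE_IDX] == 0)
            active = t.values[ds.cue_onset:, plant.FT_CUE_IDX]
            np.testing.assert_array_equal(active.sum(axis=1), 1.0)

    def test_planning_cue_one_hot_from_first_step(self):
        ds = plant.make_followthrough_dataset("planning_only", n_trials=2, seed=0)
        for t in ds.trials:
            cue = t.values[:, plant.FT_CUE_IDX]
            np.testing.assert_array_equal(cue.sum(axis=1), 1.0)

    def test_noiseless_plan_peak_equals_configured_amplitude(self):
        for amp in (0.02, 0.035):
            path = plant.followthrough_plan("cw", "planning_only", amplitude=amp)
            lateral = np.abs(path[:, 0])
            # half-sine peak on a finely sampled path reaches the amplitude
            fine = plant.followthrough_plan("cw", "planning_only", amplitude=amp)
            assert lateral.max() == pytest.approx(amp, abs=amp * 0.15)
            s = np.linspace(0, 1, 2001)
            peak = np.max(amp * np.sin(np.pi * s))
            assert peak == pytest.approx(amp, abs=1e-6)

    def test_contexts_mirror_across_start_target_line(self):
        cw = plant.followthrough_plan("cw", "planning_only")
        ccw = plant.followthrough_plan("ccw", "planning_only")
        mirrored = ccw.copy()
        mirrored[:, 0] *= -1  # S->T is the +y axis
        np.testing.assert_allclose(cw, mirrored, atol=1e-9)

    def test_followthrough_leg_targets_secondary_point(self):
        path = plant.followthrough_plan("cw", "planning_and_execution")
        assert path.shape[0] == plant.FT_MAIN_STEPS + plant.FT_LEG_STEPS
        np.testing.assert_allclose(path[-1], plant._FT_SECONDARY["cw"], atol=1e-12)

    def test_two_link_kinematics_round_trip(self):
        pts = plant.followthrough_plan("ccw", "planning_only")
        joints = plant.two_link_ik(pts)
        np.testing.assert_allclose(plant.two_link_fk(joints), pts, atol=1e-9)


class TestNormalisation:
    def test_constant_channel_maps_to_zero(self):
        trials = [SensorimotorSequence(np.column_stack([np.ones(4), np.arange(4) + i]),
                                       ["c0", "c1"], ["joint", "joint"])
                  for i in range(3)]
        normed, _ = zscore_normalise(trials)
        for t in normed:
            np.testing.assert_allclose(t.values[:, 0], 0.0, atol=1e-9)

    def test_round_trip_identity(self):
        trials = plant.make_pick_place_demos("A", n_reps=3, seed=2)
        normed, norm = zscore_normalise(trials)
        for raw, n in zip(trials, normed):
            np.testing.assert_allclose(norm.inverse(n.values), raw.values, atol=1e-9)

    def test_pooled_moments_are_standardised(self):
        trials = plant.make_pick_place_demos("B", n_reps=4, seed=3)
        normed, _ = zscore_normalise(trials)
        stacked = np.concatenate([t.values for t in normed])
        moving = stacked.std(axis=0) > 1e-8
        np.testing.assert_allclose(stacked.mean(axis=0)[moving], 0.0, atol=1e-9)
        np.testing.assert_allclose(stacked.std(axis=0)[moving], 1.0, atol=1e-9)


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        trial = plant.make_pick_place_demos("A", n_reps=1, seed=5)[0]
        path = tmp_path / "trial.csv"
        trial.to_csv(path)
        back = SensorimotorSequence.from_csv(path)
        np.testing.assert_allclose(back.values, trial.values, rtol=1e-12)
        assert back.channels == trial.channels
        assert back.roles == trial.roles

    def test_npz_trial_set_round_trip(self, tmp_path):
        trials = plant.make_pick_place_demos("B", n_reps=3, seed=6)
        path = tmp_path / "set.npz"
        save_trials(path, trials)
        back = load_trials(path)
        assert len(back) == 3
        for t1, t2 in zip(trials, back):
            np.testing.assert_array_equal(t1.values, t2.values)
            assert t1.skill == t2.skill and t1.trial_id == t2.trial_id
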