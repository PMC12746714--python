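"""Synthetic sensorimotor plant: demonstrations, faults, follow-through data.

This module is a deterministic, seedable stand-in for the robot simulator:
a kinematic 7-joint arm executes scripted pick-and-place waypoint
trajectories, producing 25-channel sensorimotor sequences (7 joint angles,
3 end-effector coordinates, 3 gripper channels, 12 force/torque channels)
of 15 steps at 2 Hz. Faults are injected as joint locks (the joint
overshoots its current goal and holds) or additive collision impulses, with
end-effector channels recomputed through the forward kinematics and a floor
contact translated into a force spike. A second generator builds the
follow-through (context-cued reaching) dataset: mirrored compensatory
end-effector paths for two contexts, 2-link inverse-kinematics joint
angles, and one-hot context cues whose onset defines the cue-availability
condition.

Every generator is a pure function of its parameters and seed. Observation
noise is i.i.d. Gaussian per channel with a standard deviation expressed as
a fraction of that channel's dynamic range across the nominal trajectories
(default 2%).

Angles are degrees at every interface; radians appear only inside the
kinematics. Time steps are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ChannelNormaliser, SensorimotorSequence, zscore_normalise  # noqa: F401

# --------------------------------------------------------------- arm + FK
@dataclass
class ArmSpec:
    """Kinematic chain of the 7-joint arm.

    Rotation axes alternate so that every joint displaces the end effector;
    each link extends along the local x axis after its joint's rotation.
    """

    n_joints: int = 7
    link_lengths: tuple = (0.30, 0.28, 0.24, 0.18, 0.14, 0.10, 0.08)
    axes: tuple = ("z", "y", "z", "y", "z", "y", "y")
    joint_limits_deg: tuple = ((-180.0, 180.0),) * 7
    floor_height: float = -0.27

    def __post_init__(self) -> None:
        if len(self.link_lengths) != self.n_joints or len(self.axes) != self.n_joints:
            raise ValueError("link/axis counts must match n_joints")
        if any(l <= 0 for l in self.link_lengths):
            raise ValueError("link lengths must be positive")
        if any(lo >= hi for lo, hi in self.joint_limits_deg):
            raise ValueError("joint limits must be well-ordered")


def _rot(axis: str, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    if axis == "z":
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    if axis == "y":
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def forward_kinematics(joints_deg: np.ndarray, arm: ArmSpec | None = None) -> np.ndarray:
    """End-effector xyz for joint angles in degrees; accepts (7,) or (T, 7)."""
    arm = arm or ArmSpec()
    q = np.atleast_2d(np.asarray(joints_deg, dtype=float))
    out = np.empty((q.shape[0], 3))
    for t in range(q.shape[0]):
        R = np.eye(3)
        p = np.zeros(3)
        for theta, axis, L in zip(np.deg2rad(q[t]), arm.axes, arm.link_lengths):
            R = R @ _rot(axis, theta)
            p = p + R @ np.array([L, 0.0, 0.0])
        out[t] = p
    return out if np.asarray(joints_deg).ndim == 2 else out[0]


# --------------------------------------------------- pick-and-place scripts
#: Waypoint step indices: start, grasp (t=3 s), lift, transport, place.
_WAYPOINT_STEPS = (0, 6, 9, 12, 14)
N_STEPS = 15
DT = 0.5

# Per-skill joint waypoints (degrees, 7 joints x 5 waypoints). Every joint
# keeps moving in every segment so that a late joint lock is still a real
# deviation from the commanded motion.
_SKILL_WAYPOINTS = {
    "A": np.array(
        [
            [0, 30, 35, 60, 70],
            [-20, 25, 0, 20, 40],
            [10, -15, -25, -40, -55],
            [-30, -60, -45, -70, -90],
            [0, 20, 35, 55, 70],
            [30, 60, 45, 75, 90],
            [0, -25, -40, -20, -45],
        ],
        dtype=float,
    ),
    "B": np.array(
        [
            [0, -35, -30, -65, -80],
            [-15, 30, 5, 25, 45],
            [-5, 20, 30, 45, 60],
            [-25, -55, -40, -65, -85],
            [10, -15, -30, -50, -65],
            [25, 55, 40, 70, 85],
            [5, 30, 45, 25, 50],
        ],
        dtype=float,
    ),
}

_GRASP_STEP = 6
_RELEASE_STEP = 14
#: Load profile coefficients for the 12 force/torque channels (two grippers
#: x Fx, Fy, Fz, Tx, Ty, Tz), applied while the object is held.
_FT_LOAD = np.array([0.6, 0.4, -4.9, 0.12, 0.18, 0.06,
                     -0.5, 0.3, -4.9, -0.10, 0.15, -0.05])
GRASP_LOAD_AMPLITUDE = float(np.abs(_FT_LOAD).max())

CHANNELS = (
    [f"joint{i}" for i in range(1, 8)]
    + ["ee_x", "ee_y", "ee_z"]
    + ["grip_aperture", "finger_left", "finger_right"]
    + [f"ft_{g}_{c}" for g in ("l", "r") for c in ("fx", "fy", "fz", "tx", "ty", "tz")]
)
ROLES = ["joint"] * 7 + ["end_effector"] * 3 + ["gripper"] * 3 + ["force_torque"] * 12
JOINT_IDX = np.arange(7)
EE_IDX = np.arange(7, 10)


def _interp_waypoints(waypoints: np.ndarray) -> np.ndarray:
    steps = np.arange(N_STEPS)
    return np.stack(
        [np.interp(steps, _WAYPOINT_STEPS, waypoints[j]) for j in range(waypoints.shape[0])],
        axis=1,
    )


def _grasp_profile() -> np.ndarray:
    """1 while the object is held (grasp..release), smooth half-step edges."""
    load = np.zeros(N_STEPS)
    load[_GRASP_STEP:_RELEASE_STEP] = 1.0
    load[_GRASP_STEP] = 0.5
    load[_RELEASE_STEP - 1] = 0.5
    return load


def pick_place_nominal(skill: str, arm: ArmSpec | None = None) -> SensorimotorSequence:
    """Noise-free nominal trial of one pick-and-place skill ('A' or 'B')."""
    if skill not in _SKILL_WAYPOINTS:
        raise ValueError(f"unknown skill {skill!r}; expected one of {sorted(_SKILL_WAYPOINTS)}")
    arm = arm or ArmSpec()
    joints = _interp_waypoints(_SKILL_WAYPOINTS[skill])
    ee = forward_kinematics(joints, arm)
    load = _grasp_profile()
    aperture = 1.0 - 0.9 * load
    gripper = np.stack([aperture, aperture / 2, -aperture / 2], axis=1)
    ft = load[:, None] * _FT_LOAD[None, :]
    values = np.concatenate([joints, ee, gripper, ft], axis=1)
    return SensorimotorSequence(values, list(CHANNELS), list(ROLES), dt=DT, skill=skill)


def channel_noise_sd(noise_scale: float = 0.02, arm: ArmSpec | None = None) -> np.ndarray:
    """Per-channel noise sd: ``noise_scale`` x dynamic range over both skills."""
    pooled = np.concatenate(
        [pick_place_nominal(s, arm).values for s in ("A", "B")], axis=0
    )
    rng_span = pooled.max(axis=0) - pooled.min(axis=0)
    return noise_scale * np.maximum(rng_span, 1e-3)


def add_observation_noise(
    trial: SensorimotorSequence,
    sd: np.ndarray | float,
    seed: int,
) -> SensorimotorSequence:
    """Add i.i.d. Gaussian observation noise (per-channel sd) to a trial."""
    rng = np.random.default_rng(seed)
    noisy = trial.values + rng.normal(size=trial.values.shape) * np.asarray(sd)
    return trial.with_values(noisy)


def make_pick_place_demos(
    skill: str,
    n_reps: int = 10,
    noise_scale: float = 0.02,
    seed: int = 0,
    arm: ArmSpec | None = None,
) -> list[SensorimotorSequence]:
    """Noisy demonstration set of one skill (default 10 repetitions)."""
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    nominal = pick_place_nominal(skill, arm)
    sd = channel_noise_sd(noise_scale, arm) if noise_scale > 0 else 0.0
    rng = np.random.default_rng(seed)
    demos = []
    for rep in range(n_reps):
        values = nominal.values + (
            rng.normal(size=nominal.values.shape) * sd if noise_scale > 0 else 0.0
        )
        demos.append(
            SensorimotorSequence(values, list(CHANNELS), list(ROLES),
                                 dt=DT, skill=skill, trial_id=rep)
        )
    return demos


# ------------------------------------------------------------ fault models
def inject_joint_lock(
    trial: SensorimotorSequence,
    joint: int,
    t_fault: float,
    overshoot_deg: float,
    arm: ArmSpec | None = None,
) -> SensorimotorSequence:
    """Lock ``joint`` (1-based) from ``t_fault`` seconds onward.

    From the fault step on, the joint holds its current commanded angle plus
    ``overshoot_deg`` while the remaining joints continue the nominal
    motion. End-effector channels are recomputed through the forward
    kinematics; if the end effector crosses the floor, a collision force
    spike (10x the grasp load amplitude, halving each step) is added to the
    force/torque channels. Steps before the fault are untouched.
    """
    arm = arm or ArmSpec()
    if not (1 <= joint <= arm.n_joints):
        raise ValueError(f"joint must be in 1..{arm.n_joints}")
    k = int(round(t_fault / trial.dt))
    if not (0 <= k < trial.n_steps):
        raise ValueError("t_fault outside the trial")
    values = trial.values.copy()
    j = joint - 1
    values[k:, j] = values[k, j] + overshoot_deg
    values[k:, EE_IDX] = forward_kinematics(values[k:, JOINT_IDX], arm)
    below = np.where(values[k:, 9] < arm.floor_height)[0]
    if below.size:
        hit = k + int(below[0])
        spike = 10.0 * GRASP_LOAD_AMPLITUDE
        decay = spike * 0.5 ** np.arange(trial.n_steps - hit)
        ft_cols = np.arange(13, 25)
        values[hit:, ft_cols] += np.sign(_FT_LOAD + 1e-12)[None, :] * decay[:, None]
    return trial.with_values(values)


def inject_collision(
    trial: SensorimotorSequence,
    t: float,
    impulse_deg: np.ndarray,
    decay: float = 0.6,
    arm: ArmSpec | None = None,
) -> SensorimotorSequence:
    """Additive transient on the joint channels, geometric decay after ``t``."""
    arm = arm or ArmSpec()
    k = int(round(t / trial.dt))
    if not (0 <= k < trial.n_steps):
        raise ValueError("t outside the trial")
    impulse = np.asarray(impulse_deg, dtype=float)
    if impulse.shape != (arm.n_joints,):
        raise ValueError("impulse must have one entry per joint")
    values = trial.values.copy()
    steps = np.arange(trial.n_steps - k)
    values[k:, JOINT_IDX] += decay ** steps[:, None] * impulse[None, :]
    values[k:, EE_IDX] = forward_kinematics(values[k:, JOINT_IDX], arm)
    return trial.with_values(values)


# ------------------------------------------------- follow-through generator
CONDITIONS = ("planning_only", "planning_and_execution", "execution_only")
CONTEXTS = ("cw", "ccw")
#: Sign mapping of the correct compensation direction onto the +90-degree
#: normal of the start->target line: a clockwise field demands leftward
#: compensation, which is the +normal for our S->T geometry.
CONTEXT_SIGNS = {"cw": +1.0, "ccw": -1.0}

FT_CHANNELS = ["ee_x", "ee_y", "shoulder", "elbow", "cue_cw", "cue_ccw"]
FT_ROLES = ["end_effector", "end_effector", "joint", "joint", "cue", "cue"]
FT_EE_IDX = np.array([0, 1])
FT_JOINT_IDX = np.array([2, 3])
FT_CUE_IDX = np.array([4, 5])

_FT_S = np.array([0.0, 0.0])
_FT_T = np.array([0.0, 0.12])
_FT_SECONDARY = {
    "cw": np.array([0.055, 0.175]),
    "ccw": np.array([-0.055, 0.175]),
}
_FT_BASE = np.array([0.0, -0.25])
_FT_LINKS = (0.25, 0.25)
FT_MAIN_STEPS = 10
FT_LEG_STEPS = 5


def two_link_ik(points: np.ndarray) -> np.ndarray:
    """Elbow-up inverse kinematics of the planar 2-link arm (degrees)."""
    p = np.atleast_2d(points) - _FT_BASE
    l1, l2 = _FT_LINKS
    d2 = (p**2).sum(axis=1)
    cos_e = np.clip((d2 - l1**2 - l2**2) / (2 * l1 * l2), -1.0, 1.0)
    elbow = -np.arccos(cos_e)  # elbow-up branch
    shoulder = np.arctan2(p[:, 1], p[:, 0]) - np.arctan2(
        l2 * np.sin(elbow), l1 + l2 * np.cos(elbow)
    )
    return np.degrees(np.stack([shoulder, elbow], axis=1))


def two_link_fk(joints_deg: np.ndarray) -> np.ndarray:
    """Planar 2-link forward kinematics (inverse of :func:`two_link_ik`)."""
    q = np.deg2rad(np.atleast_2d(joints_deg))
    l1, l2 = _FT_LINKS
    x = l1 * np.cos(q[:, 0]) + l2 * np.cos(q[:, 0] + q[:, 1])
    y = l1 * np.sin(q[:, 0]) + l2 * np.sin(q[:, 0] + q[:, 1])
    return np.stack([x, y], axis=1) + _FT_BASE


def followthrough_plan(context: str, condition: str, amplitude: float = 0.02) -> np.ndarray:
    """Noise-free end-effector plan for one context.

    Straight S->T path plus a half-sine lateral bow of ``amplitude``, signed
    by the context's compensation direction; planning_and_execution appends
    the follow-through leg to the context's secondary target.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    u = _FT_T - _FT_S
    n_hat = np.array([-u[1], u[0]]) / np.linalg.norm(u)
    s = np.linspace(0.0, 1.0, FT_MAIN_STEPS)
    path = _FT_S + s[:, None] * u[None, :]
    path = path + CONTEXT_SIGNS[context] * amplitude * np.sin(np.pi * s)[:, None] * n_hat
    if condition == "planning_and_execution":
        leg_s = np.linspace(0.0, 1.0, FT_LEG_STEPS + 1)[1:]
        leg = _FT_T + leg_s[:, None] * (_FT_SECONDARY[context] - _FT_T)[None, :]
        path = np.concatenate([path, leg])
    return path


@dataclass
class FollowThroughDataset:
    """Context-labelled demonstration set for one cue-availability condition.

    Holds the noisy trials (both contexts), the noise-free motor plans used
    as ground truth for the deviation metric, the geometry anchors, and the
    cue onset step. Sensory channels are the end-effector coordinates plus
    the one-hot cue; motor channels are the two joint angles.
    """

    condition: str
    trials: list[SensorimotorSequence]
    plans: dict[str, np.ndarray]
    S: np.ndarray = field(default_factory=lambda: _FT_S.copy())
    T_pt: np.ndarray = field(default_factory=lambda: _FT_T.copy())
    secondary: dict[str, np.ndarray] = field(default_factory=lambda: {k: v.copy() for k, v in _FT_SECONDARY.items()})
    amplitude: float = 0.02
    cue_onset: int = 0
    context_signs: dict[str, float] = field(default_factory=lambda: dict(CONTEXT_SIGNS))

    @property
    def sensory_idx(self) -> np.ndarray:
        return np.concatenate([FT_EE_IDX, FT_CUE_IDX])

    @property
    def motor_idx(self) -> np.ndarray:
        return FT_JOINT_IDX


def make_followthrough_dataset(
    condition: str,
    n_trials: int = 12,
    noise_scale: float = 0.02,
    amplitude: float = 0.02,
    seed: int = 0,
) -> FollowThroughDataset:
    """Build the follow-through dataset for one cue condition.

    ``n_trials`` noisy repetitions per context. The one-hot context cue is
    active from step 0 in the two planning conditions and from mid-movement
    (step ceil(T/2)) in ``execution_only``; before onset the cue channels
    are zero. Noise sd is ``noise_scale`` x each channel's dynamic range
    over the noise-free plans (cue channels stay noise-free).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    n_steps = FT_MAIN_STEPS + (FT_LEG_STEPS if condition == "planning_and_execution" else 0)
    cue_onset = 0 if condition.startswith("planning") else int(np.ceil(FT_MAIN_STEPS / 2))
    plans = {c: followthrough_plan(c, condition, amplitude) for c in CONTEXTS}
    nominal = {}
    for c in CONTEXTS:
        joints = two_link_ik(plans[c])
        cue = np.zeros((n_steps, 2))
        cue[cue_onset:, 0 if c == "cw" else 1] = 1.0
        nominal[c] = np.concatenate([plans[c], joints, cue], axis=1)
    pooled = np.concatenate(list(nominal.values()))
    span = pooled.max(axis=0) - pooled.min(axis=0)
    sd = noise_scale * np.maximum(span, 1e-3)
    sd[FT_CUE_IDX] = 0.0
    rng = np.random.default_rng(seed)
    trials = []
    for rep in range(n_trials):
        for c in CONTEXTS:
            values = nominal[c] + rng.normal(size=nominal[c].shape) * sd
            trials.append(
                SensorimotorSequence(values, list(FT_CHANNELS), list(FT_ROLES),
                                     dt=DT, skill=c, trial_id=rep)
            )
    return FollowThroughDataset(condition=condition, trials=trials, plans=plans,
                                amplitude=amplitude, cue_onset=cue_onset)
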