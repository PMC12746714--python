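"""Fault detection, isolation, the Z-score baseline, and reactive correction.

Detection thresholds the tPC monitoring energy against a nearest-rank
percentile of its distribution during normal (fault-free) operation: with
the 95th percentile, at most 5% of normal per-step energies exceed the
threshold, so the percentile directly controls the false-positive rate.
Isolation names the joint channel with the largest absolute observation
prediction error at the detection step.

The traditional associative-skill-memory baseline stores per-skill signal
statistics — mean and standard deviation per (time step, channel) across
demonstrations — and monitors the sum of squared Z-scored errors. Unlike
the energy monitor it must be told which skill is being executed.

Reactive correction closes the loop: a proportional low-level controller
(40 Hz) tracks the Neural ASM's predicted joint trajectory (2 Hz, linearly
interpolated), pulling the arm back after impulse disturbances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tpc
from .data import ChannelNormaliser, SensorimotorSequence
from .plant import (
    ArmSpec,
    add_observation_noise,
    channel_noise_sd,
    inject_joint_lock,
    pick_place_nominal,
)


# ---------------------------------------------------------------- threshold
@dataclass
class EnergyThreshold:
    """Nearest-rank percentile threshold fitted on normal-operation values."""

    percentile: float
    threshold: float
    n_fit: int

    def to_json(self) -> dict:
        return {"percentile": self.percentile, "threshold": self.threshold, "n_fit": self.n_fit}


def fit_threshold(normal_values: np.ndarray, percentile: float = 95.0) -> EnergyThreshold:
    """Fit the nearest-rank percentile of pooled normal-operation values.

    The threshold is the ceil(p/100 * n)-th order statistic, so the fraction
    of fitted values strictly above it is at most (100 - p)% — exactly that
    when n * (100 - p) / 100 is an integer and the values are distinct.
    """
    values = np.asarray(normal_values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot fit a threshold on no values")
    if values.size < 20:
        raise ValueError("need at least 20 normal-operation values")
    if not np.all(np.isfinite(values)):
        raise ValueError("normal-operation values must be finite")
    if not (0.0 < percentile <= 100.0):
        raise ValueError("percentile must be in (0, 100]")
    k = math.ceil(percentile / 100.0 * values.size)
    threshold = float(np.sort(values)[k - 1])
    return EnergyThreshold(percentile=percentile, threshold=threshold, n_fit=values.size)


def detect(
    energies: np.ndarray, threshold: EnergyThreshold, start_step: int = 0
) -> tuple[bool, int | None]:
    """First step (>= start_step) whose energy exceeds the threshold."""
    energies = np.asarray(energies, dtype=float)
    if not np.all(np.isfinite(energies)):
        raise ValueError("energies must be finite")
    above = np.where(energies[start_step:] > threshold.threshold)[0]
    if above.size == 0:
        return False, None
    return True, int(start_step + above[0])


def isolate(
    channel_errors: np.ndarray,
    joint_indices: np.ndarray,
    channel_names: list[str],
) -> str:
    """Joint channel with the largest |error| (ties -> lowest joint index)."""
    errors = np.asarray(channel_errors, dtype=float)
    joint_indices = np.asarray(joint_indices, dtype=int)
    best = joint_indices[int(np.argmax(errors[joint_indices]))]
    return channel_names[best]


@dataclass
class FaultReport:
    """Outcome of monitoring one trial against a fitted threshold."""

    energies: np.ndarray
    threshold: EnergyThreshold
    detected: bool
    detection_step: int | None = None
    channel_errors: np.ndarray | None = field(default=None, repr=False)
    isolated_channel: str | None = None
    isolated_joint: int | None = None

    def __post_init__(self) -> None:
        if self.detected and self.detection_step is None:
            raise ValueError("a detected fault needs a detection step")
        if not self.detected and (self.detection_step is not None or self.isolated_channel):
            raise ValueError("an undetected fault carries no detection step or channel")


def monitor_trial(
    net: tpc.TPCNetwork,
    observed: SensorimotorSequence | np.ndarray,
    threshold: EnergyThreshold,
    start_step: int = 0,
) -> FaultReport:
    """Online-recall monitoring of one (normalised) trial -> FaultReport."""
    res = tpc.online_recall(net, observed)
    return _report_from_traces(res.energies, res.channel_errors, threshold, start_step)


def _report_from_traces(
    energies: np.ndarray,
    channel_errors: np.ndarray,
    threshold: EnergyThreshold,
    start_step: int,
    joint_indices: np.ndarray | None = None,
    channel_names: list[str] | None = None,
) -> FaultReport:
    from .plant import CHANNELS, JOINT_IDX

    joint_indices = JOINT_IDX if joint_indices is None else joint_indices
    channel_names = list(CHANNELS) if channel_names is None else channel_names
    found, step = detect(energies, threshold, start_step)
    if not found:
        return FaultReport(energies=energies, threshold=threshold, detected=False,
                           channel_errors=channel_errors)
    # isolated_channel: argmax over every channel; isolated_joint: restricted
    # to the joint channels (ties -> lowest index in both cases).
    top = channel_names[int(np.argmax(channel_errors[step]))]
    name = isolate(channel_errors[step], joint_indices, channel_names)
    joint = int(name.replace("joint", "")) if name.startswith("joint") else None
    return FaultReport(energies=energies, threshold=threshold, detected=True,
                       detection_step=step, channel_errors=channel_errors,
                       isolated_channel=top, isolated_joint=joint)


# ----------------------------------------------------------- Z-score baseline
@dataclass
class ChannelStats:
    """Per (skill, channel) mean/sd pooled over demonstrations and time.

    The traditional detector stores the expected signal per movement
    phase: mean and sd per (time step, channel) across the demonstrations
    of each skill, so its Z-scores measure deviation from the phase-aligned
    expectation. Its isolation, per its own definition, names the channel
    (any channel, not only joints) with the maximum |z|.
    """

    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    floor: float = 1e-6

    @classmethod
    def fit(cls, demos_by_skill: dict[str, list[SensorimotorSequence]], floor: float = 1e-6) -> "ChannelStats":
        mean, sd = {}, {}
        for skill, demos in demos_by_skill.items():
            if len(demos) < 2:
                raise ValueError(f"skill {skill!r} needs >= 2 demonstrations")
            stacked = np.stack([d.values for d in demos])
            mean[skill] = stacked.mean(axis=0)
            sd[skill] = np.maximum(stacked.std(axis=0), floor)
        return cls(mean=mean, sd=sd, floor=floor)


def zscore_baseline(
    observed: SensorimotorSequence | np.ndarray,
    stats: ChannelStats,
    skill: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step sum of squared Z-scored errors + per-channel |z|.

    The baseline is given the true skill label: its stored statistics are
    aligned to the movement phase of that specific skill.
    """
    if skill not in stats.mean:
        raise ValueError(f"no stored statistics for skill {skill!r}")
    values = np.asarray(getattr(observed, "values", observed), dtype=float)
    z = (values - stats.mean[skill]) / stats.sd[skill]
    return (z**2).sum(axis=1), np.abs(z)


# -------------------------------------------------------- reactive correction
def reactive_correct(
    predicted_joints_deg: np.ndarray,
    gain: float = 0.5,
    rate_ratio: int = 20,
    disturbance: tuple[int, int, float] | None = None,
    initial_joints_deg: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Track the predicted joint trajectory with a proportional controller.

    The 2 Hz prediction is linearly interpolated to the low-level rate
    (``rate_ratio`` x faster, default 40 Hz) and the controller moves each
    joint a fraction ``gain`` of its remaining error per low-level step. An
    optional impulse disturbance ``(low_level_step, joint_index, degrees)``
    is added to the plant state; the returned trace shows the tracking
    error decaying back at rate (1 - gain) per step.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    target_2hz = np.atleast_2d(np.asarray(predicted_joints_deg, dtype=float))
    t_coarse = np.arange(target_2hz.shape[0])
    t_fine = np.linspace(0.0, t_coarse[-1], (target_2hz.shape[0] - 1) * rate_ratio + 1)
    target = np.stack(
        [np.interp(t_fine, t_coarse, target_2hz[:, j]) for j in range(target_2hz.shape[1])],
        axis=1,
    )
    theta = target[0].copy() if initial_joints_deg is None else np.asarray(initial_joints_deg, dtype=float).copy()
    trace = np.empty_like(target)
    for k in range(target.shape[0]):
        if disturbance is not None and k == disturbance[0]:
            theta[disturbance[1]] += disturbance[2]
        theta = theta + gain * (target[k] - theta)
        trace[k] = theta
    return {"target": target, "theta": trace, "error": trace - target}


# ------------------------------------------------------------ fault grid
DEFAULT_FAULT_TIMES = tuple(np.arange(1.0, 6.01, 0.5))
DEFAULT_OVERSHOOTS = (-15.0, -10.0, -5.0, 5.0, 10.0, 15.0)


def evaluate_fault_grid(
    net: tpc.TPCNetwork,
    normaliser: ChannelNormaliser,
    stats: ChannelStats,
    energy_threshold: EnergyThreshold,
    baseline_threshold: EnergyThreshold,
    joints: tuple = tuple(range(1, 8)),
    fault_times: tuple = DEFAULT_FAULT_TIMES,
    overshoots: tuple = DEFAULT_OVERSHOOTS,
    noise_scale: float = 0.02,
    seed: int = 0,
    arm: ArmSpec | None = None,
) -> pd.DataFrame:
    """Score both monitors on the factorial joint-lock fault grid.

    Default grid: 7 joints x 11 fault times (1.0-6.0 s in 0.5 s steps) x
    overshoots +/-5, +/-10, +/-15 degrees = 462 trials (zero overshoot is
    excluded — a lock with no overshoot at the goal is not a detectable
    fault under this plant). Each cell injects the lock into a nominal
    trial (skills alternate across cells), adds fresh observation noise,
    and runs both monitors from the fault step onward. Returns a tidy
    table with one row per (cell, method).
    """
    arm = arm or ArmSpec()
    if 0.0 in overshoots:
        raise ValueError("zero overshoot is not a detectable fault; exclude it")
    from .plant import CHANNELS, JOINT_IDX

    nominal = {s: pick_place_nominal(s, arm) for s in ("A", "B")}
    sd = channel_noise_sd(noise_scale, arm)
    rows = []
    idx = 0
    for joint in joints:
        for t_fault in fault_times:
            for overshoot in overshoots:
                skill = "A" if idx % 2 == 0 else "B"
                faulted = inject_joint_lock(nominal[skill], joint, t_fault, overshoot, arm)
                noisy = add_observation_noise(faulted, sd, seed=seed + idx)
                k = max(int(round(t_fault / noisy.dt)), 1)
                # Neural ASM: energy monitoring in normalised space
                res = tpc.online_recall(net, normaliser.transform(noisy.values))
                rep = _report_from_traces(res.energies, res.channel_errors,
                                          energy_threshold, k)
                # Z-score baseline: skill label given
                stat, absz = zscore_baseline(noisy, stats, skill)
                rep_b = _report_from_traces(stat, absz, baseline_threshold, k)
                # Isolation scoring follows each method's own definition:
                # the energy monitor names the *joint* with the largest
                # forward prediction error, the baseline names the *channel*
                # (any channel) with the largest |z|.
                correct = {
                    "neural_asm": bool(rep.detected and rep.isolated_joint == joint),
                    "zscore_baseline": bool(
                        rep_b.detected and rep_b.isolated_channel == f"joint{joint}"
                    ),
                }
                for method, r in (("neural_asm", rep), ("zscore_baseline", rep_b)):
                    rows.append(
                        {
                            "method": method,
                            "skill": skill,
                            "joint": joint,
                            "fault_time_s": t_fault,
                            "overshoot_deg": overshoot,
                            "detected": r.detected,
                            "detection_step": r.detection_step,
                            "isolated_channel": r.isolated_channel,
                            "isolated_joint": r.isolated_joint,
                            "correct_isolation": correct[method],
                        }
                    )
                idx += 1
    return pd.DataFrame(rows)


def summarise_fault_grid(table: pd.DataFrame) -> pd.DataFrame:
    """Detection rate and isolation accuracy (over all trials) per method."""
    out = (
        table.groupby("method")
        .agg(
            n_trials=("detected", "size"),
            detection_rate=("detected", "mean"),
            isolation_accuracy=("correct_isolation", "mean"),
        )
        .reset_index()
    )
    return out
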