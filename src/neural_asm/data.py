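"""Sensorimotor sequence containers, channel normalisation and on-disk formats.

A trial is a ``SensorimotorSequence``: a ``T x C`` matrix of observations
sampled at a fixed rate, with one named, role-tagged channel per column.
Roles identify what a channel measures (joint angle, end-effector coordinate,
gripper state, force/torque component, or a context cue) and drive channel
selection everywhere else in the package — fault isolation looks only at
joint channels, the follow-through metrics only at end-effector channels.

Trials round-trip through plain CSV (one file per trial, ``name:role``
header) and trial sets through a packed ``.npz`` container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: Recognised channel roles.
ROLES = ("joint", "end_effector", "gripper", "force_torque", "cue")


@dataclass
class SensorimotorSequence:
    """One demonstration trial: a time x channel observation matrix.

    Parameters
    ----------
    values : ndarray, shape (T, C)
        Observations, one row per time step.
    channels : list of str
        Channel names, length C.
    roles : list of str
        One role per channel, each drawn from :data:`ROLES`.
    dt : float
        Sampling interval in seconds (default 0.5 s, i.e. 2 Hz).
    skill : str or None
        Label of the demonstrated skill / context, if any.
    trial_id : int
        Repetition index within its dataset.
    """

    values: np.ndarray
    channels: list[str]
    roles: list[str]
    dt: float = 0.5
    skill: str | None = None
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d (time x channel) array")
        if len(self.channels) != self.values.shape[1]:
            raise ValueError("channel names do not match the number of columns")
        if len(self.roles) != len(self.channels):
            raise ValueError("one role is required per channel")
        for r in self.roles:
            if r not in ROLES:
                raise ValueError(f"unknown channel role {r!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sequence contains non-finite values")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time stamps in seconds (step 0 at t=0)."""
        return np.arange(self.n_steps) * self.dt

    def role_indices(self, role: str) -> np.ndarray:
        """Column indices of all channels carrying ``role``."""
        if role not in ROLES:
            raise ValueError(f"unknown channel role {role!r}")
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)

    def with_values(self, values: np.ndarray) -> "SensorimotorSequence":
        """Copy of this trial with ``values`` replaced."""
        return replace(self, values=np.array(values, dtype=float))

    # ------------------------------------------------------------------ CSV
    def to_csv(self, path: str | Path) -> None:
        """Write the trial as CSV with a ``name:role`` header row."""
        header = ",".join(f"{n}:{r}" for n, r in zip(self.channels, self.roles))
        np.savetxt(path, self.values, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        dt: float = 0.5,
        skill: str | None = None,
        trial_id: int = 0,
    ) -> "SensorimotorSequence":
        with open(path) as fh:
            header = fh.readline().strip().split(",")
        names, roles = zip(*(h.split(":") for h in header))
        values = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(values, list(names), list(roles), dt=dt, skill=skill, trial_id=trial_id)


# ---------------------------------------------------------------- trial sets
def save_trials(path: str | Path, trials: list[SensorimotorSequence]) -> None:
    """Pack a list of trials (shared channel layout) into one ``.npz``."""
    if not trials:
        raise ValueError("no trials to save")
    first = trials[0]
    meta = {
        "channels": first.channels,
        "roles": first.roles,
        "dt": first.dt,
        "skills": [t.skill for t in trials],
        "trial_ids": [t.trial_id for t in trials],
    }
    np.savez(
        path,
        values=np.stack([t.values for t in trials]),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_trials(path: str | Path) -> list[SensorimotorSequence]:
    with np.load(path) as npz:
        meta = json.loads(npz["meta"].tobytes().decode())
        values = npz["values"]
    return [
        SensorimotorSequence(
            v,
            meta["channels"],
            meta["roles"],
            dt=meta["dt"],
            skill=meta["skills"][i],
            trial_id=meta["trial_ids"][i],
        )
        for i, v in enumerate(values)
    ]


# ------------------------------------------------------------- normalisation
@dataclass
class ChannelNormaliser:
    """Per-channel Z-score normaliser pooled over trials and time steps.

    Channels with a pooled standard deviation below ``floor`` are treated as
    constant: the floor replaces the deviation, so a constant channel maps to
    zeros and the inverse transform restores the stored mean.
    """

    mean: np.ndarray
    sd: np.ndarray
    floor: float = 1e-6

    @classmethod
    def fit(cls, trials: list[SensorimotorSequence] | list[np.ndarray], floor: float = 1e-6) -> "ChannelNormaliser":
        if len(trials) < 2:
            raise ValueError("need at least 2 trials to pool channel statistics")
        stacked = np.concatenate([np.asarray(getattr(t, "values", t), dtype=float) for t in trials])
        mean = stacked.mean(axis=0)
        sd = np.maximum(stacked.std(axis=0), floor)
        return cls(mean=mean, sd=sd, floor=floor)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.sd + self.mean

    def transform_trial(self, trial: SensorimotorSequence) -> SensorimotorSequence:
        return trial.with_values(self.transform(trial.values))


def zscore_normalise(
    trials: list[SensorimotorSequence], floor: float = 1e-6
) -> tuple[list[SensorimotorSequence], ChannelNormaliser]:
    """Z-score a trial set per channel; returns normalised trials + the fit."""
    norm = ChannelNormaliser.fit(trials, floor=floor)
    return [norm.transform_trial(t) for t in trials], norm
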