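"""Two-layer temporal predictive coding (tPC) network.

The network is the generative model behind a Neural Associative Skill
Memory. Its graphical structure is that of a hidden Markov model: a hidden
layer ``z`` predicts its own next state through the recurrent weights
``W_H``, and predicts the current sensorimotor observation ``x`` through the
top-down weights ``W_F``. At step ``mu`` the network carries two prediction
errors,

    eps_z = z - W_H f(z_prev)        (hidden temporal prediction error)
    eps_x = x - W_F f(z)             (observation prediction error)

and the per-step energy is the sum of their squared norms,

    F_mu = ||eps_z||^2 + ||eps_x||^2.

Both learning and recall are gradient flows on F_mu. *Memorisation*
alternates iterative inference of z (explicit-Euler descent of F_mu in z)
with one local, Hebbian-style update of each weight matrix per time step —
every update uses only the converged state of the current step and the
settled hidden state of the previous step. *Recall* freezes the weights:
offline recall settles z on a short cue window and then rolls the model
forward ballistically; online recall settles z on each observed step and
emits a one-step-ahead prediction, with the converged energy serving as the
monitoring signal for fault detection.

All sequences passed to this module are expected to be Z-score normalised
(see :mod:`neural_asm.data`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import ACT_LINEAR, ACT_TANH, settle_hidden, settle_hidden_np
from .data import SensorimotorSequence

_ACT_CODES = {"linear": ACT_LINEAR, "tanh": ACT_TANH}


class DivergenceError(RuntimeError):
    """Raised when iterative inference produces non-finite values."""


@dataclass
class TPCConfig:
    """Hyperparameters of the tPC network.

    Defaults follow the reference training recipe: 256 hidden units, weight
    learning rate 1e-4 with 1000 full-sequence presentations per skill at
    batch size 1, and value-neuron dynamics integrated for 100 iterations
    per step with step size 1e-2.
    """

    n_obs: int
    n_hidden: int = 256
    activation: str = "tanh"
    inference_lr: float = 1e-2
    inference_iters: int = 100
    weight_lr: float = 1e-4
    epochs_per_skill: int = 1000
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_obs < 1 or self.n_hidden < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.inference_iters < 1 or self.batch_size < 1 or self.epochs_per_skill < 0:
            raise ValueError("counts must be positive")
        if self.inference_lr <= 0 or self.weight_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.activation not in _ACT_CODES:
            raise ValueError(f"activation must be one of {sorted(_ACT_CODES)}")

    @property
    def act_code(self) -> int:
        return _ACT_CODES[self.activation]


def _f(z: np.ndarray, act: int) -> np.ndarray:
    return np.tanh(z) if act == ACT_TANH else z


@dataclass
class TPCNetwork:
    """Weight matrices of the two-layer tPC model.

    ``W_H`` (n_hidden x n_hidden) carries the temporal prediction in the
    hidden layer; ``W_F`` (n_obs x n_hidden) carries the top-down prediction
    of the observations. This single pair of matrices is the repository of
    every memorised skill.
    """

    W_H: np.ndarray
    W_F: np.ndarray
    config: TPCConfig

    def __post_init__(self) -> None:
        self.W_H = np.ascontiguousarray(self.W_H, dtype=float)
        self.W_F = np.ascontiguousarray(self.W_F, dtype=float)
        h, c = self.config.n_hidden, self.config.n_obs
        if self.W_H.shape != (h, h) or self.W_F.shape != (c, h):
            raise ValueError("weight shapes inconsistent with config")
        if not (np.all(np.isfinite(self.W_H)) and np.all(np.isfinite(self.W_F))):
            raise ValueError("weights must be finite")

    @classmethod
    def init(cls, config: TPCConfig) -> "TPCNetwork":
        """Kaiming-uniform initialisation, U(-sqrt(6/fan_in), +sqrt(6/fan_in))."""
        rng = np.random.default_rng(config.seed)
        bound = np.sqrt(6.0 / config.n_hidden)
        W_H = rng.uniform(-bound, bound, size=(config.n_hidden, config.n_hidden))
        W_F = rng.uniform(-bound, bound, size=(config.n_obs, config.n_hidden))
        return cls(W_H=W_H, W_F=W_F, config=config)

    def copy(self) -> "TPCNetwork":
        return TPCNetwork(self.W_H.copy(), self.W_F.copy(), self.config)

    # -------------------------------------------------------- serialisation
    def save(self, path, channels: list[str] | None = None) -> None:
        """Write weights + config (+ optional channel names) to one ``.npz``."""
        import json

        cfg = json.dumps({**self.config.__dict__, "channels": channels})
        np.savez(path, W_H=self.W_H, W_F=self.W_F,
                 meta=np.frombuffer(cfg.encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> tuple["TPCNetwork", list[str] | None]:
        import json

        with np.load(path) as npz:
            meta = json.loads(npz["meta"].tobytes().decode())
            channels = meta.pop("channels")
            net = cls(npz["W_H"].copy(), npz["W_F"].copy(), TPCConfig(**meta))
        return net, channels


@dataclass
class StepState:
    """Converged value-neuron state of one time step.

    Stores the hidden state ``z``, the settled hidden state of the previous
    step ``z_prev``, the clamped (or retrieved) observation ``x``, the two
    prediction errors and the energy, all mutually consistent.
    """

    z: np.ndarray
    z_prev: np.ndarray
    x: np.ndarray
    eps_z: np.ndarray
    eps_x: np.ndarray
    energy: float

    @classmethod
    def compute(cls, z: np.ndarray, z_prev: np.ndarray, x: np.ndarray, net: TPCNetwork) -> "StepState":
        act = net.config.act_code
        eps_z = z - net.W_H @ _f(z_prev, act)
        eps_x = x - net.W_F @ _f(z, act)
        return cls(z=z, z_prev=z_prev, x=x, eps_z=eps_z, eps_x=eps_x,
                   energy=float(eps_z @ eps_z + eps_x @ eps_x))


@dataclass
class RecallResult:
    """Outcome of offline (cued) recall.

    ``predicted`` holds the retrieved observations for all ``T`` steps,
    including the cue window; ``energies`` the converged per-step energies
    (zero on the ballistic steps, where the forward pass is exact).
    """

    predicted: np.ndarray
    energies: np.ndarray
    cue_length: int
    inference_iters_used: int

    def __post_init__(self) -> None:
        if not (0 <= self.cue_length < self.predicted.shape[0]):
            raise ValueError("cue_length must satisfy 0 <= T_n < T")
        if not np.all(np.isfinite(self.energies)) or np.any(self.energies < -1e-12):
            raise ValueError("energies must be finite and non-negative")


@dataclass
class OnlineRecallResult:
    """Outcome of online (step-by-step) recall.

    ``predicted`` has one row per step after the first: the model's
    one-step-ahead prediction. ``energies`` (length T) are the converged
    per-step energies — the monitoring signal used for fault detection.
    ``channel_errors`` holds the per-step absolute *forward* prediction
    errors ``|x^mu - W_F f(W_H f(z_prev))|``, i.e. the observation error of
    the prediction made before the step's observation is seen; unlike the
    settled error it is not explained away by inference, which is what
    makes it usable for fault isolation. (Row 0 compares against the null
    prior and is not meaningful for monitoring.)
    """

    predicted: np.ndarray
    energies: np.ndarray
    channel_errors: np.ndarray
    states: list[StepState] = field(repr=False, default_factory=list)


# ------------------------------------------------------------------- energy
def energy(state: StepState, net: TPCNetwork) -> float:
    """Per-step energy F = ||z - W_H f(z_prev)||^2 + ||x - W_F f(z)||^2."""
    h, c = net.config.n_hidden, net.config.n_obs
    if state.z.shape != (h,) or state.z_prev.shape != (h,) or state.x.shape != (c,):
        raise ValueError("state vectors inconsistent with network shapes")
    act = net.config.act_code
    eps_z = state.z - net.W_H @ _f(state.z_prev, act)
    eps_x = state.x - net.W_F @ _f(state.z, act)
    return float(eps_z @ eps_z + eps_x @ eps_x)


# ---------------------------------------------------------------- inference
def infer_hidden(
    x: np.ndarray,
    z_prev: np.ndarray,
    net: TPCNetwork,
    iters: int | None = None,
    lr: float | None = None,
    engine: str = "numba",
) -> tuple[np.ndarray, np.ndarray]:
    """Settle the hidden state on a clamped observation.

    Runs ``iters`` explicit-Euler steps of the value-neuron dynamics
    ``dz ∝ -eps_z + f'(z) ⊙ W_F^T eps_x`` with step size ``lr``, starting
    from the temporal prediction ``W_H f(z_prev)`` (so the hidden error is
    zero at the first iterate). Returns the settled ``z`` and the energy at
    each iterate (length ``iters + 1``).
    """
    cfg = net.config
    iters = cfg.inference_iters if iters is None else int(iters)
    lr = cfg.inference_lr if lr is None else float(lr)
    if iters < 1:
        raise ValueError("iters must be >= 1")
    x = np.ascontiguousarray(x, dtype=float)
    if x.shape != (cfg.n_obs,) or z_prev.shape != (cfg.n_hidden,):
        raise ValueError("input vectors inconsistent with network shapes")
    a = np.ascontiguousarray(net.W_H @ _f(z_prev, cfg.act_code))
    if engine == "numba":
        z, energies = settle_hidden(
            a, net.W_F, np.ascontiguousarray(net.W_F.T), x, iters, lr, cfg.act_code
        )
    else:
        z, energies = settle_hidden_np(a, net.W_F, x, iters, lr, cfg.act_code)
    bad = ~np.isfinite(energies)
    if bad.any():
        raise DivergenceError(
            f"inference diverged at iteration {int(np.argmax(bad))} "
            f"(lr={lr}, iters={iters})"
        )
    return z, energies


# ----------------------------------------------------------------- learning
def update_weights(state: StepState, net: TPCNetwork, lr: float | None = None) -> TPCNetwork:
    """One local weight update from the converged state of a single step.

    W_H <- W_H + lr * eps_z f(z_prev)^T ;  W_F <- W_F + lr * eps_x f(z)^T.
    Returns a new network; the input is untouched.
    """
    lr = net.config.weight_lr if lr is None else float(lr)
    act = net.config.act_code
    W_H = net.W_H + lr * np.outer(state.eps_z, _f(state.z_prev, act))
    W_F = net.W_F + lr * np.outer(state.eps_x, _f(state.z, act))
    return TPCNetwork(W_H=W_H, W_F=W_F, config=net.config)


def _interleave(sequences: list) -> list:
    """Round-robin order across skill labels so every epoch interleaves skills."""
    labelled: dict[object, list] = {}
    for s in sequences:
        labelled.setdefault(getattr(s, "skill", None), []).append(s)
    if len(labelled) <= 1:
        return list(sequences)
    groups = list(labelled.values())
    order = []
    for i in range(max(len(g) for g in groups)):
        for g in groups:
            if i < len(g):
                order.append(g[i])
    return order


def memorise(
    sequences: list[SensorimotorSequence] | list[np.ndarray],
    net: TPCNetwork,
    epochs: int | None = None,
    engine: str = "numba",
) -> tuple[TPCNetwork, np.ndarray]:
    """Memorisation phase: alternate inference and local weight updates.

    For each epoch and each sequence (skills interleaved round-robin within
    an epoch), sweeps the steps in order: settles ``z`` on the clamped
    observation, applies the two local weight updates, and carries the
    converged ``z`` forward as the next step's ``z_prev`` (``z_prev = 0`` at
    the first step). The per-step energy is recorded after inference and
    before the update; the returned curve is the mean energy per epoch.
    """
    if not sequences:
        raise ValueError("memorise needs at least one sequence")
    epochs = net.config.epochs_per_skill if epochs is None else int(epochs)
    arrays = [np.ascontiguousarray(getattr(s, "values", s), dtype=float)
              for s in _interleave(list(sequences))]
    cfg = net.config
    for arr in arrays:
        if arr.ndim != 2 or arr.shape[1] != cfg.n_obs:
            raise ValueError("all sequences must be T x n_obs")
    out = net.copy()
    W_H, W_F = out.W_H, out.W_F
    act, lr_w = cfg.act_code, cfg.weight_lr
    curve = np.empty(epochs)
    for ep in range(epochs):
        total, count = 0.0, 0
        for arr in arrays:
            z_prev = np.zeros(cfg.n_hidden)
            f_prev = _f(z_prev, act)
            for mu in range(arr.shape[0]):
                x = arr[mu]
                a = np.ascontiguousarray(W_H @ f_prev)
                if engine == "numba":
                    z, energies = settle_hidden(
                        a, W_F, np.ascontiguousarray(W_F.T), x,
                        cfg.inference_iters, cfg.inference_lr, act,
                    )
                else:
                    z, energies = settle_hidden_np(
                        a, W_F, x, cfg.inference_iters, cfg.inference_lr, act
                    )
                if not np.isfinite(energies[-1]):
                    raise DivergenceError(f"training diverged at epoch {ep}, step {mu}")
                fz = _f(z, act)
                eps_z = z - a
                eps_x = x - W_F @ fz
                W_H += lr_w * np.outer(eps_z, f_prev)
                W_F += lr_w * np.outer(eps_x, fz)
                total += energies[-1]
                count += 1
                z_prev, f_prev = z, fz
        curve[ep] = total / count
    return out, curve


# ------------------------------------------------------------------- recall
def offline_recall(
    net: TPCNetwork,
    cue: np.ndarray,
    horizon: int,
    iters: int | None = None,
    lr: float | None = None,
) -> RecallResult:
    """Cued recall: settle on the cue window, then generate ballistically.

    For steps ``mu < T_n`` the observation is clamped to the cue and the
    hidden state settled iteratively; for ``mu >= T_n`` the model rolls
    forward deterministically, ``z = W_H f(z_prev)``, ``x_hat = W_F f(z)``
    (the HMM forward pass — the fixed point of the observation-settling
    dynamics for this two-layer model). The retrieved observation is
    ``W_F f(z)`` on every step, including the cue window.
    """
    cue = np.atleast_2d(np.asarray(cue, dtype=float))
    t_n = cue.shape[0]
    if not (1 <= t_n < horizon):
        raise ValueError("cue length T_n must satisfy 1 <= T_n < horizon")
    cfg = net.config
    iters = cfg.inference_iters if iters is None else int(iters)
    act = cfg.act_code
    predicted = np.empty((horizon, cfg.n_obs))
    energies = np.zeros(horizon)
    z_prev = np.zeros(cfg.n_hidden)
    for mu in range(t_n):
        z, trace = infer_hidden(cue[mu], z_prev, net, iters=iters, lr=lr)
        predicted[mu] = net.W_F @ _f(z, act)
        energies[mu] = trace[-1]
        z_prev = z
    for mu in range(t_n, horizon):
        z_prev = net.W_H @ _f(z_prev, act)
        predicted[mu] = net.W_F @ _f(z_prev, act)
    return RecallResult(predicted=predicted, energies=energies,
                        cue_length=t_n, inference_iters_used=iters)


def online_recall(
    net: TPCNetwork,
    observed: np.ndarray | SensorimotorSequence,
    iters: int | None = None,
    lr: float | None = None,
) -> OnlineRecallResult:
    """Step-by-step recall on ground-truth observations.

    At each step the observed vector is clamped, the hidden state settled,
    and the prediction for the next step emitted. The converged per-step
    energies are the monitoring signal consumed by the fault monitor; the
    per-step absolute observation errors support fault isolation.
    """
    obs = np.atleast_2d(np.asarray(getattr(observed, "values", observed), dtype=float))
    t_total = obs.shape[0]
    if t_total < 2:
        raise ValueError("online recall needs at least 2 observed steps")
    cfg = net.config
    act = cfg.act_code
    energies = np.empty(t_total)
    channel_errors = np.empty((t_total, cfg.n_obs))
    predicted = np.empty((t_total - 1, cfg.n_obs))
    states: list[StepState] = []
    z_prev = np.zeros(cfg.n_hidden)
    forward_pred = net.W_F @ _f(net.W_H @ _f(z_prev, act), act)
    for mu in range(t_total):
        z, trace = infer_hidden(obs[mu], z_prev, net, iters=iters, lr=lr)
        state = StepState.compute(z, z_prev, obs[mu], net)
        states.append(state)
        energies[mu] = trace[-1]
        channel_errors[mu] = np.abs(obs[mu] - forward_pred)
        forward_pred = net.W_F @ _f(net.W_H @ _f(z, act), act)
        if mu < t_total - 1:
            predicted[mu] = forward_pred
        z_prev = z
    return OnlineRecallResult(predicted=predicted, energies=energies,
                              channel_errors=channel_errors, states=states)
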