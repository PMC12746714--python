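"""Sequence-to-sequence RNN baselines trained by backpropagation through time.

Two vanilla (tanh) recurrent baselines mirror the tPC model in the
follow-through experiment:

* **S-to-M** maps sensory channels (end-effector position + context cue) to
  motor channels (joint angles);
* **SM-to-SM** maps the full sensorimotor vector to itself.

Both share the tPC network's hidden size, learning rate and batch size, but
are trained end-to-end by BPTT and have no iterative inference phase. To
mirror offline recall, the default training protocol feeds the real
observation only at the first time step: afterwards the S-to-M network
receives zeros on its sensory input while the SM-to-SM network feeds back
its own predictions, with gradients flowing through the feedback path.
Teacher-forced one-step-ahead training is available via a flag.

Gradients are derived by hand in numpy (validated against finite
differences in the test suite). Optimiser: plain SGD by default, Adam
behind a flag for reduced-budget runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SensorimotorSequence


@dataclass
class RNNConfig:
    """Baseline hyperparameters (defaults mirror the tPC recipe)."""

    n_hidden: int = 256
    lr: float = 1e-4
    n_iters: int = 1200
    batch_size: int = 1
    optimizer: str = "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1 or self.n_iters < 0 or self.batch_size < 1:
            raise ValueError("counts must be positive")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")


def _init_weights(n_in: int, n_hidden: int, n_out: int, seed: int):
    rng = np.random.default_rng(seed)

    def kaiming(shape, fan_in):
        b = np.sqrt(6.0 / fan_in)
        return rng.uniform(-b, b, size=shape)

    return {
        "W_in": kaiming((n_hidden, n_in), n_in),
        "W_h": kaiming((n_hidden, n_hidden), n_hidden),
        "W_out": kaiming((n_out, n_hidden), n_hidden),
    }


def _forward(weights, x0_in, targets, autoregressive, teacher_inputs=None):
    """Roll the RNN forward; returns outputs, caches for backprop, and loss.

    ``x0_in`` is the input at step 0. When ``teacher_inputs`` is given
    (teacher forcing) it supplies every step's input; otherwise steps >= 1
    receive either the network's own previous output (autoregressive) or
    zeros.
    """
    W_in, W_h, W_out = weights["W_in"], weights["W_h"], weights["W_out"]
    t_steps = targets.shape[0]
    n_hidden = W_h.shape[0]
    hs = np.empty((t_steps, n_hidden))
    ins = np.empty((t_steps, W_in.shape[1]))
    ys = np.empty_like(targets)
    h = np.zeros(n_hidden)
    inp = x0_in
    for t in range(t_steps):
        ins[t] = inp
        h = np.tanh(W_in @ inp + W_h @ h)
        hs[t] = h
        ys[t] = W_out @ h
        if teacher_inputs is not None:
            inp = teacher_inputs[t] if t + 1 < t_steps else inp
        elif autoregressive:
            inp = ys[t]
        else:
            inp = np.zeros_like(x0_in)
    loss = float(((ys - targets) ** 2).mean())
    return ys, hs, ins, loss


def _backward(weights, targets, ys, hs, ins, autoregressive, teacher_forced):
    """Hand-derived BPTT gradients of the mean-squared recall loss."""
    W_in, W_h, W_out = weights["W_in"], weights["W_h"], weights["W_out"]
    t_steps = targets.shape[0]
    grads = {k: np.zeros_like(v) for k, v in weights.items()}
    scale = 2.0 / targets.size
    dpre_next = np.zeros(W_h.shape[0])
    for t in range(t_steps - 1, -1, -1):
        dy = scale * (ys[t] - targets[t])
        if autoregressive and not teacher_forced and t + 1 < t_steps:
            dy = dy + W_in.T @ dpre_next  # feedback path: in_{t+1} = y_t
        grads["W_out"] += np.outer(dy, hs[t])
        dh = W_out.T @ dy + W_h.T @ dpre_next
        dpre = dh * (1.0 - hs[t] ** 2)
        grads["W_in"] += np.outer(dpre, ins[t])
        h_prev = hs[t - 1] if t > 0 else np.zeros_like(hs[0])
        grads["W_h"] += np.outer(dpre, h_prev)
        dpre_next = dpre
    return grads


class SequenceRNN:
    """BPTT-trained baseline over a trial set (statsmodels-style model).

    Parameters
    ----------
    trials : list of SensorimotorSequence or arrays
        Normalised training sequences (shared channel layout).
    kind : {"sm_to_sm", "s_to_m"}
        Channel mapping of the baseline.
    sensory_idx, motor_idx : array-like of int
        Channel subsets; required for ``s_to_m``.
    config : RNNConfig
    teacher_forcing : bool
        If True, train one-step-ahead on clamped inputs instead of the
        first-step-only recall protocol.
    """

    def __init__(
        self,
        trials,
        kind: str = "sm_to_sm",
        sensory_idx=None,
        motor_idx=None,
        config: RNNConfig | None = None,
        teacher_forcing: bool = False,
    ):
        if kind not in ("sm_to_sm", "s_to_m"):
            raise ValueError("kind must be 'sm_to_sm' or 's_to_m'")
        self.arrays = [np.asarray(getattr(t, "values", t), dtype=float) for t in trials]
        if not self.arrays:
            raise ValueError("need at least one training trial")
        n_channels = self.arrays[0].shape[1]
        if kind == "sm_to_sm":
            self.input_idx = np.arange(n_channels)
            self.output_idx = np.arange(n_channels)
        else:
            if sensory_idx is None or motor_idx is None:
                raise ValueError("s_to_m needs sensory_idx and motor_idx")
            self.input_idx = np.asarray(sensory_idx, dtype=int)
            self.output_idx = np.asarray(motor_idx, dtype=int)
        self.kind = kind
        self.config = config or RNNConfig()
        self.teacher_forcing = teacher_forcing

    def fit(self) -> "RNNResults":
        cfg = self.config
        weights = _init_weights(len(self.input_idx), cfg.n_hidden, len(self.output_idx), cfg.seed)
        auto = self.kind == "sm_to_sm"
        adam_m = {k: np.zeros_like(v) for k, v in weights.items()}
        adam_v = {k: np.zeros_like(v) for k, v in weights.items()}
        losses = np.empty(cfg.n_iters)
        for it in range(cfg.n_iters):
            arr = self.arrays[it % len(self.arrays)]
            x0_in = arr[0, self.input_idx]
            targets = arr[1:, self.output_idx]
            teacher = arr[1:, self.input_idx] if self.teacher_forcing else None
            ys, hs, ins, loss = _forward(weights, x0_in, targets, auto, teacher)
            if not np.isfinite(loss):
                raise RuntimeError(f"BPTT training diverged at trial {it}")
            grads = _backward(weights, targets, ys, hs, ins, auto, self.teacher_forcing)
            if cfg.optimizer == "sgd":
                for k in weights:
                    weights[k] -= cfg.lr * grads[k]
            else:  # adam
                b1, b2, eps = 0.9, 0.999, 1e-8
                for k in weights:
                    adam_m[k] = b1 * adam_m[k] + (1 - b1) * grads[k]
                    adam_v[k] = b2 * adam_v[k] + (1 - b2) * grads[k] ** 2
                    m_hat = adam_m[k] / (1 - b1 ** (it + 1))
                    v_hat = adam_v[k] / (1 - b2 ** (it + 1))
                    weights[k] -= cfg.lr * m_hat / (np.sqrt(v_hat) + eps)
            losses[it] = loss
        return RNNResults(model=self, weights=weights, loss_curve=losses)


@dataclass
class RNNResults:
    """Fitted baseline: weights, loss curve, and the recall interface."""

    model: SequenceRNN
    weights: dict
    loss_curve: np.ndarray = field(repr=False, default=None)

    def offline_recall(self, first_obs: np.ndarray, horizon: int,
                       inference_iters: int | None = None) -> np.ndarray:
        """Predictions for steps 1..horizon from the first observation only.

        ``inference_iters`` is accepted for interface parity with the tPC
        model and ignored: the baseline has no iterative inference phase,
        which is exactly why its speed-accuracy curve is flat.
        """
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        first_obs = np.asarray(first_obs, dtype=float)
        x0_in = first_obs[self.model.input_idx]
        dummy_targets = np.zeros((horizon, len(self.model.output_idx)))
        ys, _, _, _ = _forward(self.weights, x0_in, dummy_targets,
                               self.model.kind == "sm_to_sm")
        return ys


def speed_accuracy_probe(results: RNNResults, error_fn, iteration_grid=(2, 5, 10, 20, 50, 100)):
    """Constant recall-error curve over a (meaningless) iteration axis.

    Formalises the negative prediction: without an inference phase there is
    no preparation-time knob, so the recall error cannot depend on it.
    """
    import pandas as pd

    err = float(error_fn(results))
    return pd.DataFrame(
        [{"iterations": int(n), "median_mse": err} for n in iteration_grid]
    )
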