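"""Statsmodels-style modelling interface for the Neural ASM.

``NeuralASM`` is constructed from a list of demonstration trials; ``fit()``
Z-scores the channels, memorises the sequences with the tPC learning rule,
and returns a ``NeuralASMResults`` object carrying the learned weights, the
training-energy curve, and the recall / monitoring operations expressed in
the original physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import faults, tpc
from .data import ChannelNormaliser, SensorimotorSequence


class NeuralASM:
    """Neural Associative Skill Memory model over a demonstration set.

    Parameters
    ----------
    trials : list of SensorimotorSequence
        Demonstrations of one or more skills (shared channel layout).
        Skills are interleaved within every training epoch.
    normalise : bool
        Z-score channels before training (pooled over trials and time).
    **config_kwargs
        Forwarded to :class:`neural_asm.tpc.TPCConfig` (``n_hidden``,
        ``weight_lr``, ``inference_iters``, ``seed``, ...).
    """

    def __init__(self, trials: list[SensorimotorSequence], normalise: bool = True, **config_kwargs):
        if not trials:
            raise ValueError("need at least one demonstration trial")
        self.trials = list(trials)
        self.channels = trials[0].channels
        self.config = tpc.TPCConfig(n_obs=trials[0].n_channels, **config_kwargs)
        if normalise:
            self.normaliser = ChannelNormaliser.fit(trials)
        else:
            n_c = trials[0].n_channels
            self.normaliser = ChannelNormaliser(mean=np.zeros(n_c), sd=np.ones(n_c))

    def fit(self, epochs: int | None = None) -> "NeuralASMResults":
        """Memorise the demonstration set; returns the fitted results."""
        net = tpc.TPCNetwork.init(self.config)
        normalised = [self.normaliser.transform_trial(t) for t in self.trials]
        epochs = self.config.epochs_per_skill if epochs is None else epochs
        net, curve = tpc.memorise(normalised, net, epochs=epochs)
        return NeuralASMResults(model=self, network=net, energy_curve=curve)


@dataclass
class NeuralASMResults:
    """Fitted Neural ASM: weights, energy curve, recall and monitoring."""

    model: NeuralASM
    network: tpc.TPCNetwork
    energy_curve: np.ndarray = field(repr=False, default=None)

    @property
    def normaliser(self) -> ChannelNormaliser:
        return self.model.normaliser

    # ------------------------------------------------------------- recall
    def offline_recall(
        self,
        cue: np.ndarray,
        horizon: int,
        inference_iters: int | None = None,
        denormalise: bool = True,
    ) -> tpc.RecallResult:
        """Cued recall from the first ``T_n`` raw-unit observations."""
        cue_n = self.normaliser.transform(np.atleast_2d(cue))
        res = tpc.offline_recall(self.network, cue_n, horizon, iters=inference_iters)
        if denormalise:
            res.predicted = self.normaliser.inverse(res.predicted)
        return res

    def online_recall(self, observed, inference_iters: int | None = None) -> tpc.OnlineRecallResult:
        """Step-by-step recall on a raw-unit trial (normalised internally)."""
        values = np.asarray(getattr(observed, "values", observed), dtype=float)
        return tpc.online_recall(self.network, self.normaliser.transform(values),
                                 iters=inference_iters)

    # --------------------------------------------------------- monitoring
    def normal_energies(self, trials=None) -> np.ndarray:
        """Pooled per-step monitoring energies over fault-free trials.

        The initial step of each trial is excluded: with a null prior
        (``z_prev = 0``) its energy measures initial-state inference, not
        prediction quality, and would otherwise dominate the percentile.
        """
        trials = self.model.trials if trials is None else trials
        return np.concatenate([self.online_recall(t).energies[1:] for t in trials])

    def fit_threshold(self, percentile: float = 95.0, trials=None) -> faults.EnergyThreshold:
        """Energy threshold at a nearest-rank percentile of normal operation."""
        return faults.fit_threshold(self.normal_energies(trials), percentile)

    def monitor(self, observed, threshold: faults.EnergyThreshold,
                start_step: int = 1) -> faults.FaultReport:
        """Monitor one raw-unit trial against a fitted threshold.

        Monitoring starts at step 1; the initial step has no temporal
        context (see :meth:`normal_energies`).
        """
        res = self.online_recall(observed)
        return faults._report_from_traces(res.energies, res.channel_errors,
                                          threshold, max(start_step, 1))

    # ------------------------------------------------------------ summary
    def summary(self) -> str:
        cfg = self.network.config
        skills = sorted({t.skill for t in self.model.trials if t.skill is not None})
        lines = [
            "Neural Associative Skill Memory",
            "=" * 47,
            f"{'observation channels':<28}{cfg.n_obs}",
            f"{'hidden units':<28}{cfg.n_hidden}",
            f"{'activation':<28}{cfg.activation}",
            f"{'weight learning rate':<28}{cfg.weight_lr:g}",
            f"{'inference lr / iters':<28}{cfg.inference_lr:g} / {cfg.inference_iters}",
            f"{'seed':<28}{cfg.seed}",
            f"{'training trials':<28}{len(self.model.trials)}",
            f"{'skills memorised':<28}{', '.join(skills) if skills else '(unlabelled)'}",
        ]
        if self.energy_curve is not None and len(self.energy_curve):
            lines += [
                f"{'epochs run':<28}{len(self.energy_curve)}",
                f"{'initial mean energy':<28}{self.energy_curve[0]:.4f}",
                f"{'final mean energy':<28}{self.energy_curve[-1]:.4f}",
            ]
        return "\n".join(lines)

    # ------------------------------------------------------ serialisation
    def save(self, path) -> None:
        import json

        self.network.save(path, channels=self.model.channels)
        side = str(path) + ".norm.json"
        with open(side, "w") as fh:
            json.dump({"mean": self.normaliser.mean.tolist(),
                       "sd": self.normaliser.sd.tolist(),
                       "energy_curve": None if self.energy_curve is None
                       else self.energy_curve.tolist()}, fh)

    @classmethod
    def load(cls, path, trials: list[SensorimotorSequence]) -> "NeuralASMResults":
        import json

        net, _channels = tpc.TPCNetwork.load(path)
        with open(str(path) + ".norm.json") as fh:
            side = json.load(fh)
        model = NeuralASM.__new__(NeuralASM)
        model.trials = list(trials)
        model.channels = trials[0].channels if trials else _channels
        model.config = net.config
        model.normaliser = ChannelNormaliser(mean=np.array(side["mean"]),
                                             sd=np.array(side["sd"]))
        curve = None if side["energy_curve"] is None else np.array(side["energy_curve"])
        return cls(model=model, network=net, energy_curve=curve)
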