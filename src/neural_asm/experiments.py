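"""End-to-end experiment pipelines.

Two study pipelines tie the modules together:

* **Fault study** — memorise two pick-and-place skills from 10 noisy
  demonstrations each, fit the energy (and baseline) detection thresholds
  on the fault-free monitoring traces, then score both monitors over the
  462-cell factorial joint-lock grid.
* **Follow-through study** — train the tPC model and the two BPTT baselines
  on each cue-availability condition over several seeds, recall offline
  from first-step observations, and score the directional compensatory
  deviation (DCD) and the speed-accuracy curve.

The defaults here are the package's reduced experimental protocol: smaller
hidden layers and training budgets than the full recipe in
:class:`neural_asm.tpc.TPCConfig`, chosen so a complete study runs on a
single CPU in minutes (see docs/methods.md for the exact sizes and why).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import faults, metrics, plant, rnn, tpc
from .data import ChannelNormaliser, zscore_normalise
from .model import NeuralASM, NeuralASMResults


# ------------------------------------------------------------- fault study
def run_fault_pipeline(
    seed: int = 0,
    epochs: int = 200,
    n_hidden: int = 256,
    n_reps: int = 10,
    noise_scale: float = 0.02,
    percentile: float = 95.0,
    joints: tuple = tuple(range(1, 8)),
    fault_times: tuple = faults.DEFAULT_FAULT_TIMES,
    overshoots: tuple = faults.DEFAULT_OVERSHOOTS,
) -> dict:
    """Train, threshold, and score the full fault-detection study.

    Both thresholds are calibrated on a fresh set of fault-free monitoring
    trials (10 per skill) rather than the training demonstrations, so the
    fitted false-positive rate holds out-of-sample for both methods.
    Returns a dict with the fitted results object, both thresholds, the
    pooled normal energies, the per-trial grid table and its summary.
    """
    demos_a = plant.make_pick_place_demos("A", n_reps=n_reps, noise_scale=noise_scale, seed=seed)
    demos_b = plant.make_pick_place_demos("B", n_reps=n_reps, noise_scale=noise_scale, seed=seed + 1)
    trials = demos_a + demos_b
    asm = NeuralASM(trials, n_hidden=n_hidden, seed=seed)
    fitted = asm.fit(epochs=epochs)

    monitor_a = plant.make_pick_place_demos("A", n_reps=n_reps, noise_scale=noise_scale, seed=seed + 500)
    monitor_b = plant.make_pick_place_demos("B", n_reps=n_reps, noise_scale=noise_scale, seed=seed + 501)
    monitor_trials = monitor_a + monitor_b
    normal_energies = fitted.normal_energies(monitor_trials)
    energy_thr = faults.fit_threshold(normal_energies, percentile)

    stats = faults.ChannelStats.fit({"A": demos_a, "B": demos_b})
    normal_stats = np.concatenate(
        [faults.zscore_baseline(d, stats, d.skill)[0][1:] for d in monitor_trials]
    )
    baseline_thr = faults.fit_threshold(normal_stats, percentile)

    table = faults.evaluate_fault_grid(
        fitted.network,
        asm.normaliser,
        stats,
        energy_thr,
        baseline_thr,
        joints=joints,
        fault_times=fault_times,
        overshoots=overshoots,
        noise_scale=noise_scale,
        seed=seed + 10_000,
    )
    return {
        "results": fitted,
        "monitor_trials": monitor_trials,
        "channel_stats": stats,
        "energy_threshold": energy_thr,
        "baseline_threshold": baseline_thr,
        "normal_energies": normal_energies,
        "normal_baseline_stats": normal_stats,
        "table": table,
        "summary": faults.summarise_fault_grid(table),
    }


# ----------------------------------------------------- follow-through study
@dataclass
class FollowThroughProtocol:
    """Reduced training/evaluation protocol for the follow-through study."""

    n_trials: int = 4          # demonstrations per context
    n_recall: int = 12         # recall cues per context (24 per condition)
    noise_scale: float = 0.02
    amplitude: float = 0.02    # lateral bow, metres
    tpc_hidden: int = 128
    tpc_epochs: int = 600
    rnn_hidden: int = 64
    rnn_iters: int = 1200
    rnn_lr: float = 5e-3
    rnn_optimizer: str = "adam"

MODELS = ("tpc", "sm_to_sm", "s_to_m")


@dataclass
class TrainedCondition:
    """All three models trained on one condition with one seed."""

    condition: str
    seed: int
    dataset: plant.FollowThroughDataset
    normaliser: ChannelNormaliser
    tpc_net: tpc.TPCNetwork
    rnn_results: dict[str, rnn.RNNResults]
    protocol: FollowThroughProtocol


def train_followthrough_models(
    condition: str,
    seed: int,
    protocol: FollowThroughProtocol | None = None,
) -> TrainedCondition:
    """Train the tPC model and both RNN baselines on one cue condition."""
    proto = protocol or FollowThroughProtocol()
    ds = plant.make_followthrough_dataset(
        condition, n_trials=proto.n_trials, noise_scale=proto.noise_scale,
        amplitude=proto.amplitude, seed=seed,
    )
    norm_trials, norm = zscore_normalise(ds.trials)
    cfg = tpc.TPCConfig(n_obs=ds.trials[0].n_channels, n_hidden=proto.tpc_hidden, seed=seed)
    net = tpc.TPCNetwork.init(cfg)
    net, _curve = tpc.memorise(norm_trials, net, epochs=proto.tpc_epochs)

    rnn_results = {}
    for kind in ("sm_to_sm", "s_to_m"):
        model = rnn.SequenceRNN(
            norm_trials,
            kind=kind,
            sensory_idx=ds.sensory_idx,
            motor_idx=ds.motor_idx,
            config=rnn.RNNConfig(n_hidden=proto.rnn_hidden, lr=proto.rnn_lr,
                                 n_iters=proto.rnn_iters,
                                 optimizer=proto.rnn_optimizer, seed=seed),
        )
        rnn_results[kind] = model.fit()
    return TrainedCondition(condition=condition, seed=seed, dataset=ds,
                            normaliser=norm, tpc_net=net,
                            rnn_results=rnn_results, protocol=proto)


def _denorm_subset(norm: ChannelNormaliser, arr: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return arr * norm.sd[idx] + norm.mean[idx]


def _recall_paths(trained: TrainedCondition, model_name: str, context: str,
                  inference_iters: int | None = None) -> np.ndarray:
    """Mean recalled end-effector path for one context (raw units).

    Recall is cued with the first observation of ``n_recall`` freshly drawn
    noisy trials of the context and the recalled paths are averaged.
    """
    ds, proto, norm = trained.dataset, trained.protocol, trained.normaliser
    horizon = ds.plans[context].shape[0]
    fresh = plant.make_followthrough_dataset(
        ds.condition, n_trials=proto.n_recall, noise_scale=proto.noise_scale,
        amplitude=ds.amplitude, seed=trained.seed + 50_000,
    )
    cues = [t.values[0] for t in fresh.trials if t.skill == context]
    paths = []
    for cue in cues:
        cue_n = norm.transform(cue[None, :])
        if model_name == "tpc":
            res = tpc.offline_recall(trained.tpc_net, cue_n, horizon,
                                     iters=inference_iters)
            pred = norm.inverse(res.predicted)
            paths.append(pred[:, plant.FT_EE_IDX])
        elif model_name == "sm_to_sm":
            preds = trained.rnn_results["sm_to_sm"].offline_recall(cue_n[0], horizon - 1)
            pred = norm.inverse(preds)
            paths.append(np.vstack([cue[plant.FT_EE_IDX], pred[:, plant.FT_EE_IDX]]))
        elif model_name == "s_to_m":
            preds = trained.rnn_results["s_to_m"].offline_recall(cue_n[0], horizon - 1)
            joints = _denorm_subset(norm, preds, ds.motor_idx)
            ee = plant.two_link_fk(joints)
            paths.append(np.vstack([cue[plant.FT_EE_IDX], ee]))
        else:
            raise ValueError(f"unknown model {model_name!r}")
    return np.mean(paths, axis=0)


def evaluate_dcd(trained: TrainedCondition, model_name: str,
                 inference_iters: int | None = None) -> dict:
    """Context-averaged DCD of one trained model on its condition."""
    ds = trained.dataset
    per_context = {}
    for context in plant.CONTEXTS:
        path = _recall_paths(trained, model_name, context, inference_iters)
        per_context[context] = metrics.dcd(path, ds.S, ds.T_pt, context).value
    return {"mean": float(np.mean(list(per_context.values()))), **per_context}


def run_followthrough_experiment(
    seeds: tuple = (0, 1, 2, 3, 4, 5),
    conditions: tuple = plant.CONDITIONS,
    models: tuple = MODELS,
    protocol: FollowThroughProtocol | None = None,
) -> pd.DataFrame:
    """Per-seed DCD table for every model x condition (Fig-5E-style)."""
    rows = []
    for condition in conditions:
        for seed in seeds:
            trained = train_followthrough_models(condition, seed, protocol)
            for name in models:
                scores = evaluate_dcd(trained, name)
                rows.append({"model": name, "condition": condition, "seed": seed,
                             "dcd": scores["mean"], "dcd_cw": scores["cw"],
                             "dcd_ccw": scores["ccw"]})
    return pd.DataFrame(rows)


def separation_summary(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Sign-rank memory-separation test per model x condition."""
    rows = []
    for (model_name, condition), grp in table.groupby(["model", "condition"]):
        res = metrics.memory_separation_test(grp["dcd"].to_numpy(), alpha=alpha)
        rows.append({"model": model_name, "condition": condition, **res})
    return pd.DataFrame(rows)


# ----------------------------------------------------------- speed-accuracy
def tpc_recall_mse(trained: TrainedCondition, inference_iters: int) -> float:
    """Context-averaged offline-recall MSE (normalised units) of the tPC model."""
    ds, norm = trained.dataset, trained.normaliser
    errs = []
    for context in plant.CONTEXTS:
        plan = ds.plans[context]
        joints = plant.two_link_ik(plan)
        cue_chan = np.zeros((plan.shape[0], 2))
        cue_chan[ds.cue_onset:, 0 if context == "cw" else 1] = 1.0
        truth = norm.transform(np.concatenate([plan, joints, cue_chan], axis=1))
        res = tpc.offline_recall(trained.tpc_net, truth[:1], plan.shape[0],
                                 iters=inference_iters)
        _, total = metrics.recall_mse(res.predicted, truth)
        errs.append(total)
    return float(np.mean(errs))


def rnn_recall_mse(trained: TrainedCondition, kind: str) -> float:
    """Context-averaged first-step-cued recall MSE of a BPTT baseline."""
    ds, norm = trained.dataset, trained.normaliser
    out_idx = np.arange(len(ds.trials[0].channels)) if kind == "sm_to_sm" else ds.motor_idx
    errs = []
    for context in plant.CONTEXTS:
        plan = ds.plans[context]
        joints = plant.two_link_ik(plan)
        cue_chan = np.zeros((plan.shape[0], 2))
        cue_chan[ds.cue_onset:, 0 if context == "cw" else 1] = 1.0
        truth = norm.transform(np.concatenate([plan, joints, cue_chan], axis=1))
        preds = trained.rnn_results[kind].offline_recall(truth[0], plan.shape[0] - 1)
        _, total = metrics.recall_mse(preds, truth[1:, out_idx])
        errs.append(total)
    return float(np.mean(errs))


def run_speed_accuracy(
    trained_by_seed: dict[int, TrainedCondition],
    iteration_grid: tuple = (2, 5, 10, 20, 50, 100),
) -> pd.DataFrame:
    """Median-over-seeds tPC recall MSE versus inference iterations."""
    seeds = tuple(sorted(trained_by_seed))
    return metrics.speed_accuracy_curve(
        lambda iters, seed: tpc_recall_mse(trained_by_seed[seed], iters),
        iteration_grid=iteration_grid,
        seeds=seeds,
    )
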