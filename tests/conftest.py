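"""Shared fixtures.

The two study pipelines are expensive (a minute to several minutes), so
they run once per session and every test that inspects their outcomes
shares the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from neural_asm import experiments, plant, tpc


@pytest.fixture(scope="session")
def fault_run():
    """One complete fault study: training, thresholds, 462-cell grid."""
    return experiments.run_fault_pipeline(seed=0)


@pytest.fixture(scope="session")
def followthrough_runs():
    """All three models trained on all three conditions over 6 seeds.

    Returns ``(trained, table)``: the trained-condition objects keyed by
    (condition, seed), and the per-seed DCD table.
    """
    seeds = tuple(range(6))
    trained = {}
    rows = []
    for condition in plant.CONDITIONS:
        for seed in seeds:
            tc = experiments.train_followthrough_models(condition, seed)
            trained[(condition, seed)] = tc
            for name in experiments.MODELS:
                scores = experiments.evaluate_dcd(tc, name)
                rows.append({"model": name, "condition": condition, "seed": seed,
                             "dcd": scores["mean"], "dcd_cw": scores["cw"],
                             "dcd_ccw": scores["ccw"]})
    import pandas as pd

    return trained, pd.DataFrame(rows)


@pytest.fixture()
def small_net():
    """Small random tanh network for oracle tests."""
    cfg = tpc.TPCConfig(n_obs=3, n_hidden=4, seed=11)
    return tpc.TPCNetwork.init(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
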