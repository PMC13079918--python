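"""Shared fixtures: small simulated worlds and a trained tiny model.

Everything is generated at run time from seeds; no stored fixtures. The
session-scoped trained model is deliberately the most expensive fixture
(several CPU-minutes) and is shared by the end-to-end and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from coaltrace import scenarios, training
from coaltrace.features import WindowScheme, featurize_replicate
from coaltrace.model import CoalescenceTransformer, tiny_config
from coaltrace.scenarios import true_tmrca_track, within_individual_pivots


@pytest.fixture(scope="session")
def small_config():
    """10 diploids, 100 kb, constant Ne=2e4: cheap but non-trivial."""
    return scenarios.build_scenario("narrow_constant", seq_length=100_000,
                                    diploid_n=10)


@pytest.fixture(scope="session")
def small_rep(small_config):
    return scenarios.simulate(small_config, seed=11)


@pytest.fixture(scope="session")
def small_scheme(small_config):
    c = small_config
    return WindowScheme.for_cohort(c.seq_length, c.window_bp, c.diploid_n)


@pytest.fixture(scope="session")
def bench_config():
    """The benchmark world at tiny-model scale: 25 diploids, K=50 windows."""
    return scenarios.build_scenario("narrow_constant", seq_length=100_000)


#: Pivot pairs drawn per training replicate. Many independent genealogies
#: beat many pivots of one genealogy: pivots of a replicate share its ARG
#: and correlate strongly (see docs/methods.md).
TRAIN_PIVOTS = [(2 * i, 2 * i + 1) for i in range(10)]


@pytest.fixture(scope="session")
def trained_tiny(bench_config):
    """Tiny model trained on ~500 constant-Ne examples (session-shared).

    50 replicates x 10 within-individual pivot pairs = 500 examples; the
    2-layer / E=64 / K=50 configuration; AdamW at the 3e-4 base rate with
    cosine annealing, self-sampled rollout, and best-validation-epoch
    selection. Takes ~12 CPU-minutes; every end-to-end test shares it.
    """
    reps = [scenarios.simulate(bench_config, seed=s) for s in range(1, 51)]
    ds = training.dataset_from_replicates(reps, pivots=TRAIN_PIVOTS)
    net = CoalescenceTransformer(tiny_config(), seed=0)
    cfg = training.TrainConfig(epochs=80, batch_size=25, seed=0)
    ckpt = training.train(net, ds, cfg)
    return dict(ckpt=ckpt, train_reps=reps, dataset=ds, config=bench_config)


@pytest.fixture(scope="session")
def heldout_eval(trained_tiny, bench_config):
    """Held-out replicates decoded with the trained tiny model."""
    from coaltrace import inference

    ck = trained_tiny["ckpt"]
    pivots = within_individual_pivots(bench_config.diploid_n)
    tracks_all, truth_tracks, mcs_all = [], [], []
    test_reps = [scenarios.simulate(bench_config, seed=s) for s in range(100, 105)]
    for i, rep in enumerate(test_reps):
        mcs = featurize_replicate(rep, pivots)
        tracks = inference.decode_cohort(ck.net, mcs, bench_config.mu, ck.grid,
                                         n_reps=15, seed=1000 + i)
        for pv, tr, mc in zip(pivots, tracks, mcs):
            tracks_all.append(tr)
            truth_tracks.append(true_tmrca_track(rep, pv, mode="mean"))
            mcs_all.append(mc)
    return dict(tracks=tracks_all, truths=truth_tracks, mcs=mcs_all,
                test_reps=test_reps)
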