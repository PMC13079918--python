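"""Decoding, replicate posteriors, summaries and coverage."""

import numpy as np
import pytest
from scipy import stats

from coaltrace import inference
from coaltrace.features import MutationContextTensor, WindowScheme
from coaltrace.inference import (PosteriorTracks, boundary_mask, coverage_eval,
                                 decode_cohort, decode_pair, summarize)
from coaltrace.model import CoalescenceTransformer, sample_trajectory, tiny_config
from coaltrace.scenarios import TmrcaTrack
from coaltrace.timescale import TimeDiscretization


def stub_net(K=6, bias=None, n_bins=324, seed=0):
    """A real network rigged to emit a fixed categorical at every slot:
    zero final-layer weights, logits = head bias."""
    net = CoalescenceTransformer(tiny_config(n_windows=K, n_freq=9,
                                             n_bins=n_bins, dropout=0.0),
                                 seed=seed)
    net.head.W.data = np.zeros_like(net.head.W.data)
    if bias is not None:
        net.head.b.data = np.asarray(bias, dtype=np.float32)
    return net


def make_mc(K=6, n_freq=9, seed=0, xor_total=80, window_bp=2000):
    rng = np.random.default_rng(seed)
    scheme = WindowScheme(seq_length=K * window_bp, window_bp=window_bp,
                          n_freq=n_freq)
    counts = rng.integers(0, 4, size=(2, scheme.n_scales, K, n_freq)).astype(np.int32)
    return MutationContextTensor(counts=counts,
                                 accessibility=np.zeros((scheme.n_scales, K),
                                                        dtype=np.float32),
                                 scheme=scheme, xor_total=xor_total,
                                 accessible_bp=float(K * window_bp), pivot=(0, 1))


class TestDecoding:
    def test_one_hot_stub_gives_argmax_path_every_replicate(self):
        bias = np.zeros(324)
        bias[100] = 50.0
        net = stub_net(bias=bias)
        grid = TimeDiscretization.ratio_grid()
        tracks = decode_pair(net, make_mc(), mu=1e-8, grid=grid, n_reps=5, seed=0)
        assert np.allclose(tracks.ratios, grid.representative[100])

    def test_fixed_categorical_frequencies_match_chi2(self):
        """Stub emitting categorical p: sampled bin frequencies match p."""
        p = np.array([0.5, 0.3, 0.15, 0.05])
        net = stub_net(K=8, bias=np.log(p), n_bins=4)
        mc, acc = (np.random.default_rng(0).random((200, 2, 7, 8, 9))
                   .astype(np.float32), np.zeros((200, 7, 8), dtype=np.float32))
        toks = sample_trajectory(net, mc, acc, np.random.default_rng(1))
        counts = np.bincount(toks.ravel(), minlength=4)
        chi2, pval = stats.chisquare(counts, p * toks.size)
        assert pval > 0.001

    def test_default_replicate_count_is_15(self):
        net = stub_net()
        tracks = decode_pair(net, make_mc(), mu=1e-8,
                             grid=TimeDiscretization.ratio_grid(), seed=0)
        assert tracks.n_reps == 15

    def test_batched_equals_sequential_with_matched_seeds(self):
        net = CoalescenceTransformer(tiny_config(n_windows=6, n_freq=9,
                                                 dropout=0.0), seed=3)
        grid = TimeDiscretization.ratio_grid()
        mcs = [make_mc(seed=s, xor_total=60 + s) for s in range(5)]
        batched = decode_cohort(net, mcs, mu=1e-8, grid=grid, n_reps=4, seed=9,
                                batch_size=64)
        sequential = [decode_pair(net, mc, mu=1e-8, grid=grid, n_reps=4, seed=9,
                                  pair_index=i) for i, mc in enumerate(mcs)]
        for b, s in zip(batched, sequential):
            assert np.array_equal(b.times, s.times)
            assert np.array_equal(b.factors, s.factors)

    def test_empty_pivot_list_gives_empty_result(self):
        net = stub_net()
        assert decode_cohort(net, [], mu=1e-8,
                             grid=TimeDiscretization.ratio_grid()) == []

    def test_end_to_end_determinism(self):
        net = CoalescenceTransformer(tiny_config(n_windows=6, n_freq=9,
                                                 dropout=0.0), seed=1)
        grid = TimeDiscretization.ratio_grid()
        t1 = decode_pair(net, make_mc(), mu=1e-8, grid=grid, seed=4)
        t2 = decode_pair(net, make_mc(), mu=1e-8, grid=grid, seed=4)
        assert np.array_equal(t1.times, t2.times)

    def test_calibration_ties_track_mean_to_clock_draw(self):
        """Each replicate's arithmetic mean equals its clock draw exactly."""
        net = CoalescenceTransformer(tiny_config(n_windows=6, n_freq=9,
                                                 dropout=0.0), seed=2)
        tracks = decode_pair(net, make_mc(), mu=1e-8,
                             grid=TimeDiscretization.ratio_grid(), seed=0)
        assert np.allclose(tracks.times.mean(axis=1),
                           tracks.factors * tracks.ratios.mean(axis=1))


class TestSummaries:
    def test_single_replicate_degenerate(self):
        tr = PosteriorTracks(pivot=(0, 1), window_starts=np.arange(4) * 100,
                             window_bp=100, times=np.full((1, 4), 50.0),
                             ratios=np.ones((1, 4)), factors=np.ones(1))
        df = summarize(tr)
        assert np.allclose(df["mean"], 50.0)
        assert np.allclose(df["variance"], 0.0)

    def test_intervals_nested(self):
        rng = np.random.default_rng(0)
        tr = PosteriorTracks(pivot=(0, 1), window_starts=np.arange(10) * 100,
                             window_bp=100,
                             times=rng.lognormal(8, 1, size=(30, 10)),
                             ratios=np.ones((30, 10)), factors=np.ones(30))
        df = summarize(tr, levels=(0.5, 0.9))
        assert (df.lo90 <= df.lo50).all() and (df.hi50 <= df.hi90).all()

    def test_constant_replicates_mean_is_constant(self):
        tr = PosteriorTracks(pivot=(0, 1), window_starts=np.arange(3) * 10,
                             window_bp=10, times=np.full((5, 3), 7.0),
                             ratios=np.ones((5, 3)), factors=np.ones(5))
        assert np.allclose(summarize(tr)["median"], 7.0)


class TestCoverage:
    def _tracks(self, times):
        K = times.shape[1]
        return PosteriorTracks(pivot=(0, 1), window_starts=np.arange(K) * 10,
                               window_bp=10, times=times,
                               ratios=np.ones_like(times),
                               factors=np.ones(times.shape[0]))

    def _truth(self, values):
        K = len(values)
        return TmrcaTrack(pivot=(0, 1), window_starts=np.arange(K) * 10,
                          values=values, window_bp=10, kind="true_mean")

    def test_truth_at_median_gives_full_coverage(self):
        rng = np.random.default_rng(1)
        times = rng.lognormal(8, 0.4, size=(41, 20))
        tr = self._tracks(times)
        truth = self._truth(np.median(times, axis=0))
        cov = coverage_eval(tr, truth, levels=(0.5, 0.9))
        assert (cov.overall == 1.0).all()

    def test_zero_width_intervals_miss(self):
        tr = self._tracks(np.full((5, 8), 100.0))
        truth = self._truth(np.full(8, 200.0))
        cov = coverage_eval(tr, truth, levels=(0.8,))
        assert cov.overall.iloc[0] == 0.0

    def test_iid_synthetic_calibration_near_nominal(self):
        """Replicates and truth drawn iid: coverage ~= nominal level."""
        rng = np.random.default_rng(7)
        trs, ths = [], []
        for _ in range(60):
            draws = rng.lognormal(8, 0.5, size=(40, 20))
            trs.append(self._tracks(draws[:39]))
            ths.append(self._truth(draws[39]))
        cov = coverage_eval(trs, ths, levels=(0.5, 0.8))
        for _, row in cov.iterrows():
            se = np.sqrt(row.level * (1 - row.level) / 1200) * 4
            assert abs(row.overall - row.level) < max(se, 0.04)

    def test_grid_mismatch_rejected(self):
        tr = self._tracks(np.ones((3, 5)))
        truth = TmrcaTrack(pivot=(0, 1), window_starts=np.arange(4) * 10,
                           values=np.ones(4), window_bp=10)
        with pytest.raises(ValueError):
            coverage_eval(tr, truth)


def test_boundary_mask_marks_edges():
    m = boundary_mask(50)
    assert m[:3].all() and m[-3:].all()
    assert not m[3:-3].any()
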