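"""Decoding TMRCA trajectories and quantifying their uncertainty.

For one pivot pair the model is run autoregressively: at each window a
bin is sampled from the predictive distribution (temperature 1 by
default), appended to the context, and decoding continues through all K
windows. Repeating this 15 times yields samples from an approximate
posterior over the pair's coalescence history. Each replicate is placed
on the absolute timescale by its own draw from the Poisson-Gamma clock
posterior, so clock uncertainty is part of the posterior spread.

Cohort decoding is a pure throughput concern: per-pair random streams
are derived from the master seed with a counter scheme, so batched and
one-pair-at-a-time decoding produce bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import MutationContextTensor
from .model import CoalescenceTransformer, SampleSizeAdapter, sample_trajectory
from .nn import autograd as ag
from .scenarios import TmrcaTrack
from .timescale import (DEFAULT_CLOCK_PRIOR, TimeDiscretization, clock_posterior,
                        sample_correction)

N_REPS_DEFAULT = 15
#: First/last fraction of windows flagged as boundary (context truncation).
BOUNDARY_FRAC = 0.05


@dataclass
class PosteriorTracks:
    """Replicate TMRCA trajectories for one pivot pair.

    ``times`` is (n_reps, K) in generations; ``ratios`` the raw model
    output before clock calibration; ``factors`` the per-replicate clock
    draws (absolute mean-TMRCA scale).
    """

    pivot: tuple[int, int]
    window_starts: np.ndarray
    window_bp: int
    times: np.ndarray  # (R, K)
    ratios: np.ndarray  # (R, K)
    factors: np.ndarray  # (R,)
    boundary: np.ndarray = field(default=None)  # (K,) bool

    def __post_init__(self):
        self.times = np.atleast_2d(np.asarray(self.times, dtype=np.float64))
        self.ratios = np.atleast_2d(np.asarray(self.ratios, dtype=np.float64))
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        if self.times.shape != self.ratios.shape or \
                self.times.shape[1] != len(self.window_starts):
            raise ValueError("replicate/window shapes inconsistent")
        if self.boundary is None:
            self.boundary = boundary_mask(len(self.window_starts))

    @property
    def n_reps(self) -> int:
        return self.times.shape[0]

    @property
    def n_windows(self) -> int:
        return self.times.shape[1]

    def to_track(self, stat: str = "gmean") -> TmrcaTrack:
        """Point-estimate track. The default, the geometric mean across
        replicates, is the Bayes point estimate under squared log error
        (the evaluation loss for log-binned times); arithmetic mean and
        median are also available."""
        if stat == "gmean":
            values = np.exp(np.mean(np.log(self.times), axis=0))
        elif stat == "mean":
            values = self.times.mean(axis=0)
        elif stat == "median":
            values = np.median(self.times, axis=0)
        else:
            raise ValueError(f"unknown stat {stat!r}")
        return TmrcaTrack(pivot=self.pivot, window_starts=self.window_starts,
                          values=values, window_bp=self.window_bp,
                          kind="predicted")


def boundary_mask(n_windows: int, frac: float = BOUNDARY_FRAC) -> np.ndarray:
    """True for the first/last `frac` of windows (truncated context)."""
    k = max(1, int(np.ceil(frac * n_windows))) if n_windows > 2 else 0
    mask = np.zeros(n_windows, dtype=bool)
    if k:
        mask[:k] = True
        mask[-k:] = True
    return mask


def _pair_rng(master_seed: int, pair_index: int) -> np.random.Generator:
    """Counter-scheme stream: identical for cohort and single-pair runs."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed),
                                                         int(pair_index)]))


def decode_pair(net: CoalescenceTransformer, mc: MutationContextTensor, mu: float,
                grid: TimeDiscretization, n_reps: int = N_REPS_DEFAULT,
                temperature: float = 1.0, seed: int = 0, pair_index: int = 0,
                adapter: SampleSizeAdapter | None = None,
                clock_prior: tuple[float, float] = DEFAULT_CLOCK_PRIOR) -> PosteriorTracks:
    """Sample `n_reps` calibrated TMRCA trajectories for one pivot pair."""
    return decode_cohort(net, [mc], mu, grid, n_reps=n_reps,
                         temperature=temperature, seed=seed,
                         first_pair_index=pair_index, batch_size=1,
                         adapter=adapter, clock_prior=clock_prior)[0]


def decode_cohort(net: CoalescenceTransformer, mcs: list[MutationContextTensor],
                  mu: float, grid: TimeDiscretization,
                  n_reps: int = N_REPS_DEFAULT, temperature: float = 1.0,
                  seed: int = 0, batch_size: int = 32, first_pair_index: int = 0,
                  adapter: SampleSizeAdapter | None = None,
                  clock_prior: tuple[float, float] = DEFAULT_CLOCK_PRIOR
                  ) -> list[PosteriorTracks]:
    """Decode many pivot pairs; batching never changes the results.

    Replicates of one pair are decoded as one batch; separate pairs are
    grouped up to `batch_size` trajectories per forward. Each pair's
    tokens and clock factors come from its own counter-derived stream.
    """
    if not mcs:
        return []
    K = net.config.n_windows
    for mc in mcs:
        if mc.scheme.n_windows != K or mc.scheme.n_freq != \
                (net.config.n_freq if adapter is None else adapter.config.source_n):
            raise ValueError("mutational-context dims do not match model/adapter")
    out: list[PosteriorTracks] = []
    pairs_per_batch = max(1, batch_size // n_reps)
    for lo in range(0, len(mcs), pairs_per_batch):
        chunk = mcs[lo:lo + pairs_per_batch]
        dens = np.concatenate([np.repeat(m.density[None], n_reps, axis=0)
                               for m in chunk], axis=0)
        acc = np.concatenate([np.repeat(m.accessibility[None], n_reps, axis=0)
                              for m in chunk], axis=0)
        if adapter is not None:
            with ag.no_grad():
                dens = adapter(dens).data
        rngs = [_pair_rng(seed, first_pair_index + lo + i) for i in range(len(chunk))]
        row_rngs = [rngs[i // n_reps] for i in range(len(chunk) * n_reps)]
        toks = sample_trajectory(net, dens, acc, rng=None, temperature=temperature,
                                 rngs_per_row=row_rngs)
        ratios_all = grid.decode(toks).reshape(len(chunk), n_reps, K)
        for i, mc in enumerate(chunk):
            post = clock_posterior(mc.xor_total, mc.accessible_bp, mu,
                                   prior=clock_prior)
            ratios = ratios_all[i]
            # correction factor = posterior draw / model-implied mean, so each
            # replicate's implied diversity matches a draw from the observed-
            # diversity posterior exactly
            draws = sample_correction(post, n_reps, rngs[i])
            factors = draws / ratios.mean(axis=1)
            times = ratios * factors[:, None]
            starts = np.arange(K, dtype=np.int64) * mc.scheme.window_bp
            pivot = mc.pivot if mc.pivot is not None else (0, 1)
            out.append(PosteriorTracks(pivot=pivot, window_starts=starts,
                                       window_bp=mc.scheme.window_bp,
                                       times=times, ratios=ratios,
                                       factors=factors))
    return out


def summarize(tracks: PosteriorTracks,
              levels: tuple[float, ...] = (0.5, 0.8, 0.95)) -> pd.DataFrame:
    """Per-window summary table: mean/median/variance + equal-tailed intervals."""
    if tracks.n_reps < 1:
        raise ValueError("need at least one replicate")
    t = tracks.times
    df = pd.DataFrame({
        "start": tracks.window_starts,
        "end": tracks.window_starts + tracks.window_bp,
        "mean": t.mean(axis=0),
        "median": np.median(t, axis=0),
        "variance": t.var(axis=0),
        "boundary": tracks.boundary,
    })
    for lv in levels:
        a = (1.0 - lv) / 2.0
        df[f"lo{int(round(lv * 100))}"] = np.quantile(t, a, axis=0)
        df[f"hi{int(round(lv * 100))}"] = np.quantile(t, 1.0 - a, axis=0)
    return df


def coverage_eval(tracks: PosteriorTracks | list[PosteriorTracks],
                  truth: TmrcaTrack | list[TmrcaTrack],
                  levels: tuple[float, ...] = (0.5, 0.8, 0.95)) -> pd.DataFrame:
    """Empirical coverage of equal-tailed replicate intervals against truth.

    Interior and boundary windows are tallied separately (context
    truncation degrades the edges). Returns one row per level.
    """
    tr_list = tracks if isinstance(tracks, list) else [tracks]
    th_list = truth if isinstance(truth, list) else [truth]
    if len(tr_list) != len(th_list):
        raise ValueError("one truth track per posterior track required")
    rows = []
    for lv in levels:
        a = (1.0 - lv) / 2.0
        hit_int, n_int, hit_bnd, n_bnd = 0, 0, 0, 0
        for tr, th in zip(tr_list, th_list):
            if tr.n_windows != th.n_windows or \
                    not np.array_equal(tr.window_starts, th.window_starts):
                raise ValueError("window grids do not match")
            lo = np.quantile(tr.times, a, axis=0)
            hi = np.quantile(tr.times, 1.0 - a, axis=0)
            vals = np.atleast_2d(th.values)[0]
            ok = np.isfinite(vals)
            hit = (vals >= lo) & (vals <= hi) & ok
            b = tr.boundary
            hit_int += int(hit[~b & ok].sum())
            n_int += int((~b & ok).sum())
            hit_bnd += int(hit[b & ok].sum())
            n_bnd += int((b & ok).sum())
        rows.append(dict(level=lv,
                         interior=hit_int / n_int if n_int else np.nan,
                         boundary=hit_bnd / n_bnd if n_bnd else np.nan,
                         overall=(hit_int + hit_bnd) / (n_int + n_bnd)
                         if (n_int + n_bnd) else np.nan,
                         n_interior=n_int, n_boundary=n_bnd))
    return pd.DataFrame(rows)
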