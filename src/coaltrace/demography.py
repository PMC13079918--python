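"""From TMRCA samples to coalescence rates and Ne trajectories.

Treating windowed pairwise TMRCAs as event times of a coalescence
process, the instantaneous rate lambda(t) is estimated per interval of a
logarithmic time grid with the discrete-exposure (actuarial) hazard:

    lambda_k = (# events in interval k) / total exposure time in k,

where each sample contributes exposure min(T, end_k) - start_k to every
interval it survives into. For a panmictic population the trajectory of
effective size follows by inversion, Ne(t) = 1 / (2 lambda(t)). The tail
interval is open-ended (all remaining exposure accrues there).

The same estimator, applied to true TMRCAs point-sampled every window,
gives the "inference limit": the accuracy ceiling any method faces under
matched discretization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenarios import SimReplicate, TmrcaTrack, true_tmrca_track

#: Default rate grid: 32 log intervals over [10, 1e7] generations.
GRID_N_DEFAULT = 32
GRID_T_MIN = 10.0
GRID_T_MAX = 1e7
#: Minimum coalescence events for an interval's Ne to be reported.
MIN_SUPPORT_DEFAULT = 20


def default_grid(n_intervals: int = GRID_N_DEFAULT, t_min: float = GRID_T_MIN,
                 t_max: float = GRID_T_MAX) -> np.ndarray:
    return np.geomspace(t_min, t_max, n_intervals + 1)


@dataclass
class RateCurve:
    """Instantaneous coalescence rate on a log time grid."""

    grid: np.ndarray  # (n+1,) interval boundaries, generations
    lam: np.ndarray  # (n,) hazard per generation
    n_events: np.ndarray  # (n,)
    exposure: np.ndarray  # (n,) generations of exposure
    min_support: int = MIN_SUPPORT_DEFAULT

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.lam < 0):
            raise ValueError("hazard must be nonnegative")

    @property
    def supported(self) -> np.ndarray:
        return (self.n_events >= self.min_support) & (self.lam > 0)

    @property
    def ne(self) -> np.ndarray:
        """Per-interval Ne(t) = 1/(2 lambda); unsupported intervals NaN."""
        out = np.full_like(self.lam, np.nan)
        ok = self.supported
        out[ok] = 1.0 / (2.0 * self.lam[ok])
        return out

    def harmonic_mean_ne(self) -> float:
        """Exposure-weighted harmonic mean of Ne over supported intervals."""
        ok = self.supported
        if not ok.any():
            return np.nan
        w = self.exposure[ok]
        return float(w.sum() / np.sum(w * 2.0 * self.lam[ok]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(t_lo=self.grid[:-1], t_hi=self.grid[1:],
                                 lam=self.lam, ne=self.ne,
                                 n_events=self.n_events, exposure=self.exposure))


def coalescence_rate(samples: np.ndarray, grid: np.ndarray | None = None,
                     min_support: int = MIN_SUPPORT_DEFAULT) -> RateCurve:
    """Exposure-time hazard estimate of the coalescence rate.

    `samples` are TMRCA values in generations (NaN entries dropped).
    Samples older than the grid accrue exposure in the open-ended tail
    interval; samples younger than the grid are clipped to its start.
    """
    samples = np.asarray(samples, dtype=np.float64).ravel()
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        raise ValueError("no TMRCA samples")
    if np.any(samples <= 0):
        raise ValueError("TMRCA samples must be positive")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=np.float64)
    t = np.clip(samples, grid[0] * (1 + 1e-12), None)
    lo = grid[:-1][None, :]
    hi = grid[1:][None, :].copy()
    hi_open = hi.copy()
    hi_open[0, -1] = np.inf  # tail interval open-ended
    exposure = np.clip(np.minimum(t[:, None], hi_open) - lo, 0.0, None).sum(axis=0)
    idx = np.clip(np.searchsorted(grid, t, side="right") - 1, 0, len(grid) - 2)
    n_events = np.bincount(idx, minlength=len(grid) - 1).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(exposure > 0, n_events / np.where(exposure > 0, exposure, 1.0), 0.0)
    return RateCurve(grid=grid, lam=lam, n_events=n_events, exposure=exposure,
                     min_support=min_support)


def ne_trajectory(rc: RateCurve) -> pd.DataFrame:
    """Per-interval Ne(t); intervals under the support floor are masked."""
    df = rc.to_frame()
    return df[["t_lo", "t_hi", "ne", "n_events"]]


def cross_coalescence(samples_by_pair_type: dict[str, np.ndarray],
                      grid: np.ndarray | None = None,
                      min_support: int = MIN_SUPPORT_DEFAULT) -> dict[str, RateCurve]:
    """Hazard curves per pair type (e.g. within_A / within_B / cross).

    All curves share one grid, so within- and cross-deme rates are
    directly comparable; a cross rate near zero at recent times is the
    signature of an unadmixed split.
    """
    if not samples_by_pair_type:
        raise ValueError("no pair types given")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=np.float64)
    return {k: coalescence_rate(v, grid, min_support=min_support)
            for k, v in samples_by_pair_type.items()}


def pair_type_label(demes: np.ndarray, pivot: tuple[int, int]) -> str:
    """within_<deme> or cross, from per-haplotype deme labels."""
    a, b = demes[pivot[0]], demes[pivot[1]]
    return f"within_{a}" if a == b else "cross"


def inference_limit(rep: SimReplicate, pivots: list[tuple[int, int]],
                    grid: np.ndarray | None = None, window_bp: int | None = None,
                    min_support: int = MIN_SUPPORT_DEFAULT) -> RateCurve:
    """The matched-discretization accuracy ceiling.

    Point-samples the *true* TMRCAs every `window_bp` (default 2 kb) for
    the given pivot pairs and feeds them through the identical
    `coalescence_rate` estimator used for model predictions.
    """
    window_bp = rep.config.window_bp if window_bp is None else window_bp
    samples = [true_tmrca_track(rep, p, window_bp=window_bp, mode="point").values
               for p in pivots]
    return coalescence_rate(np.concatenate(samples), grid, min_support=min_support)


# ---------------------------------------------------------------------------
# evaluation metrics


def mse_log(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared error of natural-log TMRCAs over matched windows."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=np.float64).ravel()
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth shapes differ")
    ok = np.isfinite(pred) & np.isfinite(truth)
    return float(np.mean((np.log(pred[ok]) - np.log(truth[ok])) ** 2))


def kl_marginal(pred: np.ndarray, truth: np.ndarray, bins: np.ndarray | None = None,
                smoothing: float = 0.5) -> float:
    """KL(truth || pred) between binned marginal TMRCA distributions.

    Shared log-spaced bins; additive smoothing keeps zero-support bins
    finite.
    """
    pred = np.asarray(pred, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=np.float64).ravel()
    pred, truth = pred[np.isfinite(pred)], truth[np.isfinite(truth)]
    if bins is None:
        allv = np.concatenate([pred, truth])
        bins = np.geomspace(allv.min() * 0.999, allv.max() * 1.001, 33)
    cp, _ = np.histogram(pred, bins=bins)
    ct, _ = np.histogram(truth, bins=bins)
    p = (ct + smoothing) / (ct + smoothing).sum()  # truth
    q = (cp + smoothing) / (cp + smoothing).sum()  # prediction
    return float(np.sum(p * np.log(p / q)))


def metrics(pred: TmrcaTrack | np.ndarray, truth: TmrcaTrack | np.ndarray,
            bins: np.ndarray | None = None) -> dict[str, float]:
    """{mse_log, kl_marginal} between predicted and true tracks."""
    pv = pred.values if isinstance(pred, TmrcaTrack) else np.asarray(pred)
    tv = truth.values if isinstance(truth, TmrcaTrack) else np.asarray(truth)
    pv2, tv2 = np.atleast_2d(pv), np.atleast_2d(tv)
    if pv2.shape[-1] != tv2.shape[-1]:
        raise ValueError("window grids do not match")
    # replicate axes broadcast: compare each replicate to the truth
    tvb = np.broadcast_to(tv2, (pv2.shape[0], tv2.shape[-1]))
    return dict(mse_log=mse_log(pv2, tvb), kl_marginal=kl_marginal(pv2, tv2, bins))
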