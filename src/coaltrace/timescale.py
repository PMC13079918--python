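"""Log-scale time discretization and the Poisson-Gamma molecular clock.

Coalescence times are tokenized on a log-uniform grid of 324 bins. The
model itself works on the dimensionless ratio t / T-bar, where T-bar is
the diversity-implied mean pairwise TMRCA of the context window: under a
Poisson mutation model the pivot pair's heterozygous-site count S over an
accessible length L satisfies S ~ Poisson(2 * mu * L * T-bar), so a
Gamma(a0, b0) prior on T-bar yields the conjugate posterior
Gamma(a0 + S, b0 + 2 * mu * L). Decoded ratio trajectories are rescaled
by per-replicate posterior draws of T-bar, which restores absolute time
and propagates clock uncertainty into every replicate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

N_BINS_DEFAULT = 324
#: Default absolute-time grid span (generations).
T_MIN_DEFAULT = 10.0
T_MAX_DEFAULT = 1e8
#: Default span for the dimensionless ratio grid used by the model. The
#: ratio t / T-bar of an exponential coalescent has negligible mass above
#: ~20 x its mean, so the grid allots more room below 1 than above.
RATIO_MIN_DEFAULT = 1e-3
RATIO_MAX_DEFAULT = 1e2

#: Weak default prior (a0, b0): calibration is data-dominated.
DEFAULT_CLOCK_PRIOR = (1.0, 1e-9)


@dataclass(frozen=True)
class TimeDiscretization:
    """Log-uniform binning of positive times (or time ratios).

    The first and last bins are open-ended on encode: values outside
    [t_min, t_max] clamp to the end bins (with a logged warning).
    """

    edges: np.ndarray  # (n_bins + 1,) strictly increasing
    n_bins: int = field(default=N_BINS_DEFAULT)

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.float64)
        object.__setattr__(self, "edges", edges)
        if len(edges) != self.n_bins + 1:
            raise ValueError("n_bins must equal len(edges) - 1")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("edges must be strictly increasing")
        if edges[0] <= 0:
            raise ValueError("edges must be positive")

    @classmethod
    def log_uniform(cls, n_bins: int = N_BINS_DEFAULT, t_min: float = T_MIN_DEFAULT,
                    t_max: float = T_MAX_DEFAULT) -> "TimeDiscretization":
        if not 0 < t_min < t_max:
            raise ValueError("need 0 < t_min < t_max")
        edges = np.geomspace(t_min, t_max, n_bins + 1)
        return cls(edges=edges, n_bins=n_bins)

    @classmethod
    def ratio_grid(cls, n_bins: int = N_BINS_DEFAULT) -> "TimeDiscretization":
        return cls.log_uniform(n_bins, RATIO_MIN_DEFAULT, RATIO_MAX_DEFAULT)

    @property
    def representative(self) -> np.ndarray:
        """Geometric midpoint of each bin."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def encode(self, t) -> np.ndarray:
        """Map positive times to bin indices; out-of-range values clamp."""
        t = np.asarray(t, dtype=np.float64)
        if np.any(t <= 0) or np.any(~np.isfinite(t)):
            raise ValueError("times must be positive and finite")
        n_clamped = int(np.sum((t < self.edges[0]) | (t >= self.edges[-1])))
        if n_clamped:
            logger.warning("%d value(s) outside [%g, %g); clamped to end bins",
                           n_clamped, self.edges[0], self.edges[-1])
        idx = np.searchsorted(self.edges, t, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)

    def decode(self, idx) -> np.ndarray:
        idx = np.asarray(idx)
        if np.any(idx < 0) or np.any(idx >= self.n_bins):
            raise ValueError(f"bin index outside [0, {self.n_bins})")
        return self.representative[idx]

    def to_json(self) -> str:
        return json.dumps({"n_bins": self.n_bins, "edges": self.edges.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "TimeDiscretization":
        d = json.loads(s)
        return cls(edges=np.asarray(d["edges"]), n_bins=int(d["n_bins"]))


@dataclass(frozen=True)
class ClockPosterior:
    """Gamma posterior over the context's mean pairwise TMRCA scale."""

    shape: float
    rate: float
    observed_sites: int
    effective_length: float
    mu: float

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("Gamma posterior requires shape > 0 and rate > 0")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed credible interval for the mean-TMRCA scale."""
        from scipy.stats import gamma as gamma_dist
        a = (1.0 - level) / 2.0
        lo, hi = gamma_dist.ppf([a, 1.0 - a], self.shape, scale=1.0 / self.rate)
        return float(lo), float(hi)


def clock_posterior(S: int, L: float, mu: float,
                    prior: tuple[float, float] = DEFAULT_CLOCK_PRIOR) -> ClockPosterior:
    """Conjugate update: Gamma(a0 + S, b0 + 2 mu L) over mean pairwise TMRCA."""
    if L <= 0:
        raise ValueError("effective length must be positive (fully masked context?)")
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if S < 0:
        raise ValueError("site count must be nonnegative")
    a0, b0 = prior
    return ClockPosterior(shape=a0 + S, rate=b0 + 2.0 * mu * L,
                          observed_sites=int(S), effective_length=float(L), mu=float(mu))


def sample_correction(post: ClockPosterior, n_reps: int, seed: int | np.random.Generator,
                      model_implied_mean: float = 1.0) -> np.ndarray:
    """Per-replicate multiplicative clock factors: Gamma draws / implied mean.

    With ratio-space tracks the model-implied mean is 1, so the factors are
    posterior draws of the absolute mean-TMRCA scale itself.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.gamma(shape=post.shape, scale=1.0 / post.rate, size=n_reps)
    return draws / model_implied_mean


def diversity_intercept(S: int, L: float, mu: float,
                        prior: tuple[float, float] = DEFAULT_CLOCK_PRIOR) -> float:
    """Posterior-mean T-bar of a context; the centering scale for labels."""
    return clock_posterior(S, L, mu, prior).mean
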