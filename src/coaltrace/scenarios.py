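"""Scenario registry and coalescent-simulation engine.

Scenarios are simulation recipes (demography, per-bp rates, length, sample
size) from which training and evaluation data are generated with msprime.
Each simulated replicate carries the tree sequence so that ground-truth
windowed pairwise TMRCA labels can be extracted exactly.

Registry notes
--------------
``narrow_constant`` is the benchmark world: a constant diploid population
of Ne = 20,000 with equal mutation and recombination rates (1e-8 per bp
per generation) and 2 kb windows. ``vaquita`` (Phocoena sinus) and
``gorilla`` carry published per-bp rates (vaquita m = 5.83e-9, r = 1e-8,
Ne = 3,500; gorilla m = 1.235e-8, r = 1.193e-8). The gorilla Ne (25,000)
and the sus_scrofa / rattus_norvegicus rates are nominal catalog-style
placeholders, flagged in their entries; only their Ne values (270,000 and
124,000) are published.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import msprime
import numpy as np
import tskit

WINDOW_BP_DEFAULT = 2_000


@dataclass(frozen=True)
class ScenarioConfig:
    """A simulation recipe: everything needed to regenerate a dataset."""

    name: str
    diploid_n: int = 25
    Ne: float = 20_000.0
    demography: str | None = None  # None => constant size Ne
    demography_params: tuple = ()  # sorted (key, value) pairs
    mu: float = 1e-8
    rec: float = 1e-8
    seq_length: int = 1_000_000
    window_bp: int = WINDOW_BP_DEFAULT
    seed: int = 1

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mutation rate must be positive")
        if self.rec < 0:
            raise ValueError("recombination rate must be nonnegative")
        if self.seq_length <= 0:
            raise ValueError("sequence length must be positive")
        if self.window_bp <= 0 or self.seq_length % self.window_bp:
            raise ValueError("seq_length must be a positive multiple of window_bp")
        if self.diploid_n < 2:
            raise ValueError("need at least 2 diploid individuals")
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")

    @property
    def n_windows(self) -> int:
        return self.seq_length // self.window_bp

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.diploid_n

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)

    def demography_param_dict(self) -> dict:
        return dict(self.demography_params)


@dataclass
class SimReplicate:
    """One simulated replicate: genotypes, positions and the genealogy."""

    genotypes: np.ndarray  # (2N, M) binary
    positions: np.ndarray  # (M,) bp, ascending
    genealogy: tskit.TreeSequence
    config: ScenarioConfig
    seed: int
    sample_demes: np.ndarray | None = None  # per-haplotype deme label
    mask: np.ndarray | None = None  # (m, 2) inaccessible intervals, if applied

    def __post_init__(self):
        g = np.asarray(self.genotypes)
        if g.ndim != 2 or g.shape[0] != self.config.n_haplotypes:
            raise ValueError("genotypes must be (2N, M)")
        if not np.isin(g, (0, 1)).all():
            raise ValueError("genotype entries must be binary")
        pos = np.asarray(self.positions, dtype=np.float64)
        if len(pos) != g.shape[1]:
            raise ValueError("positions must match genotype columns")
        if len(pos) and (np.any(np.diff(pos) <= 0) or pos[0] < 0 or
                         pos[-1] >= self.config.seq_length):
            raise ValueError("positions must be strictly increasing within [0, seq_length)")


@dataclass
class TmrcaTrack:
    """Per-window coalescence times for one pivot pair (generations).

    ``values`` has shape (n_windows,) or (n_reps, n_windows). Masked or
    edge-truncated windows may be NaN in mean mode.
    """

    pivot: tuple[int, int]
    window_starts: np.ndarray
    values: np.ndarray
    window_bp: int
    kind: Literal["true_mean", "true_point", "predicted"] = "true_mean"

    def __post_init__(self):
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        vals = np.atleast_2d(self.values)
        if vals.shape[-1] != len(self.window_starts):
            raise ValueError("one value per window (per replicate) required")
        finite = vals[np.isfinite(vals)]
        if finite.size and np.any(finite <= 0):
            raise ValueError("coalescence times must be positive")

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)


# ---------------------------------------------------------------------------
# demography builders


def sawtooth_demography(n0: float = 20_000.0, amplitude: float = 10.0,
                        n_cycles: int = 4, t_min: float = 1e2, t_max: float = 1e6,
                        steps_per_cycle: int = 16) -> msprime.Demography:
    """Piecewise-constant log-time sinusoid: Ne oscillates `amplitude`-fold.

    max/min Ne ratio equals `amplitude`; oscillation spans n_cycles full
    periods between t_min and t_max generations; older than t_max the size
    is held at n0. A misspecification stressor, not a biological model.
    """
    demog = msprime.Demography()
    half_log_amp = 0.5 * np.log10(amplitude)
    demog.add_population(name="pop_0", initial_size=n0)  # phase 0 => sin = 0
    n_steps = n_cycles * steps_per_cycle
    ts_grid = np.geomspace(t_min, t_max, n_steps)
    phases = n_cycles * 2 * np.pi * np.linspace(0, 1, n_steps, endpoint=False)
    for t, ph in zip(ts_grid, phases):
        size = n0 * 10 ** (half_log_amp * np.sin(ph))
        demog.add_population_parameters_change(time=t, initial_size=size, population="pop_0")
    demog.add_population_parameters_change(time=t_max, initial_size=n0, population="pop_0")
    return demog


def two_deme_demography(ne: float = 20_000.0, split_time: float = 30_000.0,
                        migration: float = 0.0) -> msprime.Demography:
    """Two demes of size `ne` merging into an ancestral deme at `split_time`."""
    demog = msprime.Demography()
    demog.add_population(name="deme_A", initial_size=ne)
    demog.add_population(name="deme_B", initial_size=ne)
    demog.add_population(name="ancestral", initial_size=ne)
    if migration > 0:
        demog.set_symmetric_migration_rate(["deme_A", "deme_B"], migration)
    demog.add_population_split(time=split_time, derived=["deme_A", "deme_B"],
                               ancestral="ancestral")
    return demog


def _build_msprime_demography(config: ScenarioConfig) -> msprime.Demography | None:
    if config.demography is None:
        return None
    params = config.demography_param_dict()
    if config.demography == "sawtooth":
        return sawtooth_demography(n0=config.Ne, **params)
    if config.demography == "two_deme":
        return two_deme_demography(ne=config.Ne, **params)
    raise ValueError(f"unknown demography kind {config.demography!r}")


# ---------------------------------------------------------------------------
# registry

_REGISTRY: dict[str, dict] = {
    # benchmark world: constant Ne = 2e4, mu = rec
    "narrow_constant": dict(Ne=20_000.0, mu=1e-8, rec=1e-8, window_bp=2_000),
    # high-Ne variant inferred at 200 bp windows
    "high_ne_constant": dict(Ne=200_000.0, mu=1e-8, rec=1e-8, window_bp=200),
    "sawtooth": dict(Ne=20_000.0, mu=1e-8, rec=1e-8, window_bp=2_000,
                     demography="sawtooth"),
    "two_deme_split": dict(Ne=20_000.0, mu=1e-8, rec=1e-8, window_bp=2_000,
                           demography="two_deme"),
    # catalog-style species entries; rates as published where available
    "vaquita": dict(Ne=3_500.0, mu=5.83e-9, rec=1e-8, window_bp=2_000),
    "gorilla": dict(Ne=25_000.0, mu=1.235e-8, rec=1.193e-8, window_bp=2_000),
    # published Ne only; rates nominal
    "sus_scrofa": dict(Ne=270_000.0, mu=1e-8, rec=1e-8, window_bp=2_000),
    "rattus_norvegicus": dict(Ne=124_000.0, mu=1e-8, rec=1e-8, window_bp=2_000),
}


def scenario_names() -> list[str]:
    return sorted(_REGISTRY)


def build_scenario(spec: str | dict, **overrides) -> ScenarioConfig:
    """Resolve a named registry entry (or explicit parameter dict) to a config."""
    if isinstance(spec, str):
        if spec not in _REGISTRY:
            raise KeyError(f"unknown scenario {spec!r}; known: {scenario_names()}")
        params = dict(_REGISTRY[spec], name=spec)
    else:
        params = dict(spec)
        params.setdefault("name", "custom")
    params.update(overrides)
    if "demography_params" in params and isinstance(params["demography_params"], dict):
        params["demography_params"] = tuple(sorted(params["demography_params"].items()))
    return ScenarioConfig(**params)


# ---------------------------------------------------------------------------
# simulation


def simulate(config: ScenarioConfig, seed: int | None = None) -> SimReplicate:
    """Run a coalescent-with-recombination simulation under `config`.

    Deterministic given (config, seed). For multi-deme demographies the
    haplotypes get random deme assignments (drawn from the same seed), so
    training examples mix deme compositions.
    """
    seed = int(config.seed if seed is None else seed)
    if seed < 1:
        raise ValueError("msprime seeds must be >= 1")
    demog = _build_msprime_demography(config)
    rng = np.random.default_rng(seed)
    sample_demes = None
    if demog is None:
        samples: object = config.diploid_n
        kwargs = dict(population_size=config.Ne)
    elif config.demography == "two_deme":
        deme_of_ind = rng.integers(0, 2, size=config.diploid_n)
        n_a = int((deme_of_ind == 0).sum())
        samples = {"deme_A": n_a, "deme_B": config.diploid_n - n_a}
        # haplotype order follows population order, not draw order
        order = np.argsort(deme_of_ind, kind="stable")
        sample_demes = np.repeat(deme_of_ind[order], 2)
        kwargs = dict(demography=demog)
    else:
        samples = {demog.populations[0].name: config.diploid_n}
        kwargs = dict(demography=demog)

    try:
        ts = msprime.sim_ancestry(
            samples=samples,
            sequence_length=config.seq_length,
            recombination_rate=config.rec,
            random_seed=seed,
            **kwargs,
        )
        ts = msprime.sim_mutations(ts, rate=config.mu, random_seed=seed + 1,
                                   model=msprime.BinaryMutationModel())
    except Exception as exc:  # pragma: no cover - backend failure path
        raise RuntimeError(f"simulation failed for scenario {config.name!r} "
                           f"(seed {seed}): {exc}") from exc
    genotypes = ts.genotype_matrix().T.astype(np.uint8)
    positions = ts.tables.sites.position.copy()
    return SimReplicate(genotypes=genotypes, positions=positions, genealogy=ts,
                        config=config, seed=seed, sample_demes=sample_demes)


def pair_tmrca_segments(ts: tskit.TreeSequence, pivot: tuple[int, int]):
    """(left, right, tmrca) arrays of constant-TMRCA segments for one pair.

    Segments where the pair does not fully coalesce (e.g. deleted
    intervals) carry NaN.
    """
    a, b = pivot
    simp = ts.simplify(samples=[a, b], filter_sites=True)
    lefts, rights, times = [], [], []
    for tree in simp.trees():
        lefts.append(tree.interval.left)
        rights.append(tree.interval.right)
        if tree.num_roots == 1:
            times.append(tree.time(tree.root))
        else:
            times.append(np.nan)
    return (np.asarray(lefts), np.asarray(rights), np.asarray(times))


def true_tmrca_track(rep: SimReplicate, pivot: tuple[int, int],
                     window_bp: int | None = None,
                     mode: Literal["mean", "point"] = "mean") -> TmrcaTrack:
    """Ground-truth windowed TMRCA labels for one pivot pair.

    mode="mean" (training label default): span-weighted average pairwise
    TMRCA over the marginal trees intersecting each window.
    mode="point" (inference-limit baseline): the TMRCA of the marginal
    tree at each window start.
    """
    cfg = rep.config
    window_bp = cfg.window_bp if window_bp is None else int(window_bp)
    if window_bp <= 0 or cfg.seq_length % window_bp:
        raise ValueError("window_bp must divide seq_length")
    n_hap = cfg.n_haplotypes
    a, b = pivot
    if not (0 <= a < n_hap and 0 <= b < n_hap) or a == b:
        raise ValueError(f"pivot {pivot} out of range for 2N={n_hap}")
    n_win = cfg.seq_length // window_bp
    starts = np.arange(n_win, dtype=np.int64) * window_bp
    left, right, tmrca = pair_tmrca_segments(rep.genealogy, pivot)

    if mode == "point":
        idx = np.searchsorted(right, starts, side="right")
        idx = np.clip(idx, 0, len(tmrca) - 1)
        values = tmrca[idx]
    elif mode == "mean":
        values = np.full(n_win, np.nan)
        for k, s in enumerate(starts):
            e = s + window_bp
            lo = np.searchsorted(right, s, side="right")
            hi = np.searchsorted(left, e, side="left")
            seg_l = np.maximum(left[lo:hi], s)
            seg_r = np.minimum(right[lo:hi], e)
            seg_t = tmrca[lo:hi]
            span = seg_r - seg_l
            ok = np.isfinite(seg_t) & (span > 0)
            if ok.any():
                values[k] = np.average(seg_t[ok], weights=span[ok])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    kind = "true_mean" if mode == "mean" else "true_point"
    return TmrcaTrack(pivot=(a, b), window_starts=starts, values=values,
                      window_bp=window_bp, kind=kind)


def validate_mask(mask: np.ndarray, seq_length: int) -> np.ndarray:
    """Validate (m, 2) half-open intervals: sorted, disjoint, in range."""
    mask = np.asarray(mask, dtype=np.float64).reshape(-1, 2)
    if len(mask) == 0:
        return mask
    if np.any(mask[:, 0] >= mask[:, 1]):
        raise ValueError("mask intervals must have start < end")
    if np.any(mask[:, 0] < 0) or np.any(mask[:, 1] > seq_length):
        raise ValueError("mask intervals must lie within [0, seq_length)")
    order = np.argsort(mask[:, 0])
    mask = mask[order]
    if np.any(mask[1:, 0] < mask[:-1, 1]):
        raise ValueError("mask intervals must not overlap")
    return mask


def apply_accessibility(rep: SimReplicate, mask: np.ndarray) -> SimReplicate:
    """Delete inaccessible intervals from the genealogy and its mutations.

    Coordinates of retained material are preserved (windows keep their
    original positions; masked spans simply contribute no sites).
    """
    mask = validate_mask(mask, rep.config.seq_length)
    if len(mask) == 0:
        return rep
    ts = rep.genealogy.delete_intervals(mask, simplify=False)
    genotypes = ts.genotype_matrix().T.astype(np.uint8)
    positions = ts.tables.sites.position.copy()
    return SimReplicate(genotypes=genotypes, positions=positions, genealogy=ts,
                        config=rep.config, seed=rep.seed,
                        sample_demes=rep.sample_demes, mask=mask)


def within_individual_pivots(diploid_n: int) -> list[tuple[int, int]]:
    """The N (2i, 2i+1) pivot pairs: one per diploid, no phasing needed."""
    return [(2 * i, 2 * i + 1) for i in range(diploid_n)]
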