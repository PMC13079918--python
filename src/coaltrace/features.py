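"""Mutational-context featurization.

For a chosen pivot pair of haplotypes, every segregating site is split
into two logical channels: XOR (the pivot haplotypes differ -- the site is
heterozygous in the pair) and XNOR (they agree). Each site also carries a
site-frequency class: the derived-allele count among the 2N-2 non-pivot
haplotypes (optionally folded to minor-allele counts when ancestral
states are unknown). Sites are then histogrammed by (channel, frequency
class) in windows of geometrically increasing span centered on a fixed
2 kb base stride, giving the multi-scale mutational-context tensor the
model consumes. Counts are stored raw; the model sees per-kb densities so
the same weights serve 2 kb and 200 bp window configurations.

An accessibility channel records, per scale and window, the fraction of
the window that is uncallable (masked intervals plus out-of-sequence
truncation at the edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scenarios import SimReplicate, validate_mask

#: Scale multipliers relative to the base window (2 kb base => 2..128 kb,
#: plus the base window itself as scale 0).
SCALE_MULTIPLIERS_DEFAULT = (1, 2, 4, 8, 16, 32, 64)


@dataclass(frozen=True)
class WindowScheme:
    """Multi-scale windowing: base stride plus centered wider scales."""

    seq_length: int
    window_bp: int
    scale_multipliers: tuple[int, ...] = SCALE_MULTIPLIERS_DEFAULT
    n_freq: int = 49  # frequency-class channels (2N-2+1 for N=25 diploids)
    folded: bool = False

    def __post_init__(self):
        if self.seq_length <= 0 or self.window_bp <= 0:
            raise ValueError("lengths must be positive")
        if self.seq_length % self.window_bp:
            raise ValueError("seq_length must be a multiple of window_bp")
        if self.n_freq < 1:
            raise ValueError("need at least one frequency class")
        if any(m < 1 for m in self.scale_multipliers):
            raise ValueError("scale multipliers must be >= 1")

    @property
    def n_windows(self) -> int:
        return self.seq_length // self.window_bp

    @property
    def n_scales(self) -> int:
        return len(self.scale_multipliers)

    def bounds(self, scale_idx: int) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) bp bounds per window at one scale, centered on the base
        windows; may extend past [0, seq_length) (truncation is recorded in
        the accessibility channel, not clipped here)."""
        m = self.scale_multipliers[scale_idx]
        centers = (np.arange(self.n_windows) + 0.5) * self.window_bp
        half = 0.5 * m * self.window_bp
        return centers - half, centers + half

    @classmethod
    def for_cohort(cls, seq_length: int, window_bp: int, diploid_n: int,
                   folded: bool = False, **kw) -> "WindowScheme":
        return cls(seq_length=seq_length, window_bp=window_bp,
                   n_freq=2 * diploid_n - 2 + 1, folded=folded, **kw)


@dataclass
class SiteFeatures:
    """Per-site pivot-pair logical channels and frequency classes."""

    xor: np.ndarray  # (M,) 1 iff pivot haplotypes differ
    xnor: np.ndarray  # (M,) complement
    freq_class: np.ndarray  # (M,) derived (or minor) count among non-pivot rows
    n_other: int  # 2N - 2

    def __post_init__(self):
        if not np.array_equal(self.xor + self.xnor, np.ones_like(self.xor)):
            raise ValueError("xor + xnor must equal 1 at every site")
        if np.any(self.freq_class < 0) or np.any(self.freq_class > self.n_other):
            raise ValueError("frequency class outside [0, 2N-2]")


@dataclass
class MutationContextTensor:
    """SFS-partitioned multi-scale windowed features for one pivot pair.

    ``counts`` is indexed (Z, WS, K, N): Z=2 logical channels (0=XOR,
    1=XNOR), WS scales, K windows, N frequency classes. ``accessibility``
    is the inaccessible fraction per (WS, K). The scalars needed by the
    molecular clock travel with the tensor: the pivot pair's total
    heterozygous-site count and the accessible bp of the context.
    """

    counts: np.ndarray  # (2, WS, K, N) int32
    accessibility: np.ndarray  # (WS, K) float32 in [0, 1]
    scheme: WindowScheme
    xor_total: int
    accessible_bp: float
    pivot: tuple[int, int] | None = None

    def __post_init__(self):
        z, ws, k, n = self.counts.shape
        if z != 2 or ws != self.scheme.n_scales or k != self.scheme.n_windows \
                or n != self.scheme.n_freq:
            raise ValueError("tensor shape inconsistent with scheme")
        if self.accessibility.shape != (ws, k):
            raise ValueError("accessibility channel shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def density(self) -> np.ndarray:
        """Counts normalized to sites per kb of nominal window span."""
        spans_kb = np.asarray(self.scheme.scale_multipliers, dtype=np.float32) \
            * self.scheme.window_bp / 1000.0
        return self.counts.astype(np.float32) / spans_kb[None, :, None, None]


def pivot_site_features(G: np.ndarray, pivot: tuple[int, int],
                        folded: bool = False) -> SiteFeatures:
    """XOR/XNOR channels and non-pivot frequency classes for each site."""
    G = np.asarray(G)
    if not np.isin(G, (0, 1)).all():
        raise ValueError("genotype matrix must be binary (biallelic sites only)")
    n_hap = G.shape[0]
    a, b = pivot
    if not (0 <= a < n_hap and 0 <= b < n_hap) or a == b:
        raise ValueError(f"pivot {pivot} invalid for {n_hap} haplotypes")
    xor = (G[a] ^ G[b]).astype(np.int64)
    others = np.delete(np.arange(n_hap), [a, b])
    freq = G[others].sum(axis=0).astype(np.int64)
    if folded:
        freq = np.minimum(freq, len(others) - freq)
    return SiteFeatures(xor=xor, xnor=1 - xor, freq_class=freq, n_other=len(others))


def accessibility_channel(mask: np.ndarray | None, scheme: WindowScheme) -> np.ndarray:
    """Inaccessible fraction per (scale, window).

    Includes both masked intervals and the out-of-sequence truncation of
    wide scales at the chromosome edges.
    """
    mask = np.zeros((0, 2)) if mask is None else validate_mask(mask, scheme.seq_length)
    frac = np.zeros((scheme.n_scales, scheme.n_windows), dtype=np.float32)
    for s in range(scheme.n_scales):
        lo, hi = scheme.bounds(s)
        span = hi - lo
        # out-of-sequence truncation
        outside = np.maximum(0.0, -lo) + np.maximum(0.0, hi - scheme.seq_length)
        # masked overlap, vectorized over intervals
        masked = np.zeros_like(lo)
        for m_lo, m_hi in mask:
            masked += np.maximum(
                0.0, np.minimum(hi, m_hi) - np.maximum(lo, m_lo))
        frac[s] = np.clip((outside + masked) / span, 0.0, 1.0)
    return frac


def window_tensor(sf: SiteFeatures, positions: np.ndarray, scheme: WindowScheme,
                  mask: np.ndarray | None = None,
                  pivot: tuple[int, int] | None = None) -> MutationContextTensor:
    """Histogram sites into the (Z, WS, K, N) mutational-context tensor."""
    positions = np.asarray(positions, dtype=np.float64)
    if len(positions) and np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    if len(positions) != len(sf.xor):
        raise ValueError("positions must match site features")
    n_freq = scheme.n_freq
    freq = np.minimum(sf.freq_class, n_freq - 1)  # class capping for big cohorts
    counts = np.zeros((2, scheme.n_scales, scheme.n_windows, n_freq), dtype=np.int32)
    # joint code per site: channel * n_freq + class, histogrammed per window
    code = (1 - sf.xor) * n_freq + freq
    n_code = 2 * n_freq
    for s in range(scheme.n_scales):
        lo, hi = scheme.bounds(s)
        i0 = np.searchsorted(positions, lo, side="left")
        i1 = np.searchsorted(positions, hi, side="left")
        for k in range(scheme.n_windows):
            if i1[k] > i0[k]:
                c = np.bincount(code[i0[k]:i1[k]], minlength=n_code)
                counts[0, s, k] = c[:n_freq]
                counts[1, s, k] = c[n_freq:]
    access = accessibility_channel(mask, scheme)
    mask_bp = 0.0 if mask is None else float(np.sum(np.diff(validate_mask(mask, scheme.seq_length), axis=1)))
    return MutationContextTensor(
        counts=counts, accessibility=access, scheme=scheme,
        xor_total=int(sf.xor.sum()), accessible_bp=scheme.seq_length - mask_bp,
        pivot=pivot)


def featurize_pair(G: np.ndarray, positions: np.ndarray, pivot: tuple[int, int],
                   scheme: WindowScheme, mask: np.ndarray | None = None) -> MutationContextTensor:
    """Genotypes + positions -> mutational-context tensor for one pivot pair."""
    sf = pivot_site_features(G, pivot, folded=scheme.folded)
    return window_tensor(sf, positions, scheme, mask=mask, pivot=pivot)


def featurize_replicate(rep: SimReplicate, pivots: list[tuple[int, int]] | None = None,
                        scheme: WindowScheme | None = None) -> list[MutationContextTensor]:
    """Featurize every requested pivot pair of a simulated replicate."""
    from .scenarios import within_individual_pivots

    cfg = rep.config
    if scheme is None:
        scheme = WindowScheme.for_cohort(cfg.seq_length, cfg.window_bp, cfg.diploid_n)
    if pivots is None:
        pivots = within_individual_pivots(cfg.diploid_n)
    return [featurize_pair(rep.genotypes, rep.positions, p, scheme, mask=rep.mask)
            for p in pivots]


# ---------------------------------------------------------------------------
# VCF ingestion


def from_vcf(vcf_path: str, focal_sample: str, afs_samples: list[str],
             region: str | None = None,
             ancestral: str = "ref") -> tuple[np.ndarray, np.ndarray]:
    """Read biallelic SNVs into a haplotype matrix for one focal diploid.

    Rows 0-1 are the focal individual's two haplotypes (for unphased
    input the het/hom status alone fixes the XOR/XNOR channels, so phase
    is irrelevant); remaining rows are the AFS samples' haplotypes.
    ``ancestral="ref"`` treats REF as ancestral (suits simulation-derived
    VCFs); pair with a folded WindowScheme when ancestral states are
    unknown. Returns (G, positions) with 0-based positions; a region with
    no variants gives an empty matrix, not an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    for s in [focal_sample, *afs_samples]:
        if s not in samples:
            raise KeyError(f"sample {s!r} not in VCF header")
    if ancestral != "ref":
        raise ValueError("only ancestral='ref' is implemented; use a folded "
                         "WindowScheme for unknown ancestral states")
    focal_idx = samples.index(focal_sample)
    afs_idx = [samples.index(s) for s in afs_samples]
    rows: list[np.ndarray] = []
    positions: list[float] = []
    n_dropped = 0
    records = vcf(region) if region is not None else vcf
    for var in records:
        # biallelic single-base records only (nucleotide or symbolic states)
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        gts = var.genotype.array()[:, :2]  # (n_samples, 2) allele indices
        if np.any(gts < 0):
            n_dropped += 1
            continue
        focal = gts[focal_idx]
        # unphased hets get a fixed arbitrary order; XOR/XNOR invariant to it
        hap = np.concatenate([np.sort(focal), gts[afs_idx].reshape(-1)])
        rows.append(hap.astype(np.uint8))
        positions.append(var.POS - 1)  # VCF is 1-based; internal 0-based
    if n_dropped:
        import logging
        logging.getLogger(__name__).info(
            "from_vcf: dropped %d non-biallelic-SNV or incomplete records", n_dropped)
    if not rows:
        n_hap = 2 + 2 * len(afs_samples)
        return np.zeros((n_hap, 0), dtype=np.uint8), np.zeros(0)
    G = np.stack(rows, axis=1)
    return G, np.asarray(positions, dtype=np.float64)
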