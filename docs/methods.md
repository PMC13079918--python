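# Methods

## Problem and model

The ancestral recombination graph of a sample is hidden; mutations are a
noisy window onto it. `coaltrace` infers one well-defined projection of
that graph: the sequence of pairwise coalescence times (TMRCAs) of a
focal pair of haplotypes ("pivot pair", the distinguished pair of
SMC++-style methods) along a recombining chromosome, discretized into
fixed genomic windows. Instead of an HMM likelihood with first-order
transitions, the conditional law of the time sequence given the data is
learned by a decoder-only transformer from coalescent simulations, which
act as the prior.

### Featurization

For a pivot pair (a, b) in a cohort of N diploids (2N haplotypes):

- every segregating site is assigned to the XOR channel if a and b carry
  different alleles (the site is heterozygous in the pair — these sites
  accumulate since the pair's common ancestor) or the XNOR channel
  otherwise;
- each site carries a frequency class: its derived-allele count among
  the 2N-2 non-pivot haplotypes (folded to minor-allele counts when
  ancestral states are unknown, e.g. empirical VCFs without outgroup
  polarization). Old XNOR sites tend to sit at high frequency classes,
  recent XOR sites at low ones, so the SFS partition is an age signal.
- sites are histogrammed by (channel, class) in windows at seven scales,
  {1, 2, 4, 8, 16, 32, 64} x the base window (2 kb base: 2 kb–128 kb),
  all centered on the base-window grid. Counts are stored raw; the model
  consumes per-kb densities so the same weights serve 2 kb and 200 bp
  configurations.
- an accessibility channel carries the uncallable fraction per
  (scale, window) — masked intervals plus out-of-sequence truncation of
  the wide scales at chromosome edges.

The tensor is invariant to swapping the pivot haplotypes and, for
within-individual pivots, to phase: het/hom status alone determines the
channels, so unphased diploid data work without phasing.

### Time scale, intercept, molecular clock

Times are tokenized on a log-uniform grid of 324 bins with open-ended
end bins. The model works in dimensionless ratio space t / T-bar, where
T-bar is the context's diversity-implied mean pairwise TMRCA: with S the
pivot pair's heterozygous-site total over the accessible length L and mu
the per-bp mutation rate, S ~ Poisson(2 mu L T-bar), and a weak
Gamma(a0=1, b0=1e-9) prior gives the conjugate posterior
Gamma(a0 + S, b0 + 2 mu L). Labels are divided by the posterior mean
before encoding (residualization in continuous log space); decoding
multiplies each replicate's ratio track by

    factor_r = (posterior draw_r) / (replicate's mean ratio),

so every replicate's arithmetic-mean TMRCA equals an exact draw from the
observed-diversity posterior. This is what makes the method
mutation-rate agnostic during training and aligns predicted diversity
with observed diversity by construction, while propagating clock
uncertainty into the posterior spread.

The ratio grid spans [1e-3, 1e2]: an exponential-tailed coalescent has
essentially no mass above ~20x its mean, so the grid allots three
decades below 1 and two above. The absolute-time grid (default
[10, 1e8] generations) is a config artifact saved with every checkpoint
so grids and models travel together.

### Architecture

The fused input sequence is [mut_1..mut_K, start, e_1..e_K]: K
mutation-context embeddings (a two-layer MLP projecting the flattened
(Z, WS, N) features plus accessibility fractions of each window into the
latent space), a learned start token, and embeddings of the coalescence
tokens — a fixed latent length of 2K+1 (1,001 at K=500). A fused-causal
mask makes mutation slots causal among themselves while every
coalescence-stream slot attends to all K mutation slots and the earlier
coalescence stream; logits at the start token predict e_1 and logits at
the slot carrying e_i predict e_{i+1} (standard next-token alignment).
Rotary phases encode the base-window index, identical for a mutation
slot and its paired coalescence slot; the start token sits at phase -1.

Default full configuration: 6 layers, 8 heads, E=512, dropout 0.1
(~19.9M parameters, inside the intended 10–20M band; note 8 layers at
E=512 would exceed it). CI/tiny configuration: 2 layers, 4 heads, E=64,
K=50 (~0.7M parameters with the 25-diploid feature width).

The transformer, reverse-mode autograd, AdamW and the cosine schedule
are implemented on numpy in `coaltrace.nn` (no GPU framework is assumed
in the target environment). Autoregressive sampling uses a key/value
cache (`IncrementalDecoder`), asserted numerically equivalent to the
full masked forward pass in the test suite.

### Training

The objective is the mean NLL of the true token sequence. The
coalescence-token context is, by default, the model's own sampled
trajectory (self-sampled rollout, drawn without dropout and treated as
data — no gradient flows through the sampling); teacher forcing is
available, and self-sampling ramps in linearly over the first 10% of
steps because rollouts from a random initialization carry no signal.
AdamW: base lr 3e-4, cosine annealing to zero, decoupled weight decay
0.01 on matrices only. A held-out validation split (10% by default) is
scored every epoch with self-sampled context, and the state from the
best-validation epoch is kept (`restore_best`); with ~500 training
examples the small model otherwise overfits well before the cosine
schedule ends. Fine-tuning: 2 epochs at a ten-fold reduced rate,
all weights. Adapter training: the backbone is frozen except every
LayerNorm and the final transformer block (at a ten-fold reduced rate);
the adapter itself — per-window layer norm, gated bottleneck over SFS
channels, residual projection, gate initialized at zero so it starts as
the residual projection exactly — trains at the full rate. Features are
standardized with constants estimated from the training set and stored
in the checkpoint; datasets are stored float16 on disk, compute is
float32.

Training examples should come from as many independent simulated
genealogies as possible: pivot pairs of one replicate share an ARG and
are strongly correlated, so a corpus of many pivots from few replicates
overfits (and under-covers on held-out data) where a corpus of the same
size drawn from more replicates does not. The test suite's end-to-end
fixture uses 50 replicates x 10 pivots for this reason.

### Decoding and uncertainty

For each pivot pair, decoding samples the categorical at temperature 1,
appends, and continues through all K windows; 15 replicates by default.
Per-pair random streams derive from the master seed with a counter
scheme, so batched cohort decoding and one-pair-at-a-time decoding are
bit-identical. Point estimates use the geometric mean across replicates
— the Bayes estimator under squared-log-error, the loss on which tracks
are evaluated; arithmetic mean and median are available. The first and
last 5% of windows are flagged as boundary (truncated context) and
tallied separately in coverage evaluation.

### Demography estimation

Windowed TMRCA samples are treated as coalescence event times. On a log
time grid (default 32 intervals over [10, 1e7] generations) the
instantaneous rate is the exposure-time (actuarial) hazard: events in
the interval divided by the total time all samples spent exposed in it;
the tail interval is open-ended. Ne(t) = 1/(2 lambda(t)) pointwise;
intervals with fewer than 20 events are masked, not extrapolated. The
identical estimator serves model predictions, true point-sampled TMRCAs
(the "inference limit" accuracy ceiling under matched discretization)
and cross-coalescence curves (pair types grouped by deme labels on a
shared grid). Summary metrics: mean squared error of natural-log times
(so "pred = e x truth" gives exactly 1.0) and KL divergence between
binned marginal time distributions with additive smoothing 0.5.

## What the synthetic data does and does not emulate

The generator covers: constant-size coalescents (benchmark world:
Ne = 2e4, mu = rec = 1e-8, 2 kb windows, 25 diploids), a sawtooth
misspecification stressor (piecewise-constant log-time sinusoid, Ne
oscillating ten-fold around 2e4, four cycles over 1e2–1e6 generations —
the oscillation's shape is a package choice; the literature states none),
a two-deme split with optional migration and randomized deme assignment
of the 50 haplotypes, and catalog-style species entries (vaquita and
gorilla carry published per-bp rates; the gorilla Ne and the pig/rat
rates are nominal placeholders). Binary mutations on a discrete genome;
no selection, no gene conversion, no sequencing error, no genotyping
missingness beyond explicit interval masks. A green test therefore
certifies the inference machinery under the model's own assumptions, not
robustness to real-data artifacts.

## Numerical choices and degenerate inputs

- Windows are 0-based half-open; VCF positions convert at the boundary.
- encode() clamps out-of-range times to the end bins with a logged
  warning; t <= 0 is an error.
- Fully masked contexts (L = 0) are an error in the clock; windows whose
  truth is undefined under a mask are NaN labels, excluded from the loss.
- Hazard estimation clips samples below the grid start to its first
  interval; NaN samples are dropped.
- NaN loss aborts training and restores the last end-of-epoch state.
- Determinism: a master seed fans out to named sub-streams
  (simulate/rollout/decode/clock); fixed seeds reproduce loss
  trajectories and decoded tracks bit-for-bit.

## Known limitations

- No genealogical topology reconstruction — only pairwise times.
- Cross-individual pivots require phased input; no statistical phasing
  is provided.
- The full-size configuration trains far too slowly on CPU to reproduce
  published-scale accuracy; the test suite exercises the tiny
  configuration end-to-end and the full configuration structurally.
- The hazard estimator's open tail interval underestimates the rate in
  the final bin when samples exceed the grid; rely on the support mask.
- Window-scale posterior summaries are approximate posteriors under the
  simulation prior, not exact Bayesian posteriors for real data.
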