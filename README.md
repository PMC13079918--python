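# coaltrace

Pairwise coalescence-time inference along recombining chromosomes,
phrased as sequence-to-sequence translation: a decoder-only transformer
reads windowed, SFS-partitioned mutation patterns and autoregressively
predicts the discretized time to the most recent common ancestor (TMRCA)
of a focal ("pivot") pair of haplotypes, window by window. The package is
aimed at population geneticists who want fast genome-wide TMRCA tracks
with usable uncertainty — for selection scans, dating sweeps and
balancing selection, and nonparametric demography (Ne(t)) estimation —
without deriving a likelihood for each demographic scenario.

## The model

Divide the genome into K fixed windows (default 500 x 2 kb) and
discretize log coalescence times into 324 bins. Writing E = (e_1 ... e_K)
for the true discretized pairwise TMRCAs and MC for the mutational
context (per-window site-frequency spectra, split into the sites that are
heterozygous vs homozygous in the pivot pair, at seven nested window
scales), the model learns the conditional factorization

    P(E | MC) = prod_i P(e_i | ê_<i, MC),

where ê_<i are the model's own sampled predictions for earlier windows.
Training maximizes sum_i log P(e_i | ê_<i, MC) with AdamW (base learning
rate 3e-4, cosine annealing). At inference the generative process is
repeated (15 replicates by default), giving samples from an approximate
posterior over the TMRCA trajectory.

The model is mutation-rate agnostic: it predicts times relative to the
context's diversity-implied mean pairwise TMRCA T-bar. A Poisson-Gamma
molecular clock (S ~ Poisson(2 mu L T-bar), conjugate Gamma posterior)
restores absolute time per replicate, so clock uncertainty is part of the
posterior spread and predicted diversity matches observed diversity by
construction.

Downstream, TMRCA samples convert to demography: the instantaneous
coalescence rate lambda(t) is estimated on a log time grid with an
exposure-time (actuarial) hazard estimator and inverted via
Ne(t) = 1/(2 lambda(t)).

Everything — coalescent simulation (msprime), featurization, the
transformer (pure numpy, trained from scratch; no GPU required at test
scale), decoding, calibration, demography — is in the library; a `coaltrace`
CLI wraps the pipeline (`simulate`, `featurize`, `train`, `finetune`,
`adapt`, `infer`, `demog`, `benchmark`).

## Worked example

Recover a constant effective population size from true coalescence
times — the "inference limit" of the discretized pipeline:

```python
from coaltrace import demography, scenarios

config = scenarios.build_scenario("narrow_constant", seq_length=10_000_000)
rep = scenarios.simulate(config, seed=101)
pivots = scenarios.within_individual_pivots(config.diploid_n)
curve = demography.inference_limit(rep, pivots)  # true TMRCAs every 2 kb
print(f"Ne = {curve.harmonic_mean_ne():.0f}")
```

```
Ne = 19988
```

The simulation used Ne = 20,000; the exposure-weighted harmonic mean over
supported intervals lands within 0.1% of it (Monte-Carlo error moves this
by a few percent across seeds). A model-based version of the same
pipeline — train a small model on simulations, decode posterior tracks
for a held-out replicate:

```python
from coaltrace import inference, training
from coaltrace.features import featurize_replicate
from coaltrace.model import CoalescenceTransformer, tiny_config
from coaltrace.scenarios import true_tmrca_track

cfg = scenarios.build_scenario("narrow_constant", seq_length=100_000)
reps = [scenarios.simulate(cfg, seed=s) for s in range(1, 51)]
ds = training.dataset_from_replicates(reps, pivots=[(2*i, 2*i+1) for i in range(10)])
net = CoalescenceTransformer(tiny_config(), seed=0)
ckpt = training.train(net, ds, training.TrainConfig(epochs=80, batch_size=25))
# ~12 CPU-minutes; keeps the best-validation epoch

test = scenarios.simulate(cfg, seed=100)
mcs = featurize_replicate(test, pivots=[(0, 1)])
tracks = inference.decode_cohort(ckpt.net, mcs, cfg.mu, ckpt.grid, seed=7)
df = inference.summarize(tracks[0])
print(df[~df.boundary].head(3)[["start", "mean", "lo80", "hi80"]].round(0))

pred = tracks[0].to_track("gmean").values   # geometric mean of 15 replicates
truth = true_tmrca_track(test, (0, 1), mode="mean").values
for k in (5, 10, 25, 40):
    print(k, int(pred[k]), int(truth[k]))
```

```
   start     mean     lo80     hi80
3   6000  26646.0  10107.0  37766.0
4   8000  21310.0   6599.0  35085.0
5  10000  21937.0   2545.0  58857.0
5 9280 3293
10 49656 73309
25 50486 77524
40 4206 18211
```

Each summary row is one 2 kb window: posterior mean TMRCA of the pivot
pair (generations) and an equal-tailed 80% interval across the 15
calibrated replicates. The point track follows the truth's excursions —
recent coalescence at the start of the fragment, deep genealogy around
windows 10 and 25 — with the residual scatter expected from ~1.6
heterozygous sites per 2 kb window of signal.

## Acceptance script

`scripts/acceptance.py` re-runs the Ne-recovery pipeline from scratch —
simulating 10 Mb for 25 diploids under the constant-size benchmark
scenario, point-sampling true pairwise TMRCAs every 2 kb, estimating
interval hazards on a 32-interval log grid, and reporting the
exposure-weighted harmonic-mean Ne:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
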