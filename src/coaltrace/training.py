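"""Next-coalescence training: objective, rollout, optimizer, recipes.

The objective is the mean negative log-likelihood of the true discretized
TMRCA sequence, with the coalescence-token context built either from the
truth (teacher forcing) or, by default, from the model's own sampled
predictions (self-sampled rollout, the literal reading of the stated
objective). Because sampling from a freshly initialized model can stall
learning, self-sampled training ramps in linearly over the first 10% of
steps, starting from teacher forcing.

Optimization is AdamW (base learning rate 3e-4) with cosine annealing to
zero. Fine-tuning reuses the loop for two epochs at a ten-fold reduced
learning rate. Adapter training freezes the pretrained backbone except
the adapter itself, every LayerNorm, and the final transformer block(s),
the latter two groups at a reduced learning rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (AdapterConfig, CoalescenceTransformer, ModelConfig,
                    SampleSizeAdapter, sample_trajectory)
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import set_dropout_rng
from .timescale import TimeDiscretization

logger = logging.getLogger(__name__)


@dataclass
class FeatureDataset:
    """Featurized training examples in model-ready array form.

    ``ratios`` are the per-window true mean TMRCAs divided by each
    example's diversity intercept (the Poisson-Gamma posterior-mean
    T-bar), i.e. the residual scale the model is trained on. ``s_obs``
    and ``l_acc`` (pivot heterozygous-site totals and accessible bp)
    travel along for calibration experiments; ``t_bar`` is the intercept.
    """

    mc_density: np.ndarray  # (B, 2, WS, K, N) float32 (float16 on disk)
    access: np.ndarray  # (B, WS, K)
    ratios: np.ndarray  # (B, K) true t / t_bar
    s_obs: np.ndarray | None = None
    l_acc: np.ndarray | None = None
    t_bar: np.ndarray | None = None

    def __post_init__(self):
        if not (len(self.mc_density) == len(self.access) == len(self.ratios)):
            raise ValueError("inconsistent example counts")

    def __len__(self) -> int:
        return len(self.ratios)

    def subset(self, idx) -> "FeatureDataset":
        pick = lambda a: None if a is None else a[idx]
        return FeatureDataset(self.mc_density[idx], self.access[idx],
                              self.ratios[idx], pick(self.s_obs),
                              pick(self.l_acc), pick(self.t_bar))


@dataclass(frozen=True)
class TrainConfig:
    base_lr: float = 3e-4
    epochs: int = 5
    batch_size: int = 16
    rollout: str = "self_sample"  # self_sample | teacher_forced | mixed
    warmup_frac: float = 0.1  # linear teacher-forcing ramp for self_sample
    weight_decay: float = 0.01
    val_frac: float = 0.1
    restore_best: bool = True  # keep the best-validation-NLL epoch state
    seed: int = 0
    finetune_lr_factor: float = 0.1
    finetune_epochs: int = 2

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.rollout not in ("self_sample", "teacher_forced", "mixed"):
            raise ValueError(f"unknown rollout mode {self.rollout!r}")


@dataclass
class Checkpoint:
    net: CoalescenceTransformer
    grid: TimeDiscretization
    train_config: TrainConfig
    history: pd.DataFrame
    val_nll: float | None = None
    adapter: SampleSizeAdapter | None = None


def cosine_lr(step: int, total_steps: int, base_lr: float) -> float:
    """Cosine annealing from base_lr to 0 over the run."""
    if total_steps <= 1:
        return base_lr
    frac = min(step / (total_steps - 1), 1.0)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * frac))


class AdamW:
    """Decoupled weight decay Adam over named parameter tensors.

    Weight decay applies only to matrices (ndim >= 2); biases, layer-norm
    gains and scalar gates are exempt. `lr_scales` multiplies the shared
    schedule per parameter name (adapter recipes).
    """

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01,
                 lr_scales: dict[str, float] | None = None):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.lr_scales = lr_scales or {}
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            lr = self.lr * self.lr_scales.get(k, 1.0)
            upd = mhat / (np.sqrt(vhat) + self.eps)
            if p.data.ndim >= 2:
                upd = upd + self.weight_decay * p.data
            p.data = p.data - lr * upd

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


# ---------------------------------------------------------------------------
# objective


def nll_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood over coalescence slots.

    logits: (B, K, C) at the prediction slots; labels: (B, K) bin indices.
    Label -1 marks padding and is excluded from the mean.
    """
    labels = np.asarray(labels, dtype=np.int64)
    C = logits.shape[-1]
    if labels.max(initial=-1) >= C:
        raise ValueError(f"label outside [0, {C})")
    mask = labels >= 0
    if mask.all():
        return ag.cross_entropy(logits, labels, reduction="mean")
    safe = np.where(mask, labels, 0)
    per = ag.cross_entropy(logits, safe, reduction="none")
    w = mask.astype(np.float32) / mask.sum()
    return (per * Tensor(w)).sum()


def rollout_step(net: CoalescenceTransformer, mc: np.ndarray, access: np.ndarray,
                 labels: np.ndarray, mode: str, rng: np.random.Generator,
                 adapter: SampleSizeAdapter | None = None) -> Tensor:
    """One training loss evaluation with the requested context policy.

    self_sample: the coalescence context is the model's own sampled
    trajectory (drawn without dropout, treated as data); the loss still
    targets the true labels. teacher_forced: the context is the truth.
    """
    labels = np.asarray(labels, dtype=np.int64)
    K = net.config.n_windows
    if mode == "teacher_forced":
        context = labels
    elif mode == "self_sample":
        if adapter is None:
            mc_in = np.asarray(mc, dtype=np.float32)
        else:
            with ag.no_grad():
                mc_in = adapter(np.asarray(mc, dtype=np.float32)).data
        context = sample_trajectory(net, mc_in, access, rng)
    else:
        raise ValueError(f"unknown rollout mode {mode!r}")
    mc_t = adapter(np.asarray(mc, dtype=np.float32)) if adapter is not None else mc
    logits = net.forward(mc_t, access, context)
    pred = net.prediction_logits(logits, K)
    return nll_loss(pred, labels)


def _encode_labels(ds: FeatureDataset, grid: TimeDiscretization) -> np.ndarray:
    """Ratio labels -> bin tokens; NaN windows (masked truth) -> -1 padding."""
    ratios = np.asarray(ds.ratios, dtype=np.float64)
    ok = np.isfinite(ratios) & (ratios > 0)
    labels = np.full(ratios.shape, -1, dtype=np.int64)
    if ok.any():
        labels[ok] = grid.encode(ratios[ok])
    return labels


def _eval_nll(net, adapter, ds: FeatureDataset, labels: np.ndarray, mode: str,
              seed: int, batch_size: int) -> float:
    rng = np.random.default_rng(seed)
    was = net.training
    net.eval()
    tot, n = 0.0, 0
    try:
        for lo in range(0, len(ds), batch_size):
            sl = slice(lo, lo + batch_size)
            with ag.no_grad():
                loss = rollout_step(net, ds.mc_density[sl], ds.access[sl],
                                    labels[sl], mode, rng, adapter=adapter)
            b = len(labels[sl])
            tot += float(loss.data) * b
            n += b
    finally:
        net.train(was)
    return tot / max(n, 1)


def _fit_loop(net: CoalescenceTransformer, ds: FeatureDataset, cfg: TrainConfig,
              grid: TimeDiscretization, opt: AdamW,
              adapter: SampleSizeAdapter | None = None,
              epochs: int | None = None) -> Checkpoint:
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed)
    set_dropout_rng(np.random.default_rng(rng.integers(0, 2 ** 31)))
    n = len(ds)
    n_val = int(round(cfg.val_frac * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    tr, va = ds.subset(tr_idx), ds.subset(val_idx) if n_val else None
    labels_tr = _encode_labels(tr, grid)
    labels_va = _encode_labels(va, grid) if va is not None else None

    steps_per_epoch = max(1, int(np.ceil(len(tr) / cfg.batch_size)))
    total_steps = steps_per_epoch * epochs
    warmup_steps = int(cfg.warmup_frac * total_steps)
    rows = []
    best_state = (net.state_dict(),
                  adapter.state_dict() if adapter is not None else None)
    best_val = np.inf
    step = 0
    net.train(True)
    if adapter is not None:
        adapter.train(True)
    try:
        for epoch in range(epochs):
            order = rng.permutation(len(tr))
            epoch_loss, nb = 0.0, 0
            for lo in range(0, len(tr), cfg.batch_size):
                bidx = order[lo:lo + cfg.batch_size]
                lr = cosine_lr(step, total_steps, cfg.base_lr)
                opt.lr = lr
                if cfg.rollout == "teacher_forced":
                    mode = "teacher_forced"
                elif cfg.rollout == "self_sample" and warmup_steps > 0 and step < warmup_steps:
                    # linear ramp: P(self-sample) grows from 0 to 1
                    p_self = step / warmup_steps
                    mode = "self_sample" if rng.random() < p_self else "teacher_forced"
                else:
                    mode = "self_sample" if cfg.rollout != "teacher_forced" else "teacher_forced"
                loss = rollout_step(net, tr.mc_density[bidx], tr.access[bidx],
                                    labels_tr[bidx], mode, rng, adapter=adapter)
                if not np.isfinite(loss.data):
                    raise FloatingPointError("training loss diverged (NaN/inf)")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                nb += 1
                step += 1
            val_nll = (_eval_nll(net, adapter, va, labels_va, "self_sample",
                                 cfg.seed + 7919, cfg.batch_size)
                       if va is not None and len(va) else np.nan)
            rows.append(dict(epoch=epoch, train_nll=epoch_loss / nb,
                             val_nll=val_nll, lr=lr, mode=cfg.rollout))
            logger.info("epoch %d: train NLL %.4f, val NLL %.4f, lr %.2e",
                        epoch, epoch_loss / nb, val_nll, lr)
            keep = (not cfg.restore_best) or np.isnan(val_nll) or val_nll <= best_val
            if keep:
                best_val = val_nll if np.isfinite(val_nll) else best_val
                best_state = (net.state_dict(),
                              adapter.state_dict() if adapter is not None else None)
        if cfg.restore_best and np.isfinite(best_val):
            net.load_state_dict(best_state[0])
            if adapter is not None and best_state[1] is not None:
                adapter.load_state_dict(best_state[1])
    except FloatingPointError as exc:
        logger.error("aborting training: %s; restoring last good checkpoint", exc)
        net.load_state_dict(best_state[0])
        if adapter is not None and best_state[1] is not None:
            adapter.load_state_dict(best_state[1])
        rows.append(dict(epoch=-1, train_nll=np.nan, val_nll=np.nan, lr=np.nan,
                         mode="aborted"))
    finally:
        net.train(False)
        if adapter is not None:
            adapter.train(False)
        set_dropout_rng(None)
    hist = pd.DataFrame(rows)
    if not hist.val_nll.notna().any():
        val = None
    elif cfg.restore_best:
        val = float(hist.val_nll.min())  # the restored state's validation NLL
    else:
        val = float(hist.val_nll.dropna().iloc[-1])
    return Checkpoint(net=net, grid=grid, train_config=cfg, history=hist,
                      val_nll=val, adapter=adapter)


def train(net: CoalescenceTransformer, ds: FeatureDataset, cfg: TrainConfig,
          grid: TimeDiscretization | None = None) -> Checkpoint:
    """Train from scratch: standardize features, AdamW + cosine, NLL rollout."""
    if grid is None:
        grid = TimeDiscretization.ratio_grid(net.config.n_bins)
    # feature standardization from training data (stored in the checkpoint)
    with ag.no_grad():
        feats = net.input_features(ds.mc_density, ds.access).data
    net.feat_std = np.ones(net.config.d_in, dtype=np.float32)
    net.feat_mean = np.zeros(net.config.d_in, dtype=np.float32)
    mean = feats.reshape(-1, feats.shape[-1]).mean(axis=0)
    std = feats.reshape(-1, feats.shape[-1]).std(axis=0)
    net.set_feature_norm(mean, std)
    opt = AdamW(_trainable(net.named_parameters()), lr=cfg.base_lr,
                weight_decay=cfg.weight_decay)
    return _fit_loop(net, ds, cfg, grid, opt)


def finetune(ckpt: Checkpoint, ds: FeatureDataset, cfg: TrainConfig | None = None) -> Checkpoint:
    """Update all weights for `finetune_epochs` at the reduced learning rate."""
    cfg = cfg or ckpt.train_config
    expect = (2, ckpt.net.config.n_scales, ckpt.net.config.n_windows,
              ckpt.net.config.n_freq)
    if ds.mc_density.shape[1:] != expect:
        raise ValueError(f"feature dims {ds.mc_density.shape[1:]} do not match "
                         f"model {expect}")
    lr = cfg.base_lr * cfg.finetune_lr_factor
    run_cfg = replace(cfg, base_lr=lr)
    opt = AdamW(_trainable(ckpt.net.named_parameters()), lr=lr,
                weight_decay=cfg.weight_decay)
    return _fit_loop(ckpt.net, ds, run_cfg, ckpt.grid, opt,
                     epochs=cfg.finetune_epochs)


def train_adapter(ckpt: Checkpoint, adapter: SampleSizeAdapter, ds: FeatureDataset,
                  cfg: TrainConfig | None = None, unfreeze_last_blocks: int = 1,
                  reduced_lr_factor: float = 0.1) -> Checkpoint:
    """Adapter recipe: backbone frozen except LayerNorms and final block(s).

    The adapter trains at the full rate; the unfrozen LayerNorm and final
    transformer-block parameters at `reduced_lr_factor` times that. All
    other backbone weights are bit-identical after training.
    """
    cfg = cfg or ckpt.train_config
    net = ckpt.net
    n_blocks = len(net.blocks)
    trainable: dict[str, Tensor] = {}
    lr_scales: dict[str, float] = {}
    for name, p in net.named_parameters().items():
        is_ln = ".ln" in name or name.startswith("ln_f")
        is_final = any(name.startswith(f"blocks.{i}.")
                       for i in range(n_blocks - unfreeze_last_blocks, n_blocks))
        if is_ln or is_final:
            key = f"net.{name}"
            trainable[key] = p
            lr_scales[key] = reduced_lr_factor
        else:
            p.requires_grad = False
    for name, p in adapter.named_parameters().items():
        trainable[f"adapter.{name}"] = p
        lr_scales[f"adapter.{name}"] = 1.0
    try:
        opt = AdamW(trainable, lr=cfg.base_lr, weight_decay=cfg.weight_decay,
                    lr_scales=lr_scales)
        out = _fit_loop(net, ds, cfg, ckpt.grid, opt, adapter=adapter,
                        epochs=cfg.finetune_epochs)
    finally:
        for p in net.named_parameters().values():
            p.requires_grad = True
    return out


def _trainable(params: dict[str, Tensor]) -> dict[str, Tensor]:
    return {k: p for k, p in params.items() if p.requires_grad}


def dataset_from_replicates(reps, pivots=None, scheme=None) -> FeatureDataset:
    """Featurize simulated replicates into a training-ready dataset.

    Labels are windowed true mean TMRCAs divided by each context's
    diversity intercept (posterior-mean T-bar given the pivot pair's
    heterozygous-site total), so the model learns relative structure and
    the absolute scale is restored at decode time.
    """
    from .features import WindowScheme, featurize_replicate
    from .scenarios import true_tmrca_track, within_individual_pivots
    from .timescale import diversity_intercept

    mc_list, acc_list, ratio_list, s_list, l_list, tb_list = [], [], [], [], [], []
    for rep in reps:
        cfg = rep.config
        sch = scheme or WindowScheme.for_cohort(cfg.seq_length, cfg.window_bp,
                                                cfg.diploid_n)
        pvs = pivots or within_individual_pivots(cfg.diploid_n)
        mcs = featurize_replicate(rep, pvs, sch)
        for pv, mc in zip(pvs, mcs):
            track = true_tmrca_track(rep, pv, window_bp=sch.window_bp, mode="mean")
            t_bar = diversity_intercept(mc.xor_total, mc.accessible_bp, cfg.mu)
            mc_list.append(mc.density)
            acc_list.append(mc.accessibility)
            ratio_list.append(track.values / t_bar)
            s_list.append(mc.xor_total)
            l_list.append(mc.accessible_bp)
            tb_list.append(t_bar)
    return FeatureDataset(mc_density=np.stack(mc_list).astype(np.float32),
                          access=np.stack(acc_list).astype(np.float32),
                          ratios=np.stack(ratio_list),
                          s_obs=np.asarray(s_list), l_acc=np.asarray(l_list),
                          t_bar=np.asarray(tb_list))
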