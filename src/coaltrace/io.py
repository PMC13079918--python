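"""Readers, writers and provenance plumbing.

Conventions: internal coordinates are 0-based half-open everywhere; the
only 1-based surface is VCF, converted at the boundary. Every output file
carries a provenance header (tool version, resolved-config hash, seed).
Feature batches are stored as float16 HDF5 datasets; checkpoints as a
single .npz archive bundling weights, model config, time grid and
feature-normalization constants.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .model import AdapterConfig, CoalescenceTransformer, ModelConfig, SampleSizeAdapter
from .scenarios import SimReplicate, TmrcaTrack
from .timescale import TimeDiscretization


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_header(seed: int | None, config: dict | None = None,
                      comment: str = "#") -> list[str]:
    lines = [f"{comment} coaltrace_version={__version__}"]
    if seed is not None:
        lines.append(f"{comment} seed={seed}")
    if config is not None:
        lines.append(f"{comment} config_hash={config_hash(config)}")
    return lines


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Fan a master seed out to named sub-streams (all below 2**31)."""
    names = ("simulate", "rollout", "decode", "clock", "split")
    ss = np.random.SeedSequence(int(master_seed))
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31 - 1)) + 1
            for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# tracks


def write_tracks_tsv(path: str, tracks, chrom: str = "1", seed: int | None = None,
                     config: dict | None = None) -> None:
    """Replicate tracks as TSV: chrom, start, end, pivot, replicate, tmrca."""
    from .inference import PosteriorTracks

    track_list = tracks if isinstance(tracks, list) else [tracks]
    rows = []
    for tr in track_list:
        if isinstance(tr, PosteriorTracks):
            values, pivot, starts, wbp = tr.times, tr.pivot, tr.window_starts, tr.window_bp
        elif isinstance(tr, TmrcaTrack):
            values = np.atleast_2d(tr.values)
            pivot, starts, wbp = tr.pivot, tr.window_starts, tr.window_bp
        else:
            raise TypeError(f"cannot write {type(tr)}")
        pid = f"{pivot[0]}-{pivot[1]}"
        for r in range(values.shape[0]):
            for s, v in zip(starts, values[r]):
                rows.append((chrom, int(s), int(s) + wbp, pid, r, v))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "pivot",
                                     "replicate", "tmrca_generations"])
    with open(path, "w") as fh:
        for line in provenance_header(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tracks_tsv(path: str) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if "=" in line:
                k, v = line.lstrip("# ").rstrip().split("=", 1)
                meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def write_bedgraph(path: str, chrom: str, window_starts: np.ndarray, window_bp: int,
                   values: np.ndarray, seed: int | None = None) -> None:
    """Mean track as BEDGRAPH (0-based half-open)."""
    with open(path, "w") as fh:
        for line in provenance_header(seed):
            fh.write(line + "\n")
        fh.write(f'track type=bedGraph name="mean_tmrca"\n')
        for s, v in zip(window_starts, values):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{int(s)}\t{int(s) + window_bp}\t{v:.6g}\n")


def read_bed(path: str) -> np.ndarray:
    """BED intervals -> (m, 2) float array; malformed rows raise with line numbers."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{ln}: empty/inverted interval "
                                 f"({start} >= {end})")
            intervals.append((start, end))
    return np.asarray(intervals, dtype=np.float64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# VCF export of simulated replicates


def write_vcf(rep: SimReplicate, path: str, chrom: str = "1") -> None:
    """Simulated replicate -> uncompressed VCF with diploid genotypes."""
    names = [f"ind_{i}" for i in range(rep.config.diploid_n)]
    with open(path, "w") as fh:
        rep.genealogy.write_vcf(fh, contig_id=chrom, individual_names=names)


# ---------------------------------------------------------------------------
# feature datasets (HDF5, float16 payloads)


def save_dataset(path: str, ds) -> None:
    from .training import FeatureDataset

    assert isinstance(ds, FeatureDataset)
    with h5py.File(path, "w") as f:
        f.attrs["coaltrace_version"] = __version__
        f.create_dataset("mc_density", data=ds.mc_density.astype(np.float16),
                         compression="gzip")
        f.create_dataset("access", data=ds.access.astype(np.float16))
        f.create_dataset("ratios", data=ds.ratios.astype(np.float32))
        for name in ("s_obs", "l_acc", "t_bar"):
            arr = getattr(ds, name)
            if arr is not None:
                f.create_dataset(name, data=np.asarray(arr))


def load_dataset(path: str):
    from .training import FeatureDataset

    with h5py.File(path, "r") as f:
        opt = {name: f[name][:] if name in f else None
               for name in ("s_obs", "l_acc", "t_bar")}
        return FeatureDataset(
            mc_density=f["mc_density"][:].astype(np.float32),
            access=f["access"][:].astype(np.float32),
            ratios=f["ratios"][:].astype(np.float64), **opt)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str, ckpt) -> None:
    """Weights + ModelConfig + time grid + feature norms in one archive."""
    from .training import Checkpoint

    assert isinstance(ckpt, Checkpoint)
    net = ckpt.net
    payload = {f"net:{k}": v for k, v in net.state_dict().items()}
    payload["feat_mean"] = net.feat_mean
    payload["feat_std"] = net.feat_std
    meta = dict(model_config=net.config.to_dict(), grid=json.loads(ckpt.grid.to_json()),
                train_config=asdict(ckpt.train_config), version=__version__)
    if ckpt.adapter is not None:
        payload.update({f"adapter:{k}": v for k, v in ckpt.adapter.state_dict().items()})
        meta["adapter_config"] = asdict(ckpt.adapter.config)
    payload["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **payload)


def load_checkpoint(path: str):
    from .training import Checkpoint, TrainConfig

    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        cfg = ModelConfig(**meta["model_config"])
        net = CoalescenceTransformer(cfg, seed=0)
        net.load_state_dict({k[4:]: z[k] for k in z.files if k.startswith("net:")})
        net.feat_mean = z["feat_mean"].astype(np.float32)
        net.feat_std = z["feat_std"].astype(np.float32)
        grid = TimeDiscretization(edges=np.asarray(meta["grid"]["edges"]),
                                  n_bins=int(meta["grid"]["n_bins"]))
        adapter = None
        if "adapter_config" in meta:
            adapter = SampleSizeAdapter(AdapterConfig(**meta["adapter_config"]))
            adapter.load_state_dict({k[8:]: z[k] for k in z.files
                                     if k.startswith("adapter:")})
    tc = TrainConfig(**meta["train_config"])
    return Checkpoint(net=net, grid=grid, train_config=tc,
                      history=pd.DataFrame(), adapter=adapter)
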