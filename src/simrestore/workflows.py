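"""End-to-end workflows: simulate -> prepare -> train -> predict -> evaluate.

Each step reads/writes plain artifacts (TIFF stacks with JSON sidecars, CSV
manifests, NPZ checkpoints) in an output directory, so runs are resumable
and fully reproducible from a saved configuration and a single seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import metrics as _metrics
from . import nn as _nn
from . import prep as _prep
from . import recon as _recon
from . import synth as _synth

SCENE_KINDS = ("filament", "puncta", "blob")


def _scene_kind(i: int, kind: str) -> str:
    if kind == "mixed":
        return SCENE_KINDS[i % len(SCENE_KINDS)]
    return kind


def simulate(
    out_dir: str | Path,
    n_scenes: int = 10,
    scene_size: int = 128,
    structure_kind: str = "mixed",
    low_light_factor: float | None = 100.0,
    photon_budget: float = 200.0,
    read_noise_sd: float = 1.0,
    seed: int = 0,
    optics_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Simulate scenes, raw stacks (normal and optionally low-light) and
    classical SR ground truths; returns (and writes) the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    optics = _synth.make_optical_model(shape=(scene_size, scene_size),
                                       **(optics_kwargs or {}))
    rows = []
    for i in range(n_scenes):
        kind = _scene_kind(i, structure_kind)
        scene = _synth.generate_scene(kind, scene_size, scene_size,
                                      seed=seed + 1000 * i)
        acq = _synth.AcquisitionSettings(
            photon_budget=photon_budget, read_noise_sd=read_noise_sd,
            seed=seed + 1000 * i + 1,
        )
        if low_light_factor and low_light_factor > 1:
            normal, low = _synth.make_low_light_pair(scene, optics, acq,
                                                     low_light_factor)
        else:
            normal, low = _synth.simulate_raw_stack(scene, optics, acq), None
        raw_path = out_dir / f"scene_{i:03d}_raw.tif"
        _synth.write_stack(normal, raw_path)
        low_path = ""
        if low is not None:
            low_path = f"scene_{i:03d}_low.tif"
            _synth.write_stack(low, out_dir / low_path)
        sr = _recon.reconstruct(normal, params_mode="known")
        gt_path = out_dir / f"scene_{i:03d}_gt.tif"
        tifffile.imwrite(gt_path, sr.image.astype(np.float32))
        rows.append({
            "scene": i, "kind": kind, "raw": raw_path.name, "low": low_path,
            "ground_truth": gt_path.name, "seed": seed + 1000 * i,
        })
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "manifest.csv", index=False)
    return df


def prepare(
    sim_dir: str | Path,
    out_dir: str | Path,
    variant: str = "sim15",
    patch_size: int = 32,
    stride: int | None = None,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    min_foreground_fraction: float = 0.01,
    use_low_light: bool = False,
    seed: int = 0,
) -> _prep.PatchDataset:
    """Cut, filter, resize, split and normalize network-ready patch pairs.

    ``variant`` selects the channel contract: sim15/scunet use all 15
    frames, sim3 the first phase per angle, snr maps 15 low-light frames to
    the 15 normal-light frames.  Inputs are bicubic-resized 2x so input and
    target share the network grid.
    """
    sim_dir, out_dir = Path(sim_dir), Path(out_dir)
    manifest = pd.read_csv(sim_dir / "manifest.csv", keep_default_na=False)
    if manifest.empty:
        raise ValueError("simulation manifest is empty")
    pairs = []
    for _, row in manifest.iterrows():
        normal = _synth.read_stack(sim_dir / row["raw"])
        source = normal
        if use_low_light or variant in ("snr", "scunet"):
            if not row["low"]:
                raise ValueError("variant needs low-light stacks; none simulated")
            source = _synth.read_stack(sim_dir / row["low"])
        gt = tifffile.imread(sim_dir / row["ground_truth"]).astype(np.float64)
        in_frames = source.frames
        raw_pairs = _prep.crop_patches(in_frames, gt, patch_size,
                                       stride or patch_size,
                                       source_id=f"scene_{row['scene']:03d}")
        for p in raw_pairs:
            if not _prep.reject_background(p.input_patch, min_foreground_fraction):
                continue
            inp = p.input_patch
            if variant == "sim3":
                inp = _prep.select_sim3_frames(inp)
            if variant == "snr":
                y, x = p.offset
                tgt = normal.frames[:, y: y + patch_size, x: x + patch_size]
                tgt = _prep.resize_bicubic(tgt, 2 * patch_size, 2 * patch_size)
                p.target_patch = tgt
            inp = _prep.resize_bicubic(inp, 2 * patch_size, 2 * patch_size)
            p.input_patch = inp
            pairs.append(p)
    if not pairs:
        raise ValueError("no patches survived background rejection")
    split = _prep.split_dataset(pairs, fractions, seed=seed)
    pairs, in_max, tgt_max = _prep.normalize_dataset(pairs, split)
    ds = _prep.PatchDataset(pairs, split, in_max, tgt_max)
    _prep.save_dataset(ds, out_dir)
    return ds


def train_model(
    dataset_dir: str | Path,
    out_path: str | Path,
    variant: str = "sim15",
    depth: int = 3,
    base_features: int = 8,
    epochs: int = 30,
    batch_size: int = 4,
    learning_rate: float = 1e-3,
    loss_variant: str = "l1_l2",
    seed: int = 0,
    init_from: str | Path | None = None,
) -> _nn.TrainingHistory:
    """Train a named variant on a prepared dataset and checkpoint it."""
    ds = _prep.load_dataset(dataset_dir)
    net = _nn.build_named(variant if variant in _nn.NAMED_CHANNELS else "sim15",
                          depth=depth, base_features=base_features, seed=seed)
    if init_from is not None:
        _nn.transfer_init(net, init_from)
    cfg = _nn.TrainingConfig(epochs, batch_size, learning_rate, loss_variant, seed)
    hist = _nn.train(net, ds.pairs, ds.split, cfg)
    norm = ds.pairs[0].normalization if ds.pairs else (1.0, 1.0)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    _nn.save_checkpoint(out_path, net, normalization=norm, training_seed=seed)
    pd.DataFrame({
        "epoch": np.arange(1, len(hist.train_loss) + 1),
        "train_loss": hist.train_loss, "val_loss": hist.val_loss,
    }).to_csv(out_path.with_suffix(".history.csv"), index=False)
    return hist


def predict_stack(
    checkpoint_path: str | Path,
    stack_path: str | Path,
    out_path: str | Path,
    variant: str = "sim15",
) -> np.ndarray:
    """Run full-frame inference on one raw stack TIFF."""
    ck = _nn.load_checkpoint(checkpoint_path)
    stack = _synth.read_stack(stack_path)
    frames = stack.frames
    if variant == "sim3":
        frames = _prep.select_sim3_frames(frames)
    out = _nn.predict(ck["net"], frames, ck["normalization"])
    img = out[0] if out.ndim == 3 else out
    tifffile.imwrite(out_path, img.astype(np.float32))
    return img


def evaluate_dataset(
    dataset_dir: str | Path,
    checkpoint_path: str | Path,
    out_csv: str | Path,
    subset: str = "test",
) -> pd.DataFrame:
    """Metrics for every patch of a split subset; one CSV row per patch."""
    ds = _prep.load_dataset(dataset_dir)
    ck = _nn.load_checkpoint(checkpoint_path)
    net = ck["net"]
    idx = getattr(ds.split, subset) if ds.split is not None else range(len(ds.pairs))
    rows = []
    for i in idx:
        p = ds.pairs[i]
        out = net(_nn.Tensor(p.input_patch[None])).data[0]
        out = np.clip(out, 0.0, None)
        gt = p.target_patch
        rep = _metrics.evaluate_pair(out[0], gt[0], None, data_range=max(gt.max(), 1e-12))
        rows.append({"index": i, **rep.to_dict()})
    df = pd.DataFrame(rows)
    Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_csv, index=False)
    return df


def save_run_config(path: str | Path, config: dict) -> None:
    Path(path).write_text(json.dumps(config, indent=1, sort_keys=True))
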