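"""Patch extraction, background rejection, normalization and dataset splits.

Raw SIM stacks (W x H x C, angle-major frames) and their super-resolution
ground truths (2W x 2H) are tiled into patch pairs, background-only patches
are dropped, inputs are resized to the network grid by bicubic interpolation
and everything is normalized by a single per-domain scalar (the maximum over
the training portion), which is stored and reused at inference.

Ground-truth crops are taken at exactly twice the raw-patch offsets and
sizes, so patch k of the stack and patch k of the reconstruction cover the
same field of view.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize as _sk_resize


SIM3_FRAME_INDICES = (0, 5, 10)   # first phase of each of the 3 angles


@dataclass
class PatchPair:
    """One network training sample: input frames + matched ground truth."""

    input_patch: np.ndarray    # (C_in, h, w)
    target_patch: np.ndarray   # (C_out, H, W), H = 2h etc. for SIM tasks
    source_id: str
    offset: tuple[int, int]    # (y, x) of the raw crop, 0-based row-major
    normalization: tuple[float, float] = (1.0, 1.0)   # (input_max, target_max)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test membership lists of patch indices."""

    train: list[int]
    validation: list[int]
    test: list[int]
    seed: int = 0

    def all_indices(self) -> list[int]:
        return sorted(self.train + self.validation + self.test)


@dataclass
class PatchDataset:
    pairs: list[PatchPair]
    split: DatasetSplit | None = None
    input_max: float = field(default=1.0)
    target_max: float = field(default=1.0)


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def crop_patches(
    frames: np.ndarray,
    ground_truth: np.ndarray | None = None,
    patch_size: int = 128,
    stride: int = 128,
    source_id: str = "stack",
) -> list[PatchPair]:
    """Tile a (C, H, W) stack into patches with row-major (y, x) offsets.

    When ``ground_truth`` (a (2H, 2W) image) is given, the matching crop at
    2x the offset and 2x the size is attached to each patch.
    """
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    _, h, w = frames.shape
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch_size {patch_size} exceeds image size {h}x{w}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if ground_truth is not None:
        gt = np.asarray(ground_truth)
        if gt.shape != (2 * h, 2 * w):
            raise ValueError("ground truth must be exactly 2x the stack grid")
    out = []
    for y in range(0, h - patch_size + 1, stride):
        for x in range(0, w - patch_size + 1, stride):
            inp = frames[:, y: y + patch_size, x: x + patch_size].copy()
            if ground_truth is not None:
                tgt = gt[2 * y: 2 * (y + patch_size), 2 * x: 2 * (x + patch_size)]
                tgt = tgt[None].copy()
            else:
                tgt = np.zeros((1, 2 * patch_size, 2 * patch_size))
            out.append(PatchPair(inp, tgt, source_id, (y, x)))
    return out


# ---------------------------------------------------------------------------
# background rejection
# ---------------------------------------------------------------------------

def reject_background(
    patch: np.ndarray,
    min_foreground_fraction: float = 0.01,
    mad_factor: float = 3.0,
) -> bool:
    """Keep a patch only when enough of it rises above the background.

    A pixel counts as foreground when its mean-over-frames intensity exceeds
    ``median + mad_factor * MAD``; the patch is kept when the foreground
    fraction is at least ``min_foreground_fraction``.  Setting the fraction
    to 0 keeps everything.  This automates the manual culling of
    background-only patches with a stated, reproducible rule.
    """
    if min_foreground_fraction <= 0:
        return True
    p = np.asarray(patch, dtype=float)
    img = p.mean(axis=0) if p.ndim == 3 else p
    med = np.median(img)
    mad = np.median(np.abs(img - med))
    thresh = med + mad_factor * max(mad, 1e-12)
    frac = np.mean(img > thresh)
    if not np.any(img > 0):
        return False
    return bool(frac >= min_foreground_fraction)


# ---------------------------------------------------------------------------
# 3-frame selection
# ---------------------------------------------------------------------------

def select_sim3_frames(frames: np.ndarray) -> np.ndarray:
    """Pick the first phase of each of the three angles from a 15-frame,
    angle-major stack (frames 0, 5 and 10)."""
    frames = np.asarray(frames)
    if frames.shape[0] != 15:
        raise ValueError(
            f"expected a 15-frame (3 angles x 5 phases) stack, got {frames.shape[0]} frames"
        )
    return frames[list(SIM3_FRAME_INDICES)].copy()


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_dataset(
    pairs: list[PatchPair],
    split: DatasetSplit | None = None,
) -> tuple[list[PatchPair], float, float]:
    """Scale inputs and targets by one scalar maximum per domain.

    The maxima are computed over the *training* portion only (all pairs when
    no split is given) and recorded on every pair, so the same constants can
    be re-applied at validation/test/inference time.
    """
    if not pairs:
        raise ValueError("empty dataset")
    idx = split.train if split is not None else range(len(pairs))
    input_max = max(float(pairs[i].input_patch.max()) for i in idx)
    target_max = max(float(pairs[i].target_patch.max()) for i in idx)
    if input_max <= 0 or target_max <= 0:
        raise ValueError("all-zero dataset: cannot normalize")
    out = []
    for p in pairs:
        out.append(
            dataclasses.replace(
                p,
                input_patch=p.input_patch / input_max,
                target_patch=p.target_patch / target_max,
                normalization=(input_max, target_max),
            )
        )
    return out, input_max, target_max


# ---------------------------------------------------------------------------
# resize
# ---------------------------------------------------------------------------

def resize_bicubic(patch: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Channel-wise 2-D bicubic resize of a (C, h, w) or (h, w) patch."""
    if target_h <= 0 or target_w <= 0:
        raise ValueError("target size must be positive")
    p = np.asarray(patch, dtype=np.float64)
    squeeze = p.ndim == 2
    if squeeze:
        p = p[None]
    if p.shape[1:] == (target_h, target_w):
        out = p.copy()
    else:
        out = np.stack(
            [
                _sk_resize(c, (target_h, target_w), order=3, mode="edge",
                           anti_aliasing=False, preserve_range=True)
                for c in p
            ]
        )
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(
    pairs: list[PatchPair],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Randomly split patch pairs into train/validation/test.

    Disjointness is enforced at the *source stack* level: all patches cut
    from one stack land in the same subset, so neighbouring patches can never
    straddle the train/test boundary.
    """
    if not pairs:
        raise ValueError("empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    sources = sorted({p.source_id for p in pairs})
    rng = np.random.default_rng(seed)
    rng.shuffle(sources)
    n = len(sources)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    groups = {
        s: ("train" if i < n_train else "validation" if i < n_train + n_val else "test")
        for i, s in enumerate(sources)
    }
    split = DatasetSplit([], [], [], seed=seed)
    for i, p in enumerate(pairs):
        getattr(split, {"train": "train", "validation": "validation", "test": "test"}[groups[p.source_id]]).append(i)
    return split


# ---------------------------------------------------------------------------
# persistence: TIFF pairs + CSV manifest
# ---------------------------------------------------------------------------

def save_dataset(ds: PatchDataset, directory: str | Path) -> Path:
    """Write patches as TIFF pairs plus a CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    member = {}
    if ds.split is not None:
        for name in ("train", "validation", "test"):
            for i in getattr(ds.split, name):
                member[i] = name
    for i, p in enumerate(ds.pairs):
        in_name = f"pair_{i:05d}_input.tif"
        tgt_name = f"pair_{i:05d}_target.tif"
        tifffile.imwrite(directory / in_name, p.input_patch.astype(np.float32),
                         photometric="minisblack")
        tifffile.imwrite(directory / tgt_name, p.target_patch.astype(np.float32),
                         photometric="minisblack")
        rows.append({
            "index": i, "input": in_name, "target": tgt_name,
            "source_id": p.source_id, "offset_y": p.offset[0], "offset_x": p.offset[1],
            "split": member.get(i, ""),
            "input_max": p.normalization[0], "target_max": p.normalization[1],
        })
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(directory: str | Path) -> PatchDataset:
    directory = Path(directory)
    df = pd.read_csv(directory / "manifest.csv", keep_default_na=False)
    pairs = []
    split = DatasetSplit([], [], [])
    has_split = False
    for _, row in df.iterrows():
        inp = tifffile.imread(directory / row["input"]).astype(np.float64)
        tgt = tifffile.imread(directory / row["target"]).astype(np.float64)
        if inp.ndim == 2:
            inp = inp[None]
        if tgt.ndim == 2:
            tgt = tgt[None]
        pairs.append(PatchPair(
            inp, tgt, str(row["source_id"]),
            (int(row["offset_y"]), int(row["offset_x"])),
            (float(row["input_max"]), float(row["target_max"])),
        ))
        if row["split"]:
            has_split = True
            getattr(split, row["split"]).append(int(row["index"]))
    ds = PatchDataset(pairs, split if has_split else None)
    if pairs:
        ds.input_max = pairs[0].normalization[0]
        ds.target_max = pairs[0].normalization[1]
    return ds
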