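"""Loss, Adam training loop, transfer learning and tiled inference."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..prep import DatasetSplit, PatchPair, resize_bicubic
from .autograd import Tensor
from .unet import Module, NetworkConfig, SCUNet, UNet, build_scunet, build_unet


@dataclass
class TrainingConfig:
    epochs: int = 50
    batch_size: int = 4
    learning_rate: float = 1e-4
    loss_variant: str = "l1_l2"    # or "as_printed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 1 and learning_rate > 0 required")
        if self.loss_variant not in ("l1_l2", "as_printed"):
            raise ValueError("loss_variant must be 'l1_l2' or 'as_printed'")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    wall_clock_s: float = 0.0
    config: TrainingConfig | None = None


def loss(U: Tensor | np.ndarray, V: Tensor | np.ndarray,
         variant: str = "l1_l2") -> Tensor:
    """Training loss between ground truth ``U`` and network output ``V``.

    Per-pixel mean of ``r + 5 r^2`` where ``r = U - V``.  The ``as_printed``
    variant keeps the first term *signed* (it can be negative and admits a
    biased minimizer at r = -0.1); ``l1_l2`` uses ``|r| + 5 r^2``, the
    absolute-value reading, and is the default for actual training.
    """
    if not isinstance(U, Tensor):
        U = Tensor(U)
    if not isinstance(V, Tensor):
        V = Tensor(V)
    if U.shape != V.shape:
        raise ValueError(f"shape mismatch {U.shape} vs {V.shape}")
    if variant not in ("as_printed", "l1_l2"):
        raise ValueError(f"unknown loss variant {variant!r}")
    r = U - V
    first = r.mean() if variant == "as_printed" else r.abs().mean()
    return first + 5.0 * r.square().mean()


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _eval_loss(net: Module, pairs: list[PatchPair], indices, variant: str) -> float:
    total, n = 0.0, 0
    for i in indices:
        x = Tensor(pairs[i].input_patch[None])
        y = net(x)
        total += float(loss(pairs[i].target_patch[None], y, variant).data)
        n += 1
    return total / max(n, 1)


def train(
    net: Module,
    pairs: list[PatchPair],
    split: DatasetSplit,
    config: TrainingConfig,
) -> TrainingHistory:
    """Train in place; retains the best-validation parameters.

    Deterministic given ``config.seed`` (batch order and all arithmetic are
    seeded and pure numpy).  Aborts on a NaN loss with a diagnostic.
    """
    import time

    if not split.train:
        raise ValueError("empty training split")
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    hist = TrainingHistory(config=config)
    best_val = np.inf
    best_state = None
    val_idx = split.validation or split.train
    for epoch in range(config.epochs):
        order = np.array(split.train)
        rng.shuffle(order)
        ep_loss, n_batches = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            batch = order[s: s + config.batch_size]
            x = Tensor(np.stack([pairs[i].input_patch for i in batch]))
            t = np.stack([pairs[i].target_patch for i in batch])
            opt.zero_grad()
            out = net(x)
            lo = loss(t, out, config.loss_variant)
            if not np.isfinite(lo.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: {lo.data}"
                )
            lo.backward()
            opt.step()
            ep_loss += float(lo.data)
            n_batches += 1
        vl = _eval_loss(net, pairs, val_idx, config.loss_variant)
        hist.train_loss.append(ep_loss / max(n_batches, 1))
        hist.val_loss.append(vl)
        if vl < best_val:
            best_val = vl
            best_state = net.state_dict()
    if best_state is not None:
        net.load_state_dict(best_state)
    hist.wall_clock_s = time.time() - t0
    return hist


def transfer_init(new_net: Module, checkpoint: "dict | str | Path") -> Module:
    """Initialize ``new_net`` with the parameters of a pre-trained model.

    The architectures must match exactly; mismatching layers are listed in
    the raised error.  Retraining the transferred model on a new structure
    typically needs an order of magnitude fewer samples and epochs than
    training from scratch.
    """
    state = checkpoint
    if isinstance(checkpoint, (str, Path)):
        state = load_checkpoint(checkpoint)["state"]
    elif isinstance(checkpoint, dict) and "state" in checkpoint:
        state = checkpoint["state"]
    new_net.load_state_dict(state)
    return new_net


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    net: Module,
    normalization: tuple[float, float] = (1.0, 1.0),
    training_seed: int = 0,
) -> None:
    """Single-archive checkpoint: parameters + config + normalization."""
    cfg = net.config
    meta = {
        "variant": cfg.variant, "c_in": cfg.c_in, "c_out": cfg.c_out,
        "depth": cfg.depth, "base_features": cfg.base_features,
        "seed": cfg.seed, "cross_skips": cfg.cross_skips,
        "input_max": normalization[0], "target_max": normalization[1],
        "training_seed": training_seed,
    }
    np.savez(path, __meta__=json.dumps(meta), **net.state_dict())


def load_checkpoint(path: str | Path) -> dict:
    with np.load(path) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = NetworkConfig(meta["variant"], meta["c_in"], meta["c_out"],
                        meta["depth"], meta["base_features"], meta["seed"],
                        meta["cross_skips"])
    net = build_scunet(cfg) if cfg.variant == "scunet" else build_unet(cfg)
    net.load_state_dict(state)
    return {
        "net": net, "state": state, "config": cfg,
        "normalization": (meta["input_max"], meta["target_max"]),
        "training_seed": meta["training_seed"],
    }


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _feather_window(h: int, w: int) -> np.ndarray:
    wy = np.hanning(h + 2)[1:-1]
    wx = np.hanning(w + 2)[1:-1]
    return np.outer(wy, wx)


def predict(
    net: Module,
    stack: np.ndarray,
    normalization: tuple[float, float],
    tile: int | None = None,
    overlap: int = 16,
    upsample: bool = True,
) -> np.ndarray:
    """Full-frame inference.

    The (C, H, W) raw stack is scaled by the stored input maximum, bicubic-
    upsampled 2x to the network grid (unless ``upsample=False``), processed
    in overlapping tiles blended with a feathered (raised-cosine) window and
    rescaled by the target maximum.  A single tile covering the whole frame
    is used when possible, in which case blending is exact pass-through.
    """
    if normalization is None:
        raise ValueError("normalization constants are required for inference")
    input_max, target_max = normalization
    x = np.asarray(stack, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    x = x / input_max
    if upsample:
        x = resize_bicubic(x, x.shape[1] * 2, x.shape[2] * 2)
    c, h, w = x.shape
    d = net.config.depth
    unit = 2 ** d
    if tile is None or (h <= tile and w <= tile):
        if h % unit == 0 and w % unit == 0:
            out = net(Tensor(x[None])).data[0]
            return np.clip(out, 0.0, None) * target_max
        tile = tile or max(unit, (min(h, w) // unit) * unit)
    tile = (tile // unit) * unit
    step = tile - overlap
    acc = None
    weight = None
    win = _feather_window(tile, tile)
    ys = sorted({min(y, h - tile) for y in range(0, h, step)})
    xs = sorted({min(xx, w - tile) for xx in range(0, w, step)})
    for y in ys:
        for xx in xs:
            patch = x[:, y: y + tile, xx: xx + tile]
            out = net(Tensor(patch[None])).data[0]
            if acc is None:
                acc = np.zeros((out.shape[0], h, w))
                weight = np.zeros((h, w))
            acc[:, y: y + tile, xx: xx + tile] += out * win
            weight[y: y + tile, xx: xx + tile] += win
    out = acc / np.maximum(weight, 1e-12)
    return np.clip(out, 0.0, None) * target_max
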