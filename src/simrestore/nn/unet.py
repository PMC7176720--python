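"""U-Net variants for SIM restoration.

All named models share one encoder–decoder architecture with skip
concatenations between matching scales and differ only in channel counts:

- ``unet_sim15``: 15 raw frames -> 1 super-resolution image
- ``unet_sim3``:   3 raw frames (first phase per angle) -> 1 image
- ``unet_snr``:   15 low-light frames -> 15 denoised frames
- ``unet_srrf5``:  5 TIRF frames -> 1 super-resolution image
- ``scunet``: two U-Nets chained end to end, with the first net's decoder
  feature maps additionally concatenated into the second net's encoder at
  matching scales.

Defaults: depth 4, 2 conv(3x3)+ReLU per level, 2x max-pool down,
2x transposed-conv up, feature count doubling per level.  The output layer
is a linear 1x1 convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, conv2d, conv_transpose2d, maxpool2

NAMED_CHANNELS = {
    "sim15": (15, 1),
    "sim3": (3, 1),
    "snr": (15, 15),
    "srrf5": (5, 1),
    "scunet": (15, 1),
}


@dataclass
class NetworkConfig:
    variant: str = "unet"          # "unet" or "scunet"
    c_in: int = 15
    c_out: int = 1
    depth: int = 4
    base_features: int = 64
    seed: int = 0
    cross_skips: bool = True       # scU-Net only: net1 decoder -> net2 encoder

    def __post_init__(self) -> None:
        if self.variant not in ("unet", "scunet"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.depth < 1 or self.base_features < 1:
            raise ValueError("depth and base_features must be >= 1")


class Module:
    """Base class: a named, ordered collection of parameter tensors."""

    def parameters(self) -> dict[str, Tensor]:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(int(np.prod(t.shape)) for t in self.parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = sorted(set(params) - set(state))
        extra = sorted(set(state) - set(params))
        bad_shapes = [
            k for k in params
            if k in state and tuple(state[k].shape) != tuple(params[k].shape)
        ]
        if missing or extra or bad_shapes:
            raise ValueError(
                "architecture mismatch — "
                f"missing: {missing}; unexpected: {extra}; shape mismatch: {bad_shapes}"
            )
        for k, t in params.items():
            t.data = np.asarray(state[k], dtype=t.data.dtype).copy()


def _he_conv(rng, f, c, k) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / (c * k * k)), size=(f, c, k, k))


class UNet(Module):
    """Encoder–decoder with skip concatenations between matching scales.

    ``extra_skip_channels[i]`` extends the encoder input at level i with
    externally supplied feature maps (used by the stacked variant); it is a
    tuple of zeros for a plain U-Net.
    """

    def __init__(self, config: NetworkConfig,
                 extra_skip_channels: tuple[int, ...] | None = None,
                 rng: np.random.Generator | None = None):
        self.config = config
        d, b = config.depth, config.base_features
        self.extra = tuple(extra_skip_channels or (0,) * (d + 1))
        if len(self.extra) != d + 1:
            raise ValueError("need one extra-channel entry per level incl. bottleneck")
        rng = rng or np.random.default_rng(config.seed)
        self._p: dict[str, Tensor] = {}

        def make_conv(name, f, c, k=3):
            self._p[f"{name}.w"] = Tensor(_he_conv(rng, f, c, k), requires_grad=True)
            self._p[f"{name}.b"] = Tensor(np.zeros(f), requires_grad=True)

        feat = lambda i: b * 2 ** i
        c_prev = config.c_in
        for i in range(d):
            make_conv(f"enc{i}.conv1", feat(i), c_prev + self.extra[i])
            make_conv(f"enc{i}.conv2", feat(i), feat(i))
            c_prev = feat(i)
        make_conv(f"bottleneck.conv1", feat(d), c_prev + self.extra[d])
        make_conv(f"bottleneck.conv2", feat(d), feat(d))
        for i in reversed(range(d)):
            # transposed-conv weight layout: (C_in, C_out, 2, 2)
            self._p[f"up{i}.w"] = Tensor(
                _he_conv(rng, feat(i + 1), feat(i), 2), requires_grad=True
            )
            self._p[f"up{i}.b"] = Tensor(np.zeros(feat(i)), requires_grad=True)
            make_conv(f"dec{i}.conv1", feat(i), feat(i) * 2)
            make_conv(f"dec{i}.conv2", feat(i), feat(i))
        make_conv("out", config.c_out, b, k=1)

    def parameters(self) -> dict[str, Tensor]:
        return self._p

    def _block(self, name: str, x: Tensor) -> Tensor:
        x = conv2d(x, self._p[f"{name}.conv1.w"], self._p[f"{name}.conv1.b"]).relu()
        return conv2d(x, self._p[f"{name}.conv2.w"], self._p[f"{name}.conv2.b"]).relu()

    def forward(self, x: Tensor, extra_inputs: list[Tensor] | None = None,
                return_decoder_feats: bool = False):
        d = self.config.depth
        h, w = x.shape[2], x.shape[3]
        if h % 2 ** d or w % 2 ** d:
            raise ValueError(
                f"spatial dims {h}x{w} must be divisible by 2^depth = {2 ** d}"
            )
        skips = []
        cur = x
        for i in range(d):
            if self.extra[i]:
                cur = concat([cur, extra_inputs[i]])
            cur = self._block(f"enc{i}", cur)
            skips.append(cur)
            cur = maxpool2(cur)
        if self.extra[d]:
            cur = concat([cur, extra_inputs[d]])
        cur = self._block("bottleneck", cur)
        dec_feats: dict[int, Tensor] = {}
        for i in reversed(range(d)):
            cur = conv_transpose2d(cur, self._p[f"up{i}.w"], self._p[f"up{i}.b"])
            cur = concat([cur, skips[i]])
            cur = self._block(f"dec{i}", cur)
            dec_feats[i] = cur
        out = conv2d(cur, self._p["out.w"], self._p["out.b"])
        if return_decoder_feats:
            return out, dec_feats
        return out

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class SCUNet(Module):
    """Two stacked U-Nets trained end to end.

    The first U-Net maps the low-light input stack to a same-channel
    restored stack; the second maps that to the final image.  With
    ``cross_skips`` the first net's decoder feature maps are concatenated
    into the second net's encoder at matching scales, giving the deeper
    network direct access to intermediate representations.
    """

    def __init__(self, config: NetworkConfig, c_mid: int | None = None):
        if config.variant != "scunet":
            raise ValueError("config.variant must be 'scunet'")
        self.config = config
        c_mid = c_mid if c_mid is not None else config.c_in
        rng = np.random.default_rng(config.seed)
        d, b = config.depth, config.base_features
        cfg1 = NetworkConfig("unet", config.c_in, c_mid, d, b, config.seed)
        cfg2 = NetworkConfig("unet", c_mid, config.c_out, d, b, config.seed)
        self.net1 = UNet(cfg1, rng=rng)
        extra = tuple(b * 2 ** i for i in range(d)) + (0,) if config.cross_skips \
            else (0,) * (d + 1)
        self.net2 = UNet(cfg2, extra_skip_channels=extra, rng=rng)

    def parameters(self) -> dict[str, Tensor]:
        out = {}
        out.update({f"net1.{k}": v for k, v in self.net1.parameters().items()})
        out.update({f"net2.{k}": v for k, v in self.net2.parameters().items()})
        return out

    def forward(self, x: Tensor) -> Tensor:
        mid, feats = self.net1.forward(x, return_decoder_feats=True)
        mid = mid.relu()
        if self.config.cross_skips:
            extra = [feats[i] for i in range(self.config.depth)] + [None]
            return self.net2.forward(mid, extra_inputs=extra)
        return self.net2.forward(mid)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def build_unet(config: NetworkConfig) -> UNet:
    """Construct a plain U-Net (deterministic parameters given config.seed)."""
    return UNet(config)


def build_scunet(config: NetworkConfig, c_mid: int | None = None) -> SCUNet:
    """Construct the stacked (skip-connected) double U-Net."""
    return SCUNet(config, c_mid=c_mid)


def build_named(name: str, depth: int = 4, base_features: int = 64,
                seed: int = 0) -> Module:
    """Build one of the named model variants by task name."""
    if name not in NAMED_CHANNELS:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(NAMED_CHANNELS)}")
    c_in, c_out = NAMED_CHANNELS[name]
    variant = "scunet" if name == "scunet" else "unet"
    cfg = NetworkConfig(variant, c_in, c_out, depth, base_features, seed)
    return build_scunet(cfg) if variant == "scunet" else build_unet(cfg)
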