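"""U-Net-style encoder-decoder for MP/background segmentation.

The network maps a 3-channel patch to a single-channel logit map of the
same spatial size.  The encoder halves resolution and doubles channel
width at each level; the decoder mirrors it with nearest-neighbour
upsampling, a channel-halving convolution, and a skip concatenation from
the matching encoder level.  All convolutions are 3x3 except the 1x1
output head.

Named presets mirror the loss/optimizer grid of the published comparison:
``unet1`` (BCE-with-logits + SGD), ``unet2`` (Dice+BCE + Adam), ``unet3``
(Dice + Adam) and ``unet4`` alias ``mp_net`` (Dice + SGD), the best
performer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .layers import Conv2d, MaxPool2, ReLU, UpsampleNearest2

__all__ = ["ModelConfig", "UNet", "build_model"]

PRESETS: dict[str, tuple[str, str]] = {
    "unet1": ("bce_logits", "sgd"),
    "unet2": ("dice_bce", "adam"),
    "unet3": ("dice", "adam"),
    "unet4": ("dice", "sgd"),
    "mp_net": ("dice", "sgd"),
}


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    ``base_width`` defaults to a desk-scale 16 channels; the published-scale
    topology is depth 4, width 64 on 256x256 patches.  Default learning
    rates: 0.1 with momentum 0.9 for SGD, 1e-3 for Adam.  Gradients are
    clipped to a global norm of ``max_grad_norm`` (None disables); without
    clipping, Dice + SGD is prone to collapsing onto the all-background
    prediction, where the saturated sigmoid kills the gradient.
    """

    depth: int = 4
    base_width: int = 16
    loss: str = "dice"
    optimizer: str = "sgd"
    lr: float | None = None
    momentum: float = 0.9
    max_grad_norm: float | None = 1.0
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("bce_logits", "dice", "dice_bce"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lr is None:
            self.lr = 0.1 if self.optimizer == "sgd" else 1e-3

    @classmethod
    def preset(cls, name: str, **kwargs) -> "ModelConfig":
        loss, opt = PRESETS[name.replace("-", "_")]
        return cls(loss=loss, optimizer=opt, **kwargs)


class _DoubleConv:
    """conv-relu-conv-relu block."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c1 = Conv2d(c_in, c_out, 3, rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(c_out, c_out, 3, rng)
        self.r2 = ReLU()
        self.layers = [self.c1, self.r1, self.c2, self.r2]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class UNet:
    """Encoder-decoder with skip connections; see module docstring."""

    def __init__(self, config: ModelConfig):
        if config.depth < 1:
            raise ValueError("depth must be >= 1")
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, w = config.depth, config.base_width

        self.enc = [
            _DoubleConv(3 if i == 0 else w * 2 ** (i - 1), w * 2**i, rng)
            for i in range(d)
        ]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = _DoubleConv(w * 2 ** (d - 1), w * 2**d, rng)
        self.ups = [UpsampleNearest2() for _ in range(d)]
        # channel-halving conv after upsampling, then double conv on the
        # concatenation with the skip
        self.up_convs = [Conv2d(w * 2 ** (i + 1), w * 2**i, 3, rng) for i in range(d)]
        self.up_relus = [ReLU() for _ in range(d)]
        self.dec = [_DoubleConv(w * 2 ** (i + 1), w * 2**i, rng) for i in range(d)]
        self.head = Conv2d(w, 1, 1, rng)

    # -- parameter plumbing -------------------------------------------------

    def _conv_layers(self) -> list[Conv2d]:
        convs: list[Conv2d] = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            convs += [blk.c1, blk.c2]
        convs += self.up_convs
        convs.append(self.head)
        return convs

    def parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, grad) triples for every trainable tensor."""
        out = []
        for i, conv in enumerate(self._conv_layers()):
            for key in ("w", "b"):
                out.append((f"conv{i}.{key}", conv.params[key], conv.grads[key]))
        return out

    def n_parameters(self) -> int:
        return sum(v.size for _, v, _ in self.parameters())

    def zero_grad(self) -> None:
        for conv in self._conv_layers():
            conv.zero_grad()

    def get_state(self) -> dict[str, np.ndarray]:
        return {name: value.copy() for name, value, _ in self.parameters()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for name, value, _ in self.parameters():
            value[...] = state[name]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """3-channel float patch batch (N,3,H,W) -> logit batch (N,1,H,W)."""
        d = self.config.depth
        h, w = x.shape[2], x.shape[3]
        if h % 2**d or w % 2**d:
            raise ValueError(f"patch size must be divisible by 2^{d}")
        skips = []
        for i in range(d):
            x = self.enc[i].forward(x)
            skips.append(x)
            x = self.pools[i].forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = [s.shape[1] for s in skips]
        for i in reversed(range(d)):
            x = self.ups[i].forward(x)
            x = self.up_relus[i].forward(self.up_convs[i].forward(x))
            x = np.concatenate([skips[i], x], axis=1)
            x = self.dec[i].forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.config.depth
        dy = self.head.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * d
        for i in range(d):
            dy = self.dec[i].backward(dy)
            c_skip = self._skip_channels[i]
            dskips[i] = dy[:, :c_skip]
            dy = self.up_convs[i].backward(self.up_relus[i].backward(dy[:, c_skip:]))
            dy = self.ups[i].backward(dy)
        dy = self.bottleneck.backward(dy)
        for i in reversed(range(d)):
            dy = self.pools[i].backward(dy)
            dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write parameters (.npz) plus a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self.get_state())
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        config = ModelConfig(**json.loads(sidecar.read_text()))
        model = cls(config)
        with np.load(path) as data:
            model.set_state({k: data[k] for k in data.files})
        return model


def build_model(config: ModelConfig) -> UNet:
    """Construct a seeded U-Net from a :class:`ModelConfig`."""
    return UNet(config)
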