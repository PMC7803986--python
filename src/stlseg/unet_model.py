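"""A configurable U-Net-style encoder-decoder implemented in numpy.

The network is a fully-convolutional encoder-decoder: ``depth`` encoder
blocks of two 3x3 same-padding convolutions (ReLU) followed by 2x2 max
pooling, a two-convolution bottleneck whose channel count is
``base_filters * 2**depth``, and mirrored decoder blocks (nearest-neighbour
x2 up-sampling + 2x2 up-convolution, skip concatenation, two 3x3
convolutions).  A replaceable 1x1-convolution classifier head maps the
top decoder features to ``C`` per-pixel class scores; softmax normalisation
happens in :meth:`SegmentationModel.forward_proba` (and inside the
training loss).  Filter counts double per encoder level and halve per
decoder level, so depth 4 yields the classic 23-convolution network and
depth 5 the extended 28-convolution variant with an 8x8x1024 bottleneck at
256x256 input.

Everything — forward pass, backward pass, parameter initialisation — is
plain numpy so the model is trainable and bit-reproducible on CPU.
Parameters use seeded He-normal initialisation (zero initialisation cannot
break symmetry and never trains).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

__all__ = [
    "NetworkConfig",
    "SegmentationModel",
    "build_unet",
    "replace_head",
    "extract_bottleneck",
    "save_model",
    "load_model",
]

_DTYPE = np.float32


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    ``bottleneck_channels`` is derived (``base_filters * 2**depth``) because
    filter counts double at every down-sampling step.
    """

    input_size: tuple[int, int] = (256, 256)
    base_filters: int = 32
    depth: int = 5
    head_classes: int = 66
    seed: int = 0
    bottleneck_channels: int = field(init=False)

    def __post_init__(self) -> None:
        self.bottleneck_channels = self.base_filters * 2 ** self.depth

    def to_dict(self) -> dict:
        return {
            "input_size": list(self.input_size),
            "base_filters": self.base_filters,
            "depth": self.depth,
            "head_classes": self.head_classes,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(
            input_size=tuple(d["input_size"]),
            base_filters=int(d["base_filters"]),
            depth=int(d["depth"]),
            head_classes=int(d["head_classes"]),
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# Layers (NCHW float32 throughout)
# ---------------------------------------------------------------------------

class Conv2D:
    """Same-padding convolution with hand-written backward pass.

    Forward and backward are a single GEMM each over an im2col layout,
    which is the fastest formulation for small kernels in numpy.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        std = np.sqrt(2.0 / (in_ch * ksize * ksize))
        self.w = rng.normal(0.0, std, size=(out_ch, in_ch, ksize, ksize)).astype(_DTYPE)
        self.b = np.zeros(out_ch, dtype=_DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {"w": self.dw, "b": self.db}

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix (same padding)."""
        k = self.ksize
        pb, pa = (k - 1) // 2, k // 2
        N, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pb, pa), (pb, pa)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * H * W, C * k * k
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        cols = self._im2col(x)
        self._cols = cols
        self._xshape = x.shape
        wmat = self.w.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.b
        return y.reshape(N, H, W, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.ksize
        pb, pa = (k - 1) // 2, k // 2
        N, C, H, W = self._xshape
        dy_mat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(
            N * H * W, self.out_ch
        )
        self.db = dy_mat.sum(axis=0)
        self.dw = (dy_mat.T @ self._cols).reshape(self.w.shape)
        dcols = dy_mat @ self.w.reshape(self.out_ch, -1)
        dcols = dcols.reshape(N, H, W, C, k, k)
        dxp = np.zeros((N, C, H + pb + pa, W + pb + pa), dtype=_DTYPE)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + H, dj:dj + W] += dcols[:, :, :, :, di, dj
                                                         ].transpose(0, 3, 1, 2)
        return dxp[:, :, pb:pb + H, pb:pb + W]


# leaky slope: keeps gradient flowing through inactive units, so channels
# that a coarse curriculum stage turns off stay revivable in later stages
LEAKY_SLOPE = 0.01


class ReLU:
    """Leaky rectifier (slope ``LEAKY_SLOPE`` on the negative side)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, LEAKY_SLOPE * x).astype(_DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, LEAKY_SLOPE * dy).astype(_DTYPE)


class MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(N, C, H // 2, W // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        onehot = np.eye(4, dtype=_DTYPE)[self._argmax]  # (N,C,H/2,W/2,4)
        dxr = dy[..., None] * onehot
        dxr = dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(N, C, H, W).astype(_DTYPE)


class Upsample2:
    """Nearest-neighbour x2 up-sampling (parameter-free)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H2, W2 = dy.shape
        return dy.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)).astype(_DTYPE)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class SegmentationModel:
    """U-Net-style network with a named layer registry.

    The registry maps names like ``enc1.conv2`` / ``bottleneck.conv1`` /
    ``dec1.upconv`` / ``head`` to :class:`Conv2D` layers; the head and the
    bottleneck tap are addressable by name so the classifier can be swapped
    and prototype features extracted.
    """

    HEAD_NAME = "head"
    BOTTLENECK_NAME = "bottleneck.conv2"

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        f, d = config.base_filters, config.depth
        self.conv_registry: dict[str, Conv2D] = {}
        self._relu: dict[str, ReLU] = {}
        self._pool = [MaxPool2() for _ in range(d)]
        self._up = [Upsample2() for _ in range(d)]

        def conv(name: str, cin: int, cout: int, k: int) -> None:
            self.conv_registry[name] = Conv2D(cin, cout, k, rng)
            self._relu[name] = ReLU()

        cin = 3
        for i in range(d):
            ch = f * 2 ** i
            conv(f"enc{i + 1}.conv1", cin, ch, 3)
            conv(f"enc{i + 1}.conv2", ch, ch, 3)
            cin = ch
        ch = f * 2 ** d
        conv("bottleneck.conv1", cin, ch, 3)
        conv("bottleneck.conv2", ch, ch, 3)
        cin = ch
        for i in reversed(range(d)):
            ch = f * 2 ** i
            conv(f"dec{i + 1}.upconv", cin, ch, 2)
            conv(f"dec{i + 1}.conv1", 2 * ch, ch, 3)
            conv(f"dec{i + 1}.conv2", ch, ch, 3)
            cin = ch
        self.conv_registry[self.HEAD_NAME] = Conv2D(cin, config.head_classes, 1, rng)
        self._last_bottleneck: np.ndarray | None = None

    # -- introspection ------------------------------------------------------

    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_registry)

    def parameters(self) -> dict[str, dict[str, np.ndarray]]:
        return {name: layer.params for name, layer in self.conv_registry.items()}

    def non_head_parameters(self) -> dict[str, dict[str, np.ndarray]]:
        return {
            name: layer.params
            for name, layer in self.conv_registry.items()
            if name != self.HEAD_NAME
        }

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        h, w = self.config.input_size
        if x.shape[2:] != (h, w):
            raise ValueError(
                f"input spatial size {x.shape[2:]} does not match the "
                f"configured size {(h, w)}"
            )

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """Forward pass on an NCHW float batch; returns (N, C, H, W) logits."""
        self._check_input(x)
        d = self.config.depth
        reg, relu = self.conv_registry, self._relu
        skips = []
        h = x.astype(_DTYPE)
        for i in range(d):
            h = relu[f"enc{i + 1}.conv1"].forward(reg[f"enc{i + 1}.conv1"].forward(h))
            h = relu[f"enc{i + 1}.conv2"].forward(reg[f"enc{i + 1}.conv2"].forward(h))
            skips.append(h)
            h = self._pool[i].forward(h)
        h = relu["bottleneck.conv1"].forward(reg["bottleneck.conv1"].forward(h))
        h = relu["bottleneck.conv2"].forward(reg["bottleneck.conv2"].forward(h))
        self._last_bottleneck = h
        self._skip_channels = [s.shape[1] for s in skips]
        for i in reversed(range(d)):
            h = self._up[i].forward(h)
            h = relu[f"dec{i + 1}.upconv"].forward(reg[f"dec{i + 1}.upconv"].forward(h))
            h = np.concatenate([skips[i], h], axis=1)
            h = relu[f"dec{i + 1}.conv1"].forward(reg[f"dec{i + 1}.conv1"].forward(h))
            h = relu[f"dec{i + 1}.conv2"].forward(reg[f"dec{i + 1}.conv2"].forward(h))
        return reg[self.HEAD_NAME].forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backward pass; leaves gradients on each conv layer's ``dw``/``db``."""
        d = self.config.depth
        reg, relu = self.conv_registry, self._relu
        g = reg[self.HEAD_NAME].backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * d
        for i in range(d):
            g = relu[f"dec{i + 1}.conv2"].backward(g)
            g = reg[f"dec{i + 1}.conv2"].backward(g)
            g = relu[f"dec{i + 1}.conv1"].backward(g)
            g = reg[f"dec{i + 1}.conv1"].backward(g)
            ch = self._skip_channels[i]
            dskips[i] = g[:, :ch]
            g = g[:, ch:]
            g = relu[f"dec{i + 1}.upconv"].backward(g)
            g = reg[f"dec{i + 1}.upconv"].backward(g)
            g = self._up[i].backward(g)
        g = relu["bottleneck.conv2"].backward(g)
        g = reg["bottleneck.conv2"].backward(g)
        g = relu["bottleneck.conv1"].backward(g)
        g = reg["bottleneck.conv1"].backward(g)
        for i in reversed(range(d)):
            g = self._pool[i].backward(g)
            g = g + dskips[i]
            g = relu[f"enc{i + 1}.conv2"].backward(g)
            g = reg[f"enc{i + 1}.conv2"].backward(g)
            g = relu[f"enc{i + 1}.conv1"].backward(g)
            g = reg[f"enc{i + 1}.conv1"].backward(g)

    # -- public prediction API (HWC uint8 patches) --------------------------

    @staticmethod
    def _to_nchw(patches: np.ndarray) -> np.ndarray:
        """HWC or NHWC uint8/float image(s) -> normalised NCHW float batch."""
        a = np.asarray(patches)
        if a.ndim == 3:
            a = a[None]
        x = a.astype(_DTYPE) / 255.0 - 0.5
        return x.transpose(0, 3, 1, 2)

    def forward_proba(self, patches: np.ndarray) -> np.ndarray:
        """Per-pixel softmax class probabilities, shape (N, H, W, C)."""
        logits = self.forward_logits(self._to_nchw(patches))
        return softmax_channels(logits).transpose(0, 2, 3, 1)

    def predict_labels(self, patches: np.ndarray) -> np.ndarray:
        """Per-pixel argmax labels, shape (N, H, W)."""
        logits = self.forward_logits(self._to_nchw(patches))
        return logits.argmax(axis=1)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis of (N, C, H, W)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Construction, head replacement, feature tap
# ---------------------------------------------------------------------------

def build_unet(config: NetworkConfig) -> SegmentationModel:
    """Build a seeded network for the given configuration.

    The input size must be divisible by ``2**depth`` so every pooling step
    halves the resolution exactly.
    """
    h, w = config.input_size
    div = 2 ** config.depth
    if h % div or w % div:
        raise ValueError(
            f"input size {config.input_size} must be divisible by "
            f"2**depth = {div} for {config.depth} pooling steps"
        )
    if config.head_classes < 2:
        raise ValueError("head_classes must be >= 2")
    rng = np.random.default_rng(config.seed)
    return SegmentationModel(config, rng)


# scale applied to a replacement head's seeded He draw: a swapped-in head
# starts with near-zero logits (near-uniform predictions), so the first
# steps of a new stage adapt the classifier to the carried features instead
# of back-propagating confidently-wrong gradients through them
HEAD_REINIT_SCALE = 0.01


def replace_head(model: SegmentationModel, C: int, seed: int) -> SegmentationModel:
    """Return a copy with a freshly initialised C-way 1x1-convolution head.

    All non-head parameters are carried over unchanged (exact equality);
    only the classifier is re-drawn from ``seed``, at a small magnitude
    (``HEAD_REINIT_SCALE``) so the new stage starts near-uniform.
    """
    if C < 2:
        raise ValueError(f"head must have at least 2 classes, got {C}")
    cfg = copy.deepcopy(model.config)
    cfg.head_classes = C
    new = SegmentationModel(cfg, np.random.default_rng(0))
    for name, layer in model.conv_registry.items():
        if name == model.HEAD_NAME:
            continue
        new.conv_registry[name].w = layer.w.copy()
        new.conv_registry[name].b = layer.b.copy()
    head_in = model.conv_registry[model.HEAD_NAME].in_ch
    head = Conv2D(head_in, C, 1, np.random.default_rng(seed))
    head.w *= HEAD_REINIT_SCALE
    new.conv_registry[new.HEAD_NAME] = head
    return new


def extract_bottleneck(model: SegmentationModel, patch: np.ndarray):
    """Deepest encoder activation for one patch, as an H'xW'xD feature volume.

    H' = H / 2**depth and D = ``bottleneck_channels``; for the full-size
    configuration (256x256, depth 5, base 32) this is 8x8x1024.
    """
    from .feature_analysis import FeatureVolume

    h, w = model.config.input_size
    if patch.shape[:2] != (h, w):
        raise ValueError(
            f"patch size {patch.shape[:2]} does not match model input {(h, w)}"
        )
    model.forward_logits(model._to_nchw(patch))
    vol = model._last_bottleneck[0].transpose(1, 2, 0).copy()
    return FeatureVolume(values=vol, source_class=0, source_patch="")


# ---------------------------------------------------------------------------
# Persistence (HDF5 weights + YAML config sidecar)
# ---------------------------------------------------------------------------

def save_model(model: SegmentationModel, path: str | Path) -> Path:
    """Persist weights to one HDF5 file; config in a YAML sidecar (.yaml)."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        for name, layer in model.conv_registry.items():
            grp = fh.create_group(name)
            grp.create_dataset("w", data=layer.w)
            grp.create_dataset("b", data=layer.b)
        fh.attrs["config"] = yaml.safe_dump(model.config.to_dict())
    path.with_suffix(".yaml").write_text(yaml.safe_dump(model.config.to_dict()))
    return path


def load_model(path: str | Path) -> SegmentationModel:
    path = Path(path)
    with h5py.File(path, "r") as fh:
        config = NetworkConfig.from_dict(yaml.safe_load(fh.attrs["config"]))
        model = SegmentationModel(config, np.random.default_rng(config.seed))
        for name, layer in model.conv_registry.items():
            layer.w = fh[name]["w"][...].astype(_DTYPE)
            layer.b = fh[name]["b"][...].astype(_DTYPE)
    return model
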