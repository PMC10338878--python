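"""LDSE-NET: lightweight densely connected regression network with
Tanh-gated squeeze-and-excitation channel attention.

Architecture (input: a C x S x S defocused tile):

    stem:   7x7 conv, stride 2, pad 3 -> BN -> ReLU -> 3x3 max pool, stride 2
    body:   [dense block -> transition] x n_blocks
    attend: squeeze-excitation on the final feature map (Tanh gate)
    head:   global average pooling -> fully connected -> 1 scalar

Each dense-block layer sees the channel concatenation of the block input
and every previous layer's output and contributes ``growth_rate_k`` new
channels (feature reuse); transitions compress channels by a fixed
reduction and halve the spatial size with 2x2 average pooling, using Tanh
as the pre-activation.  The excitation gate is Tanh rather than the usual
sigmoid, so channel gates live in (-1, 1) and may flip a channel's sign.

The scalar output is trained against defocus distance normalised to
[-1, 1] over the configured axial range; ``predict_um`` applies the
inverse scaling.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from ldsefocus.nn.layers import (
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Tanh,
)

__all__ = [
    "LDSENetConfig",
    "DenseLayer",
    "DenseBlock",
    "Transition",
    "SqueezeExcitation",
    "LDSENet",
    "squeeze",
    "excitation",
    "scale",
    "model_size_bytes",
]


@dataclass(frozen=True)
class LDSENetConfig:
    """Hyperparameters of the network.

    Attributes
    ----------
    input_channels : image channels (3 for RGB micrographs)
    input_size : square tile side in pixels fed to the stem
    stem_channels : channels produced by the 7x7 stem convolution
    layers_per_block : dense layers in each block (its length is the
        number of blocks)
    growth_rate_k : channels each dense layer adds to the concatenation
    transition_reduction : channel compression factor of each transition
    se_reduction_r : bottleneck ratio of the excitation MLP (width
        ceil(C / r))
    se_gate : "tanh" (default) or "sigmoid" for ablation
    z_half_range_um : defocus magnitude mapped to +/-1 in label scaling
    """

    input_channels: int = 3
    input_size: int = 224
    stem_channels: int = 24
    layers_per_block: tuple[int, ...] = (4, 4, 4)
    growth_rate_k: int = 12
    transition_reduction: float = 0.5
    se_reduction_r: int = 4
    se_gate: str = "tanh"
    z_half_range_um: float = 10.0

    def __post_init__(self):
        if self.input_channels < 1 or self.growth_rate_k < 1 or self.stem_channels < 1:
            raise ValueError("channel counts must be positive")
        if not 0 < self.transition_reduction <= 1:
            raise ValueError("transition_reduction must lie in (0, 1]")
        if self.se_gate not in ("tanh", "sigmoid"):
            raise ValueError("se_gate must be 'tanh' or 'sigmoid'")
        object.__setattr__(self, "layers_per_block", tuple(int(n) for n in self.layers_per_block))

    @property
    def n_dense_blocks(self) -> int:
        return len(self.layers_per_block)

    def channel_plan(self) -> list[int]:
        """Channels entering each block and after the final transition.

        Dense concatenation arithmetic: a block entered with C0 channels
        exits with ``C0 + L * k``; transitions floor-compress by the
        reduction factor.
        """
        plan = [self.stem_channels]
        c = self.stem_channels
        for n_layers in self.layers_per_block:
            c = c + n_layers * self.growth_rate_k
            c = max(1, math.floor(c * self.transition_reduction))
            plan.append(c)
        return plan


# --- squeeze / excitation / scale primitives -------------------------------

def squeeze(u: np.ndarray) -> np.ndarray:
    """Channel descriptor by global average pooling.

    ``Z_m = (1 / (H W)) * sum_ij u_m(i, j)`` for each channel m; accepts a
    single ``(C, H, W)`` map or a batch ``(N, C, H, W)``.
    """
    if u.ndim == 3:
        return u.mean(axis=(1, 2))
    return u.mean(axis=(2, 3))


def _gate(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(x)
    return 1.0 / (1.0 + np.exp(-x))


def excitation(z: np.ndarray, W1: np.ndarray, W2: np.ndarray,
               b1: np.ndarray | None = None, b2: np.ndarray | None = None,
               gate: str = "tanh") -> np.ndarray:
    """Channel gates ``S = gate(W2 . relu(W1 . z))``.

    ``W1`` maps C -> ceil(C/r) and ``W2`` back to C.  The Tanh gate keeps
    S in (-1, 1); gates are applied per channel by :func:`scale`.
    """
    z = np.asarray(z, dtype=float)
    h = W1 @ z
    if b1 is not None:
        h = h + b1
    h = np.maximum(h, 0.0)
    s = W2 @ h
    if b2 is not None:
        s = s + b2
    return _gate(s, gate)


def scale(u: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Rescale channel m of ``u`` by gate ``s_m`` elementwise."""
    s = np.asarray(s)
    if u.ndim == 3:
        if s.shape != (u.shape[0],):
            raise ValueError(f"gate length {s.shape} does not match {u.shape[0]} channels")
        return u * s[:, None, None]
    if s.ndim == 1:
        if s.shape != (u.shape[1],):
            raise ValueError(f"gate length {s.shape} does not match {u.shape[1]} channels")
        return u * s[None, :, None, None]
    if s.shape != u.shape[:2]:
        raise ValueError(f"gate shape {s.shape} does not match {u.shape[:2]}")
    return u * s[:, :, None, None]


# --- composite modules -----------------------------------------------------

class DenseLayer(Module):
    """Pre-activation composite BN -> ReLU -> 3x3 conv emitting k channels."""

    def __init__(self, in_ch: int, growth_rate: int, rng, name: str, dtype=np.float32):
        self.bn = BatchNorm2d(in_ch, name=f"{name}.bn", dtype=dtype)
        self.act = ReLU()
        self.conv = Conv2d(in_ch, growth_rate, kernel=3, stride=1, pad=1,
                           rng=rng, name=f"{name}.conv", dtype=dtype)

    def forward(self, x, train=True):
        return self.conv(self.act(self.bn(x, train), train), train)

    def backward(self, grad):
        return self.bn.backward(self.act.backward(self.conv.backward(grad)))


class DenseBlock(Module):
    """Stack of dense layers with channel concatenation between them.

    Layer L receives ``[X0, X1, ..., X_{L-1}]`` (block input plus every
    previous layer's output) and appends its own ``growth_rate`` channels.
    """

    def __init__(self, in_ch: int, n_layers: int, growth_rate: int, rng, name: str, dtype=np.float32):
        self.layers = [
            DenseLayer(in_ch + i * growth_rate, growth_rate, rng, f"{name}.layer{i}", dtype=dtype)
            for i in range(n_layers)
        ]
        self.in_ch = in_ch
        self.growth_rate = growth_rate
        self.out_ch = in_ch + n_layers * growth_rate

    def forward(self, x, train=True):
        for layer in self.layers:
            y = layer(x, train)
            x = np.concatenate([x, y], axis=1)
        return x

    def backward(self, grad):
        k = self.growth_rate
        for layer in reversed(self.layers):
            grad, gy = grad[:, :-k], grad[:, -k:]
            grad = grad + layer.backward(np.ascontiguousarray(gy))
        return grad


class Transition(Module):
    """BN -> Tanh -> 1x1 conv (channel compression) -> 2x2 average pool."""

    def __init__(self, in_ch: int, reduction: float, rng, name: str, dtype=np.float32):
        self.out_ch = max(1, math.floor(in_ch * reduction))
        self.bn = BatchNorm2d(in_ch, name=f"{name}.bn", dtype=dtype)
        self.act = Tanh()
        self.conv = Conv2d(in_ch, self.out_ch, kernel=1, rng=rng, name=f"{name}.conv", dtype=dtype)
        self.pool = AvgPool2d(2)

    def forward(self, x, train=True):
        return self.pool(self.conv(self.act(self.bn(x, train), train), train), train)

    def backward(self, grad):
        return self.bn.backward(self.act.backward(self.conv.backward(self.pool.backward(grad))))


class SqueezeExcitation(Module):
    """Channel attention: squeeze -> bottleneck MLP -> gate -> rescale."""

    def __init__(self, channels: int, reduction_r: int, rng, gate: str = "tanh",
                 name: str = "se", dtype=np.float32):
        bottleneck = max(1, math.ceil(channels / reduction_r))
        self.fc1 = Linear(channels, bottleneck, rng=rng, name=f"{name}.fc1", dtype=dtype)
        self.relu = ReLU()
        self.fc2 = Linear(bottleneck, channels, rng=rng, name=f"{name}.fc2", dtype=dtype)
        self.gate_kind = gate
        self.channels = channels
        self.bottleneck = bottleneck

    def forward(self, u, train=True):
        z = u.mean(axis=(2, 3))  # squeeze
        s = _gate(self.fc2(self.relu(self.fc1(z, train), train), train), self.gate_kind)
        self._cache = (u, s)
        return u * s[:, :, None, None]

    def backward(self, grad):
        u, s = self._cache
        du = grad * s[:, :, None, None]
        ds = (grad * u).sum(axis=(2, 3))
        if self.gate_kind == "tanh":
            dpre = ds * (1.0 - s**2)
        else:
            dpre = ds * s * (1.0 - s)
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(dpre)))
        h, w = u.shape[2], u.shape[3]
        du = du + dz[:, :, None, None] / (h * w)
        return du


class LDSENet(Module):
    """The full regression network; see module docstring for the layout."""

    def __init__(self, config: LDSENetConfig | None = None, seed: int = 0, dtype=np.float32):
        cfg = config or LDSENetConfig()
        rng = np.random.default_rng(seed)
        self.config = cfg
        self.dtype = dtype

        self.stem_conv = Conv2d(cfg.input_channels, cfg.stem_channels, kernel=7,
                                stride=2, pad=3, rng=rng, name="stem.conv", dtype=dtype)
        self.stem_bn = BatchNorm2d(cfg.stem_channels, name="stem.bn", dtype=dtype)
        self.stem_act = ReLU()
        self.stem_pool = MaxPool2d(kernel=3, stride=2, pad=1)

        self.blocks: list[Module] = []
        c = cfg.stem_channels
        for bi, n_layers in enumerate(cfg.layers_per_block):
            block = DenseBlock(c, n_layers, cfg.growth_rate_k, rng, f"block{bi}", dtype=dtype)
            trans = Transition(block.out_ch, cfg.transition_reduction, rng, f"trans{bi}", dtype=dtype)
            self.blocks.extend([block, trans])
            c = trans.out_ch
        self.feature_channels = c

        self.se = SqueezeExcitation(c, cfg.se_reduction_r, rng, gate=cfg.se_gate, dtype=dtype)
        self.gap = GlobalAvgPool()
        self.head = Linear(c, 1, rng=rng, name="head", dtype=dtype)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Normalised defocus prediction for a batch ``(N, C, S, S)``."""
        if x.ndim != 4 or x.shape[1] != self.config.input_channels:
            raise ValueError(
                f"expected (N, {self.config.input_channels}, S, S) input, got {x.shape}"
            )
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise ValueError(
                f"expected {self.config.input_size}x{self.config.input_size} tiles, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        h = self.stem_pool(self.stem_act(self.stem_bn(self.stem_conv(x, train), train), train), train)
        for mod in self.blocks:
            h = mod(h, train)
        h = self.se(h, train)
        self._head_spatial = h.shape[2:]
        return self.head(self.gap(h, train), train)[:, 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.gap.backward(self.head.backward(grad[:, None]))
        g = self.se.backward(g)
        for mod in reversed(self.blocks):
            g = mod.backward(g)
        g = self.stem_conv.backward(self.stem_bn.backward(self.stem_act.backward(self.stem_pool.backward(g))))
        return g

    # -- user-facing prediction --------------------------------------------

    def predict_um(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Defocus distance in micrometres for tiles ``(N, C, S, S)``.

        Runs in inference mode (batch-norm running statistics) and applies
        the inverse label scaling.
        """
        images = np.asarray(images, dtype=self.dtype)
        if images.ndim == 3:
            images = images[None]
        outs = []
        for i in range(0, len(images), batch_size):
            outs.append(self.forward(images[i : i + batch_size], train=False))
        return np.concatenate(outs) * self.config.z_half_range_um

    def normalize_labels(self, z_um: np.ndarray) -> np.ndarray:
        return np.asarray(z_um, dtype=self.dtype) / self.config.z_half_range_um

    # -- bookkeeping ---------------------------------------------------------

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {f"param:{p.name}": p.value for p in self.parameters()}
        for name, buf in self.buffers():
            arrays[f"buffer:{name}"] = buf
        return arrays

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p.value[...] = w

    def get_buffers(self) -> list[np.ndarray]:
        return [b.copy() for _, b in self.buffers()]

    def set_buffers(self, buffers: list[np.ndarray]) -> None:
        for (_, b), new in zip(self.buffers(), buffers, strict=True):
            b[...] = new

    def buffers(self):
        yield from self.stem_bn.buffers()
        for i, mod in enumerate(self.blocks):
            for name, buf in mod.buffers():
                yield f"blocks.{i}.{name}", buf

    def parameters(self):
        yield from self.stem_conv.parameters()
        yield from self.stem_bn.parameters()
        for mod in self.blocks:
            yield from mod.parameters()
        yield from self.se.parameters()
        yield from self.head.parameters()

    # -- checkpointing -------------------------------------------------------

    def save(self, path) -> None:
        """Write weights, running stats and full config to one archive."""
        meta = json.dumps(asdict(self.config))
        arrays = self.state_arrays()
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "LDSENet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            meta["layers_per_block"] = tuple(meta["layers_per_block"])
            net = cls(LDSENetConfig(**meta))
            for p in net.parameters():
                p.value[...] = data[f"param:{p.name}"]
            for name, buf in net.buffers():
                buf[...] = data[f"buffer:{name}"]
        return net


def model_size_bytes(config: LDSENetConfig) -> int:
    """Float32 storage of all trainable parameters (4 bytes each)."""
    return 4 * LDSENet(config).n_parameters()
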