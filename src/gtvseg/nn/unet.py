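"""2D attention U-Net for binary slice segmentation, in numpy.

The network follows the encoder/decoder layout with additive attention gates
on the skip connections.  A basic convolutional block is

    batch-norm -> conv 3x3 -> leaky ReLU(0.1) -> conv 3x3 -> leaky ReLU(0.1)

with batch normalization prefixed to every block (encoder, bottleneck and
decoder alike).  The encoder stacks ``depth`` such blocks, each followed by
2x2 max pooling, doubling the channel count per level from ``base_channels``;
one block forms the bottleneck; the decoder mirrors the encoder with
nearest-neighbour 2x upsampling and an attention-gated skip merge per level,
so a depth-4 configuration has 9 blocks in total.  The head is a single 1x1
convolution with a sigmoid, producing per-pixel foreground probabilities.

The additive attention gate computes, per pixel,

    alpha = sigmoid( psi( relu( W_x * skip + up(W_g * gating) + b ) ) )

where ``gating`` is the coarser decoder-side feature one level below, the
inter-channel width of W_x / W_g is half the skip channel count, and the
gated skip is ``skip * alpha``.  Gates expose ``force_alpha`` so tests can
pin the coefficients (alpha = 1 recovers a plain U-Net skip).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .layers import (
    DTYPE,
    Adam,
    BatchNorm2d,
    Conv2d,
    Layer,
    LeakyReLU,
    MaxPool2x2,
    ReLU,
    Sigmoid,
    UpsampleNearest2x,
)


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    input_size : side length in pixels of the (square) input slices; must be
        divisible by 2**depth.
    depth : number of encoder (= decoder) blocks.
    base_channels : filter count of the first encoder block; doubles per level.
    leaky_alpha : negative-slope of the leaky ReLU activations.
    use_attention : gate the skip connections (False gives a plain U-Net).
    seed : weight-initialization seed.
    """

    input_size: int = 512
    depth: int = 4
    base_channels: int = 16
    leaky_alpha: float = 0.1
    use_attention: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2 ** self.depth}"
            )
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        return cls(**json.loads(s))


class ConvBlock:
    """batch-norm -> (conv3x3 -> leaky ReLU) x 2."""

    def __init__(self, c_in: int, c_out: int, alpha: float, rng: np.random.Generator):
        self.bn = BatchNorm2d(c_in)
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.act1 = LeakyReLU(alpha)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.act2 = LeakyReLU(alpha)
        self._layers = [("bn", self.bn), ("conv1", self.conv1), ("act1", self.act1),
                        ("conv2", self.conv2), ("act2", self.act2)]

    def forward(self, x, train=False):
        for _, layer in self._layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for _, layer in reversed(self._layers):
            dout = layer.backward(dout)
        return dout

    def named_layers(self):
        return self._layers


class AttentionGate:
    """Additive attention gate acting on one skip connection."""

    def __init__(self, c_skip: int, c_gate: int, rng: np.random.Generator):
        width = max(1, c_skip // 2)
        self.conv_x = Conv2d(c_skip, width, 1, rng)
        self.conv_g = Conv2d(c_gate, width, 1, rng)
        self.psi = Conv2d(width, 1, 1, rng)
        self.relu = ReLU()
        self.sigmoid = Sigmoid()
        self.up = UpsampleNearest2x()
        self.force_alpha: float | None = None  # test hook: pin alpha to a constant
        self.last_alpha: np.ndarray | None = None
        self._cache = None

    def forward(self, skip, gating, train=False):
        if self.force_alpha is not None:
            alpha = np.full((skip.shape[0], 1) + skip.shape[2:], self.force_alpha, dtype=DTYPE)
        else:
            gx = self.up.forward(self.conv_g.forward(gating, train), train)
            xx = self.conv_x.forward(skip, train)
            a = self.relu.forward(gx + xx, train)
            alpha = self.sigmoid.forward(self.psi.forward(a, train), train)
        self.last_alpha = alpha
        if train:
            self._cache = (skip, alpha)
        return skip * alpha

    def backward(self, dout):
        skip, alpha = self._cache
        dskip = dout * alpha
        if self.force_alpha is not None:
            return dskip, None
        dalpha = (dout * skip).sum(axis=1, keepdims=True)
        da = self.psi.backward(self.sigmoid.backward(dalpha))
        da = self.relu.backward(da)
        dskip = dskip + self.conv_x.backward(da)
        dgate = self.conv_g.backward(self.up.backward(da))
        return dskip, dgate

    def named_layers(self):
        return [("conv_x", self.conv_x), ("conv_g", self.conv_g), ("psi", self.psi)]


class AttentionUNet:
    """The full segmentation network; see module docstring for the layout."""

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        base, depth, alpha = config.base_channels, config.depth, config.leaky_alpha

        self.encoder_blocks: list[ConvBlock] = []
        self.pools: list[MaxPool2x2] = []
        c_in = 1
        for lvl in range(depth):
            c_out = base * 2 ** lvl
            self.encoder_blocks.append(ConvBlock(c_in, c_out, alpha, rng))
            self.pools.append(MaxPool2x2())
            c_in = c_out
        self.bottleneck_block = ConvBlock(c_in, base * 2 ** depth, alpha, rng)

        self.ups: list[UpsampleNearest2x] = []
        self.gates: list[AttentionGate | None] = []
        self.decoder_blocks: list[ConvBlock] = []
        for lvl in reversed(range(depth)):
            c_skip = base * 2 ** lvl
            c_deep = base * 2 ** (lvl + 1)
            self.ups.append(UpsampleNearest2x())
            self.gates.append(AttentionGate(c_skip, c_deep, rng) if config.use_attention else None)
            self.decoder_blocks.append(ConvBlock(c_deep + c_skip, c_skip, alpha, rng))
        self.head = Conv2d(base, 1, 1, rng)
        self.out_act = Sigmoid()

        self._named = list(self._iter_named_layers())
        self._cache = None

    # ----- bookkeeping -------------------------------------------------
    def _iter_named_layers(self):
        for i, blk in enumerate(self.encoder_blocks):
            for name, layer in blk.named_layers():
                yield f"enc{i}.{name}", layer
        for name, layer in self.bottleneck_block.named_layers():
            yield f"bottleneck.{name}", layer
        for i, blk in enumerate(self.decoder_blocks):
            gate = self.gates[i]
            if gate is not None:
                for name, layer in gate.named_layers():
                    yield f"gate{i}.{name}", layer
            for name, layer in blk.named_layers():
                yield f"dec{i}.{name}", layer
        yield "head", self.head

    @property
    def blocks(self) -> list[ConvBlock]:
        """All convolutional blocks: depth encoder + 1 bottleneck + depth decoder."""
        return [*self.encoder_blocks, self.bottleneck_block, *self.decoder_blocks]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, layer in self._named:
            for pname, arr in layer.params.items():
                out[f"{prefix}.{pname}"] = arr
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, layer in self._named:
            for pname, arr in layer.grads.items():
                out[f"{prefix}.{pname}"] = arr
        return out

    @property
    def parameter_count(self) -> int:
        return sum(arr.size for arr in self.parameters().values())

    def set_bn_frozen(self, frozen: bool) -> None:
        """Freeze/unfreeze batch-norm statistics (the fine-tuning guard)."""
        for _, layer in self._named:
            if isinstance(layer, BatchNorm2d):
                layer.frozen_stats = frozen

    def state_dict(self) -> dict[str, np.ndarray]:
        """Trainable parameters plus batch-norm running statistics (copies)."""
        out = {k: v.copy() for k, v in self.parameters().items()}
        for prefix, layer in self._named:
            if isinstance(layer, BatchNorm2d):
                out[f"{prefix}.running_mean"] = layer.running_mean.copy()
                out[f"{prefix}.running_var"] = layer.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for key, arr in state.items():
            if key.endswith(".running_mean") or key.endswith(".running_var"):
                prefix, stat = key.rsplit(".", 1)
                layer = dict(self._named)[prefix]
                setattr(layer, stat, np.asarray(arr, dtype=DTYPE).copy())
            else:
                if key not in params:
                    raise ValueError(f"unknown parameter {key!r} in state")
                if params[key].shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {key!r}: model {params[key].shape}, state {arr.shape}"
                    )
                params[key][...] = arr

    # ----- forward / backward ------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (N, H, W) images in [0,1] to (N, H, W) probabilities in (0,1)."""
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3:
            raise ValueError("expected a batch of 2D slices (N, H, W)")
        n, h, w = x.shape
        if h != self.config.input_size or w != self.config.input_size:
            raise ValueError(
                f"input spatial size {h}x{w} does not match configured "
                f"{self.config.input_size}x{self.config.input_size}"
            )
        h_feat = x[:, None, :, :]
        skips = []
        for blk, pool in zip(self.encoder_blocks, self.pools):
            s = blk.forward(h_feat, train)
            skips.append(s)
            h_feat = pool.forward(s, train)
        h_feat = self.bottleneck_block.forward(h_feat, train)

        split_sizes = []
        for i, lvl in enumerate(reversed(range(self.config.depth))):
            skip = skips[lvl]
            up = self.ups[i].forward(h_feat, train)
            gate = self.gates[i]
            gated = skip if gate is None else gate.forward(skip, h_feat, train)
            split_sizes.append((up.shape[1], gated.shape[1]))
            h_feat = self.decoder_blocks[i].forward(np.concatenate([up, gated], axis=1), train)
        logits = self.head.forward(h_feat, train)
        prob = self.out_act.forward(logits, train)
        if train:
            self._cache = split_sizes
        return prob[:, 0]

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probabilities), filling every layer's grads."""
        split_sizes = self._cache
        depth = self.config.depth
        d = self.head.backward(self.out_act.backward(np.asarray(dprob, dtype=DTYPE)[:, None]))
        dskip_gate: dict[int, np.ndarray] = {}
        # decoder stages in reverse construction order (shallow to deep)
        for i in range(depth - 1, -1, -1):
            lvl = depth - 1 - i  # encoder level this decoder stage merges with
            dcat = self.decoder_blocks[i].backward(d)
            c_up, _ = split_sizes[i]
            dup, dgated = dcat[:, :c_up], dcat[:, c_up:]
            gate = self.gates[i]
            if gate is None:
                dskip = dgated
                dgate = None
            else:
                dskip, dgate = gate.backward(dgated)
            dskip_gate[lvl] = dskip
            d = self.ups[i].backward(dup)
            if dgate is not None:
                d = d + dgate
        d = self.bottleneck_block.backward(d)
        # encoder, deep to shallow
        for lvl in range(depth - 1, -1, -1):
            dskip = self.pools[lvl].backward(d) + dskip_gate[lvl]
            d = self.encoder_blocks[lvl].backward(dskip)

    # ----- persistence --------------------------------------------------
    def save(self, path, provenance: dict | None = None) -> None:
        meta = {"config": asdict(self.config), "provenance": provenance or {}, "format_version": 1}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> tuple["AttentionUNet", dict]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        net = cls(NetworkConfig(**meta["config"]))
        net.load_state_dict(state)
        return net, meta.get("provenance", {})


__all__ = ["NetworkConfig", "AttentionUNet", "ConvBlock", "AttentionGate", "Adam"]
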