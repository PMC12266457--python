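"""The two segmentation architectures.

``CustomUNet`` is a four-level (configurable) encoder–decoder with skip
connections: each encoder block is two 3x3 convolutions + ReLU (He-normal
init) followed by 2x2 max-pooling and 20 % dropout, filters doubling from
``base_filters`` (16 by default) to ``base_filters * 2**depth`` at the
bottleneck; each decoder level is a 2x2 stride-2 transposed convolution,
concatenation of the matching encoder feature map, dropout, and two
convolutions; a 1x1 convolution plus per-pixel softmax produces the
2-class probability map.

``UNetGRU`` shares the encoder/decoder recipe at ``base_filters`` 64
(bottleneck 1024) but inserts a recurrent stage at the bottleneck: the
h x w x C bottleneck map is flattened row-major into a sequence of h*w
C-dimensional vectors, processed by a unidirectional GRU (512 units by
default) emitting one vector per position, and reshaped back to
h x w x units before the decoder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .layers import (Conv2D, ConvTranspose2x2, Dropout, GRU, Layer, MaxPool2x2,
                     ReLU, softmax)
from .losses import categorical_crossentropy, crossentropy_grad_logits
from .optim import Adam


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    ``bottleneck_filters`` and (for the GRU variant) ``gru_units`` default
    to ``base_filters * 2**depth`` and ``base_filters * 2**(depth-1)``
    respectively, which reproduces the published scales: 16 -> 256 for the
    plain variant and 64 -> 1024 with a 512-unit GRU for the recurrent one.
    """

    architecture: str = "custom_unet"
    input_hw: tuple = (256, 256)
    in_channels: int = 3
    n_classes: int = 2
    base_filters: int | None = None
    depth: int = 4
    gru_units: int | None = None
    dropout: float = 0.2
    kernel: int = 3
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.architecture not in ("custom_unet", "unet_gru"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.base_filters is None:
            self.base_filters = 16 if self.architecture == "custom_unet" else 64
        h, w = self.input_hw
        if h % (1 << self.depth) or w % (1 << self.depth):
            raise ValueError(
                f"input_hw {self.input_hw} must be divisible by 2^depth = {1 << self.depth}")
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")

    @property
    def bottleneck_filters(self) -> int:
        return self.base_filters * (1 << self.depth)

    @property
    def encoder_filters(self) -> list[int]:
        return [self.base_filters << i for i in range(self.depth)]

    @property
    def decoder_filters(self) -> list[int]:
        return [self.base_filters << i for i in range(self.depth - 1, -1, -1)]

    def resolved_gru_units(self) -> int:
        return self.gru_units if self.gru_units is not None else (
            self.base_filters << (self.depth - 1))


class ConvBlock(Layer):
    """Two kxk convolutions, each followed by ReLU."""

    def __init__(self, cin, cout, k, rng, dtype, name):
        self.c1 = Conv2D(cin, cout, k, rng, dtype, f"{name}.c1")
        self.r1 = ReLU()
        self.c2 = Conv2D(cout, cout, k, rng, dtype, f"{name}.c2")
        self.r2 = ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x, train=False):
        x = self.r1.forward(self.c1.forward(x, train), train)
        return self.r2.forward(self.c2.forward(x, train), train)

    def backward(self, d):
        d = self.c2.backward(self.r2.backward(d))
        return self.c1.backward(self.r1.backward(d))


class _UNetBase:
    """Shared encoder/decoder machinery."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.dtype = np.dtype(spec.dtype).type
        self._build()

    # -- construction -----------------------------------------------------
    def _build_encoder(self):
        k, d = self.spec.kernel, self.spec.dropout
        cin = self.spec.in_channels
        self.enc_blocks, self.pools, self.enc_drops = [], [], []
        for i, f in enumerate(self.spec.encoder_filters):
            self.enc_blocks.append(ConvBlock(cin, f, k, self.rng, self.dtype, f"enc{i}"))
            self.pools.append(MaxPool2x2())
            self.enc_drops.append(Dropout(d, self.rng))
            cin = f
        return cin

    def _build_decoder(self, cin):
        k, d = self.spec.kernel, self.spec.dropout
        self.upconvs, self.dec_drops, self.dec_blocks = [], [], []
        for j, f in enumerate(self.spec.decoder_filters):
            self.upconvs.append(ConvTranspose2x2(cin, f, self.rng, self.dtype, f"up{j}"))
            self.dec_drops.append(Dropout(d, self.rng))
            skip_f = self.spec.encoder_filters[self.spec.depth - 1 - j]
            self.dec_blocks.append(
                ConvBlock(f + skip_f, f, k, self.rng, self.dtype, f"dec{j}"))
            cin = f
        self.head = Conv2D(cin, self.spec.n_classes, 1, self.rng, self.dtype, "head")

    # -- parameters -------------------------------------------------------
    def layers(self) -> list[Layer]:
        raise NotImplementedError

    def params(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self) -> dict:
        return {p.name: p.value.copy() for p in self.params()}

    def set_weights(self, weights: dict) -> None:
        for p in self.params():
            p.value[...] = weights[p.name]

    def save_weights(self, path) -> None:
        """Checkpoint: npz of parameters plus a JSON sidecar with the spec."""
        np.savez(path, **self.get_weights())
        with open(str(path) + ".json", "w") as fh:
            json.dump(asdict(self.spec), fh, indent=1)

    def load_weights(self, path) -> None:
        with np.load(path) as npz:
            self.set_weights({k: npz[k] for k in npz.files})

    def layer_inventory(self) -> dict:
        """Counts of structural layers, for contract checks."""
        inv: dict[str, int] = {}
        for layer in self.layers():
            inv[type(layer).__name__] = inv.get(type(layer).__name__, 0) + 1
        inv["skip_concat"] = len(self.dec_blocks)
        return inv

    # -- forward/backward shared paths ------------------------------------
    def _encode(self, x, train):
        skips = []
        for blk, pool, drop in zip(self.enc_blocks, self.pools, self.enc_drops):
            x = blk.forward(x, train)
            skips.append(x)
            x = drop.forward(pool.forward(x, train), train)
        return x, skips

    def _decode(self, x, skips, train):
        self._skip_channels = []
        for up, drop, blk, skip in zip(self.upconvs, self.dec_drops, self.dec_blocks,
                                       reversed(skips)):
            x = up.forward(x, train)
            if x.shape[:3] != skip.shape[:3]:
                raise AssertionError(
                    f"skip shape {skip.shape} does not match decoder {x.shape}")
            self._skip_channels.append((x.shape[3], skip.shape[3]))
            x = np.concatenate([x, skip], axis=3)
            x = drop.forward(x, train)
            x = blk.forward(x, train)
        logits = self.head.forward(x, train)
        return softmax(logits)

    def _decode_backward(self, dlogits):
        d = self.head.backward(dlogits)
        dskips = []
        for up, drop, blk, (cu, cs) in zip(reversed(self.upconvs), reversed(self.dec_drops),
                                           reversed(self.dec_blocks),
                                           reversed(self._skip_channels)):
            d = blk.backward(d)
            d = drop.backward(d)
            dskips.append(d[..., cu:])
            d = up.backward(d[..., :cu])
        # iterating the decoder in reverse visits the shallowest skip first,
        # so dskips is already in encoder order
        return d, dskips

    def _encode_backward(self, d, dskips):
        for blk, pool, drop, dskip in zip(reversed(self.enc_blocks), reversed(self.pools),
                                          reversed(self.enc_drops), reversed(dskips)):
            d = pool.backward(drop.backward(d))
            d = blk.backward(d + dskip)
        return d


class CustomUNet(_UNetBase):
    """Plain encoder–decoder with skip connections (base 16, bottleneck 256)."""

    def _build(self):
        cin = self._build_encoder()
        k, d = self.spec.kernel, self.spec.dropout
        self.bottleneck = ConvBlock(cin, self.spec.bottleneck_filters, k, self.rng,
                                    self.dtype, "bottleneck")
        self.bottleneck_drop = Dropout(d, self.rng)
        self._build_decoder(self.spec.bottleneck_filters)

    def layers(self):
        return (self.enc_blocks + self.pools + self.enc_drops
                + [self.bottleneck, self.bottleneck_drop]
                + self.upconvs + self.dec_drops + self.dec_blocks + [self.head])

    def forward(self, x, train: bool = False):
        x = np.asarray(x, dtype=self.dtype)
        x, skips = self._encode(x, train)
        x = self.bottleneck_drop.forward(self.bottleneck.forward(x, train), train)
        if train:
            self._skips_shapes = [s.shape for s in skips]
        return self._decode(x, skips, train)

    def backward(self, dlogits):
        """Backprop from d(loss)/d(logits) (softmax+CCE combined)."""
        d, dskips = self._decode_backward(dlogits)
        d = self.bottleneck.backward(self.bottleneck_drop.backward(d))
        return self._encode_backward(d, dskips)

    @property
    def bottleneck_hw(self):
        h, w = self.spec.input_hw
        s = 1 << self.spec.depth
        return (h // s, w // s)


class UNetGRU(_UNetBase):
    """UNet encoder/decoder with a GRU over the flattened bottleneck.

    The bottleneck feature map (h x w x C) is read row-major as a sequence
    of h*w vectors; the GRU emits one ``units``-vector per position which
    is reshaped back to (h x w x units) and decoded.
    """

    def _build(self):
        cin = self._build_encoder()
        k, d = self.spec.kernel, self.spec.dropout
        self.bottleneck = ConvBlock(cin, self.spec.bottleneck_filters, k, self.rng,
                                    self.dtype, "bottleneck")
        self.bottleneck_drop = Dropout(d, self.rng)
        self.gru = GRU(self.spec.bottleneck_filters, self.spec.resolved_gru_units(),
                       self.rng, self.dtype, "gru")
        self._build_decoder(self.spec.resolved_gru_units())

    def layers(self):
        return (self.enc_blocks + self.pools + self.enc_drops
                + [self.bottleneck, self.bottleneck_drop, self.gru]
                + self.upconvs + self.dec_drops + self.dec_blocks + [self.head])

    @property
    def bottleneck_hw(self):
        h, w = self.spec.input_hw
        s = 1 << self.spec.depth
        return (h // s, w // s)

    @property
    def sequence_length(self):
        h, w = self.bottleneck_hw
        return h * w

    def forward(self, x, train: bool = False):
        x = np.asarray(x, dtype=self.dtype)
        x, skips = self._encode(x, train)
        x = self.bottleneck_drop.forward(self.bottleneck.forward(x, train), train)
        n, h, w, c = x.shape
        seq = x.reshape(n, h * w, c)            # row-major flattening
        seq = self.gru.forward(seq, train)
        x = seq.reshape(n, h, w, self.gru.units)
        self._bneck_hw = (h, w, c)
        return self._decode(x, skips, train)

    def backward(self, dlogits):
        d, dskips = self._decode_backward(dlogits)
        n = d.shape[0]
        h, w, c = self._bneck_hw
        dseq = self.gru.backward(d.reshape(n, h * w, self.gru.units))
        d = dseq.reshape(n, h, w, c)
        d = self.bottleneck.backward(self.bottleneck_drop.backward(d))
        return self._encode_backward(d, dskips)


def build_custom_unet(spec: ModelSpec | None = None, **overrides) -> CustomUNet:
    spec = spec or ModelSpec(architecture="custom_unet", **overrides)
    if spec.architecture != "custom_unet":
        raise ValueError("spec.architecture must be 'custom_unet'")
    return CustomUNet(spec)


def build_unet_gru(spec: ModelSpec | None = None, **overrides) -> UNetGRU:
    spec = spec or ModelSpec(architecture="unet_gru", **overrides)
    if spec.architecture != "unet_gru":
        raise ValueError("spec.architecture must be 'unet_gru'")
    return UNetGRU(spec)


def build_model(spec: ModelSpec):
    return build_custom_unet(spec) if spec.architecture == "custom_unet" else build_unet_gru(spec)


class TrainableModel:
    """A built model bundled with Adam and the cross-entropy objective."""

    def __init__(self, model, lr: float = 1e-4):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.model = model
        self.optimizer = Adam(model.params(), lr=lr)

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    @lr.setter
    def lr(self, value: float) -> None:
        self.optimizer.lr = value

    def train_step(self, x, y_onehot):
        """One Adam step on a batch; returns (loss, probabilities)."""
        probs = self.model.forward(x, train=True)
        loss = categorical_crossentropy(probs, y_onehot)
        self.optimizer.zero_grad()
        self.model.backward(crossentropy_grad_logits(probs, y_onehot))
        self.optimizer.step()
        return loss, probs

    def evaluate(self, x, y_onehot):
        """Loss and probabilities without dropout or weight updates."""
        probs = self.model.forward(x, train=False)
        return categorical_crossentropy(probs, y_onehot), probs


def compile_model(model, lr: float = 1e-4) -> TrainableModel:
    """Attach the training configuration (Adam at ``lr``, categorical
    cross-entropy on one-hot masks) to a built model."""
    return TrainableModel(model, lr=lr)
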