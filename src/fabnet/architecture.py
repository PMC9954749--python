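"""The feature-agglomeration network: declarative spec and compiled model.

The network is a sequence of convolutional blocks B1..Bn. Each block runs two
parallel convolutions (5x5 and 3x3, stride 1, zero padding, ReLU), channel-
concatenates them, reduces with a 1x1 convolution, applies batch
normalization and a final ReLU. Blocks are fused in consecutive pairs
((B1,B2), (B3,B4), ...): within a pair the first block's output feeds the
second, the two block outputs are concatenated, and a 2x2 stride-2 average
pool downsamples the fusion. The pooled fusion is both the next pair's input
and a stage tap (C1..C5). All stage taps are average-pooled down to the final
spatial size, concatenated (the stage-C5 fusion), globally average-pooled and
classified by a single dense softmax head.

The default 10-block network uses parallel filter counts
(16, 32, 32, 64, 64, 128, 128, 256, 256, 512) so that every pair follows an
(f, 2f) progression, and 1x1 reduction widths ``min(filters, 32)`` which keep
the whole binary model at ~2.19 M trainable parameters — 30 convolution
layers in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "ConvBlockSpec",
    "ArchitectureSpec",
    "FeatureShape",
    "ArchitectureError",
    "default_fabnet_spec",
    "tiny_fabnet_spec",
    "build_model",
    "count_conv_layers",
    "count_trainable_parameters",
    "parameter_count_formula",
    "infer_feature_shapes",
    "FabNetModel",
]

_DEFAULT_FILTERS = (16, 32, 32, 64, 64, 128, 128, 256, 256, 512)
_ALLOWED_FILTERS = {16, 32, 64, 128, 256, 512}


class ArchitectureError(ValueError):
    """Invalid architecture specification or shape."""


@dataclass(frozen=True)
class ConvBlockSpec:
    """One convolutional block: two parallel convs, 1x1 reduce, batch norm."""

    index: int
    filters_parallel: int
    reduce_width: int
    use_batch_norm: bool = True
    activation: str = "relu"

    def __post_init__(self):
        if self.index < 1:
            raise ArchitectureError("block index must be >= 1")
        if self.filters_parallel < 1 or self.reduce_width < 1:
            raise ArchitectureError("filter counts must be positive")
        if self.reduce_width > 2 * self.filters_parallel:
            raise ArchitectureError(
                "reduce_width cannot exceed the concatenated width "
                f"(got {self.reduce_width} > 2*{self.filters_parallel})"
            )
        if self.activation != "relu":
            raise ArchitectureError(f"unsupported activation {self.activation!r}")


@dataclass(frozen=True)
class FeatureShape:
    height: int
    width: int
    channels: int

    def __post_init__(self):
        if min(self.height, self.width, self.channels) < 1:
            raise ArchitectureError("feature shape components must be positive")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of the agglomerative network."""

    blocks: tuple[ConvBlockSpec, ...]
    pairs: tuple[tuple[int, int], ...]
    pool: str = "average"
    stage_taps: tuple[str, ...] = ()
    head_classes: int = 2
    input_shape: tuple[int, int, int] = (224, 224, 3)

    def __post_init__(self):
        if self.head_classes < 2:
            raise ArchitectureError("head_classes must be >= 2")
        if self.pool != "average":
            raise ArchitectureError("only average pooling is supported")
        indices = [b.index for b in self.blocks]
        if indices != list(range(1, len(self.blocks) + 1)):
            raise ArchitectureError("blocks must be numbered 1..n in order")
        paired = [i for pair in self.pairs for i in pair]
        if sorted(paired) != indices:
            raise ArchitectureError("every block index must appear in exactly one pair")
        for a, b in self.pairs:
            if b != a + 1 or a % 2 != 1:
                raise ArchitectureError("pairs must be consecutive (odd, even) blocks")
        if len(self.stage_taps) != len(self.pairs):
            raise ArchitectureError("number of stage taps must equal number of pairs")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def block(self, index: int) -> ConvBlockSpec:
        return self.blocks[index - 1]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blocks"] = [asdict(b) for b in self.blocks]
        d["pairs"] = [list(p) for p in self.pairs]
        d["stage_taps"] = list(self.stage_taps)
        d["input_shape"] = list(self.input_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            blocks=tuple(ConvBlockSpec(**b) for b in d["blocks"]),
            pairs=tuple((int(a), int(b)) for a, b in d["pairs"]),
            pool=d.get("pool", "average"),
            stage_taps=tuple(d["stage_taps"]),
            head_classes=int(d["head_classes"]),
            input_shape=tuple(int(v) for v in d["input_shape"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ArchitectureSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_fabnet_spec(head_classes: int = 2, reduce_cap: int = 32) -> ArchitectureSpec:
    """The canonical 10-block network (B1..B10, pairs fused into stages C1..C5).

    Parameters
    ----------
    head_classes
        Width of the dense softmax head (2 for benign/malignant, 8 for the
        breast subtypes, 9 for the colorectal classes).
    reduce_cap
        Cap on the per-block 1x1 reduction width: ``reduce_width =
        min(filters_parallel, reduce_cap)``.
    """
    if head_classes < 2:
        raise ArchitectureError("head_classes must be >= 2")
    blocks = tuple(
        ConvBlockSpec(index=i + 1, filters_parallel=f, reduce_width=min(f, reduce_cap))
        for i, f in enumerate(_DEFAULT_FILTERS)
    )
    for b in blocks:
        if b.filters_parallel not in _ALLOWED_FILTERS:
            raise ArchitectureError(f"unexpected default filter count {b.filters_parallel}")
    n_pairs = len(blocks) // 2
    return ArchitectureSpec(
        blocks=blocks,
        pairs=tuple((2 * i + 1, 2 * i + 2) for i in range(n_pairs)),
        stage_taps=tuple(f"C{i + 1}" for i in range(n_pairs)),
        head_classes=head_classes,
    )


def tiny_fabnet_spec(
    head_classes: int = 2,
    filters: tuple[int, ...] = (8, 16),
    reduce_cap: int = 8,
    input_size: int = 32,
) -> ArchitectureSpec:
    """A reduced variant (fewer blocks/filters) for CPU-scale work.

    Same block/pair/stage topology as the full network, scaled down.
    """
    if len(filters) % 2:
        raise ArchitectureError("filters must come in pairs")
    blocks = tuple(
        ConvBlockSpec(index=i + 1, filters_parallel=f, reduce_width=min(f, reduce_cap))
        for i, f in enumerate(filters)
    )
    n_pairs = len(blocks) // 2
    return ArchitectureSpec(
        blocks=blocks,
        pairs=tuple((2 * i + 1, 2 * i + 2) for i in range(n_pairs)),
        stage_taps=tuple(f"C{i + 1}" for i in range(n_pairs)),
        head_classes=head_classes,
        input_shape=(input_size, input_size, 3),
    )


# ---------------------------------------------------------------------------
# pure shape/parameter accounting (no model required)


def _pair_channel_trace(spec: ArchitectureSpec):
    """Yield (pair_idx, in_ch_first, in_ch_second, fused_ch) walking the pairs."""
    in_ch = spec.input_shape[2]
    for p, (a, b) in enumerate(spec.pairs):
        ra = spec.block(a).reduce_width
        rb = spec.block(b).reduce_width
        yield p, in_ch, ra, ra + rb
        in_ch = ra + rb


def infer_feature_shapes(
    spec: ArchitectureSpec, input_shape: FeatureShape | None = None
) -> dict[str, FeatureShape]:
    """Deterministic shape trace for every block, fusion, pool, tap and head.

    Raises :class:`ArchitectureError` if the input spatial size is not
    divisible by ``2**n_pairs``.
    """
    if input_shape is None:
        h, w, c = spec.input_shape
        input_shape = FeatureShape(h, w, c)
    h, w = input_shape.height, input_shape.width
    div = 2 ** spec.n_pairs
    if h % div or w % div:
        raise ArchitectureError(
            f"input spatial size ({h},{w}) not divisible by 2^{spec.n_pairs}"
        )
    shapes: dict[str, FeatureShape] = {"input": input_shape}
    for p, in_a, in_b, fused in _pair_channel_trace(spec):
        a, b = spec.pairs[p]
        ra, rb = spec.block(a).reduce_width, spec.block(b).reduce_width
        shapes[f"B{a}"] = FeatureShape(h, w, ra)
        shapes[f"B{b}"] = FeatureShape(h, w, rb)
        shapes[f"fuse{p + 1}"] = FeatureShape(h, w, fused)
        h, w = h // 2, w // 2
        shapes[f"pool{p + 1}"] = FeatureShape(h, w, fused)
        shapes[spec.stage_taps[p]] = FeatureShape(h, w, fused)
    tap_channels = sum(shapes[t].channels for t in spec.stage_taps)
    shapes["stage_fusion"] = FeatureShape(h, w, tap_channels)
    shapes["gap"] = FeatureShape(1, 1, tap_channels)
    shapes["head"] = FeatureShape(1, 1, spec.head_classes)
    return shapes


def count_conv_layers(spec: ArchitectureSpec) -> int:
    """Number of convolution layers: two parallel plus one 1x1 per block."""
    return 3 * len(spec.blocks)


def parameter_count_formula(spec: ArchitectureSpec) -> int:
    """Closed-form trainable-parameter total from the spec alone.

    Per block with input channels c, parallel filters f, reduce width r:
    5x5 conv 25cf+f, 3x3 conv 9cf+f, 1x1 conv 2fr+r, batch norm 2r.
    Head: dense over the concatenated tap channels. Pooling layers and the
    stage bridges are parameter-free.
    """
    total = 0
    for p, in_a, in_b, fused in _pair_channel_trace(spec):
        for idx, c in zip(spec.pairs[p], (in_a, in_b)):
            blk = spec.block(idx)
            f, r = blk.filters_parallel, blk.reduce_width
            total += 25 * c * f + f          # 5x5 conv
            total += 9 * c * f + f           # 3x3 conv
            total += 2 * f * r + r           # 1x1 reduce
            if blk.use_batch_norm:
                total += 2 * r               # BN scale + shift
    tap_channels = sum(
        spec.block(a).reduce_width + spec.block(b).reduce_width for a, b in spec.pairs
    )
    total += tap_channels * spec.head_classes + spec.head_classes
    return total


# ---------------------------------------------------------------------------
# compiled model


class _Block:
    """Compiled conv block: parallel 5x5/3x3 -> concat -> 1x1 -> BN -> ReLU."""

    def __init__(self, c_in: int, spec: ConvBlockSpec, rng: np.random.Generator):
        f, r = spec.filters_parallel, spec.reduce_width
        self.conv5 = nn.Conv2D(c_in, f, 5, rng)
        self.conv3 = nn.Conv2D(c_in, f, 3, rng)
        self.conv1 = nn.Conv2D(2 * f, r, 1, rng)
        self.bn = nn.BatchNorm2D(r) if spec.use_batch_norm else None
        self.f = f
        self._cache = None

    @property
    def layers(self):
        out = [self.conv5, self.conv3, self.conv1]
        if self.bn is not None:
            out.append(self.bn)
        return out

    def forward(self, x, training=False):
        a5 = self.conv5.forward(x, training)
        a3 = self.conv3.forward(x, training)
        cat = np.concatenate([nn.relu(a5), nn.relu(a3)], axis=1)
        z = self.conv1.forward(cat, training)
        if self.bn is not None:
            z = self.bn.forward(z, training)
        if training:
            self._cache = (a5, a3, z)
        return nn.relu(z)

    def backward(self, dout):
        a5, a3, z = self._cache
        dz = nn.relu_backward(dout, z)
        if self.bn is not None:
            dz = self.bn.backward(dz)
        dcat = self.conv1.backward(dz)
        d5 = nn.relu_backward(dcat[:, : self.f], a5)
        d3 = nn.relu_backward(dcat[:, self.f :], a3)
        return self.conv5.backward(d5) + self.conv3.backward(d3)


class FabNetModel:
    """A spec compiled to trainable NumPy layers.

    Forward topology: pairs of blocks with intra-pair feeding, pair fusion by
    concatenation, 2x2 average pooling, parameter-free average-pool bridges
    carrying every stage tap to the final spatial size, stage concatenation,
    global average pooling, dense softmax head.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.blocks: list[_Block] = []
        for p, in_a, in_b, fused in _pair_channel_trace(spec):
            a, b = spec.pairs[p]
            self.blocks.append(_Block(in_a, spec.block(a), rng))
            self.blocks.append(_Block(in_b, spec.block(b), rng))
        self.pool = nn.AvgPool2x2()
        self.gap = nn.GlobalAvgPool()
        tap_channels = sum(
            spec.block(a).reduce_width + spec.block(b).reduce_width
            for a, b in spec.pairs
        )
        self.tap_channels_each = [
            spec.block(a).reduce_width + spec.block(b).reduce_width
            for a, b in spec.pairs
        ]
        self.head = nn.Dense(tap_channels, spec.head_classes, rng)
        self._cache = None

    # -- bookkeeping -------------------------------------------------------

    @property
    def layers(self):
        out = []
        for blk in self.blocks:
            out.extend(blk.layers)
        out.append(self.head)
        return out

    @property
    def conv_layers(self):
        return [l for l in self.layers if isinstance(l, nn.Conv2D)]

    def n_trainable_parameters(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def state_arrays(self):
        """Flat list of (name, array) for checkpointing / determinism checks."""
        out = []
        for i, blk in enumerate(self.blocks):
            for j, layer in enumerate(blk.layers):
                for key, val in layer.params.items():
                    out.append((f"block{i}.layer{j}.{key}", val))
                if isinstance(layer, nn.BatchNorm2D):
                    out.append((f"block{i}.layer{j}.running_mean", layer.running_mean))
                    out.append((f"block{i}.layer{j}.running_var", layer.running_var))
        for key, val in self.head.params.items():
            out.append((f"head.{key}", val))
        return out

    def save(self, path: str | Path) -> None:
        np.savez(path, **dict(self.state_arrays()))

    def load(self, path: str | Path) -> None:
        data = np.load(path)
        for name, arr in self.state_arrays():
            arr[...] = data[name]

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch of NCHW images (float in [0,1] expected)."""
        n_pairs = self.spec.n_pairs
        taps = []
        cur = x
        for p in range(n_pairs):
            a_out = self.blocks[2 * p].forward(cur, training)
            b_out = self.blocks[2 * p + 1].forward(a_out, training)
            fused = np.concatenate([a_out, b_out], axis=1)
            pooled = self.pool.forward(fused)
            taps.append(pooled)
            cur = pooled
        final_hw = taps[-1].shape[2]
        bridged = []
        for t in taps:
            while t.shape[2] > final_hw:
                t = self.pool.forward(t)
            bridged.append(t)
        stage = np.concatenate(bridged, axis=1)
        pooled_flat = self.gap.forward(stage, training)
        logits = self.head.forward(pooled_flat, training)
        if training:
            self._cache = (x.shape, [t.shape for t in taps], stage.shape)
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, training=False))

    def backward(self, dlogits: np.ndarray) -> None:
        """Backprop from head gradients; accumulates into layer grads."""
        x_shape, tap_shapes, stage_shape = self._cache
        dflat = self.head.backward(dlogits)
        n, c_stage = stage_shape[0], stage_shape[1]
        hw = tap_shapes[-1][2]
        dstage = np.broadcast_to(
            dflat[:, :, None, None], (n, c_stage, hw, hw)
        ) / (hw * hw)
        # split stage gradient back into per-tap bridge gradients
        dtaps = []
        off = 0
        for p, ch in enumerate(self.tap_channels_each):
            d = dstage[:, off : off + ch]
            off += ch
            # invert the bridge poolings: upsample back to the tap's size
            while d.shape[2] < tap_shapes[p][2]:
                d = np.repeat(np.repeat(d, 2, axis=2), 2, axis=3) / 4.0
            dtaps.append(np.ascontiguousarray(d))
        dnext = None
        for p in reversed(range(self.spec.n_pairs)):
            dpooled = dtaps[p] if dnext is None else dtaps[p] + dnext
            dfused = np.repeat(np.repeat(dpooled, 2, axis=2), 2, axis=3) / 4.0
            ra = self.spec.block(self.spec.pairs[p][0]).reduce_width
            da_out = dfused[:, :ra].copy()
            db_out = dfused[:, ra:]
            da_out += self.blocks[2 * p + 1].backward(db_out)
            dnext = self.blocks[2 * p].backward(da_out)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


def build_model(spec: ArchitectureSpec, seed: int = 0) -> FabNetModel:
    """Compile an :class:`ArchitectureSpec` to a trainable model.

    Validates that the input spatial size survives the pair poolings (raises
    :class:`ArchitectureError` otherwise) and seeds every parameter tensor.
    """
    infer_feature_shapes(spec)  # raises on non-divisible spatial sizes
    return FabNetModel(spec, seed=seed)


def count_trainable_parameters(model: FabNetModel) -> int:
    """Total trainable scalars (conv w+b, BN scale+shift, dense w+b)."""
    return model.n_trainable_parameters()
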