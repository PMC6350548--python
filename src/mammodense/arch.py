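"""Declarative architecture specs for ASPP-FC-DenseNet and FC-DenseNet.

The networks are described as ordered lists of blocks with explicit
channel, stride and dilation bookkeeping, independent of any tensor
backend.  The encoder halves resolution once per transition using a
stride-2 convolution in place of pooling; the decoder mirrors it with
stride-2 transposed convolutions and skip concatenations.  The
bottleneck is either an atrous-spatial-pyramid-pooling (ASPP) block —
parallel dilated convolutions at several sampling rates whose outputs
are fused — or a plain dense block (the FC-DenseNet baseline).

Layer counting follows the FC-DenseNet convention: the initial
convolution, every dense-layer convolution, one unit per transition in
each path, the ASPP convolutions (or bottleneck dense layers) and the
final classifier convolution.  With growth rate 12, 4 layers per dense
block and 4 transitions the ASPP variant has 47 counted layers; the
5-transition dense-bottleneck baseline has 56.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

CONV_KINDS = ("conv", "transposed_conv")
LAYER_KINDS = CONV_KINDS + ("batch_norm", "relu", "dropout", "softmax", "concat")


# ---------------------------------------------------------------------------
# dilation arithmetic

def effective_kernel_size(k: int, r: int) -> int:
    """Side length of a k x k kernel dilated at sampling rate r.

    Dilation inserts ``r - 1`` zeros between consecutive taps, enlarging
    the support to ``k + (k - 1)(r - 1)`` without adding parameters; a
    3x3 kernel at rates 2 and 3 covers 5x5 and 7x7 receptive fields.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"kernel side must be odd and positive, got {k}")
    if r < 1:
        raise ValueError(f"sampling rate must be >= 1, got {r}")
    return k + (k - 1) * (r - 1)


def dilate_kernel(kernel: np.ndarray, r: int) -> np.ndarray:
    """Materialize the zero-inserted (atrous) version of a square kernel.

    The original weights land at positions that are multiples of ``r``;
    every other entry is exactly zero.  At rate 1 (or for a 1x1 kernel)
    the kernel is returned unchanged.
    """
    kernel = np.asarray(kernel)
    if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1]:
        raise ValueError(f"kernel must be square 2-D, got shape {kernel.shape}")
    if r < 1:
        raise ValueError(f"sampling rate must be >= 1, got {r}")
    k = kernel.shape[0]
    if r == 1 or k == 1:
        return kernel.copy()
    side = k + (k - 1) * (r - 1)
    out = np.zeros((side, side), dtype=kernel.dtype)
    out[::r, ::r] = kernel
    return out


# ---------------------------------------------------------------------------
# domain types

@dataclass
class ArchConfig:
    """Hyperparameters fixing one network variant.

    Defaults are the proposed ASPP variant: growth rate 12, 4 layers per
    dense block, 4 transitions, ASPP rates (6, 12, 18), 512x512 input.
    ``initial_features`` (48) and the ASPP branch width are not pinned by
    the layer totals and are configurable.
    """

    growth_rate: int = 12
    layers_per_block: int = 4
    n_transitions: int = 4
    aspp_rates: tuple[int, ...] = (6, 12, 18)
    use_aspp: bool = True
    initial_features: int = 48
    dropout_rate: float = 0.2
    n_classes: int = 2
    input_side: int = 512

    def __post_init__(self):
        self.aspp_rates = tuple(self.aspp_rates)
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if self.layers_per_block < 1:
            raise ValueError("layers_per_block must be >= 1")
        if self.n_transitions < 1:
            raise ValueError("n_transitions must be >= 1")
        if self.use_aspp:
            if not self.aspp_rates:
                raise ValueError("use_aspp requires at least one rate")
            if any(r < 1 for r in self.aspp_rates):
                raise ValueError("aspp_rates must all be >= 1")
            if any(b >= a for b, a in zip(self.aspp_rates, self.aspp_rates[1:])):
                raise ValueError("aspp_rates must be strictly increasing")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be a fraction in [0, 1)")
        if self.input_side % (2 ** self.n_transitions) != 0:
            raise ValueError(
                f"input_side {self.input_side} not divisible by "
                f"2^{self.n_transitions}")

    @property
    def branch_channels(self) -> int:
        """ASPP branch width: matches the dense bottleneck it replaces."""
        return self.layers_per_block * self.growth_rate


def aspp_fc_densenet_config(**overrides) -> ArchConfig:
    """The proposed 47-layer ASPP-FC-DenseNet configuration."""
    return ArchConfig(**overrides)


def fc_densenet56_config(**overrides) -> ArchConfig:
    """The FC-DenseNet56 baseline: 5 transitions, dense bottleneck."""
    kw = dict(use_aspp=False, n_transitions=5)
    kw.update(overrides)
    return ArchConfig(**kw)


def tiny_config(**overrides) -> ArchConfig:
    """Desk-scale variant for CPU tests: growth 4, 2 layers/block,
    2 transitions, ASPP rates (2, 4), 64x64 input."""
    kw = dict(growth_rate=4, layers_per_block=2, n_transitions=2,
              aspp_rates=(2, 4), initial_features=16, input_side=64)
    kw.update(overrides)
    return ArchConfig(**kw)


@dataclass
class LayerSpec:
    kind: str
    kernel: int = 0
    stride: int = 1
    dilation: int = 1
    in_channels: int = 0
    out_channels: int = 0
    padding_mode: str = "same"

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.stride < 1 or self.dilation < 1:
            raise ValueError("stride and dilation must be >= 1")
        if self.kind in CONV_KINDS and self.kernel < 1:
            raise ValueError("conv layers need a positive kernel size")


@dataclass
class BlockSpec:
    """One named block: an ordered list of layers plus dataflow metadata.

    ``attrs`` records the block's role in the encoder/decoder walk, its
    input/output channels and spatial sides, and block-specific
    parameters (growth rate, ASPP rates) needed to realize it.
    """

    name: str
    layers: list[LayerSpec] = field(default_factory=list)
    skip_output: bool = False
    attrs: dict = field(default_factory=dict)


@dataclass
class NetworkSpec:
    blocks: list[BlockSpec]
    skip_edges: list[tuple[int, int]]
    config: ArchConfig

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["aspp_rates"] = list(cfg["aspp_rates"])
        return {
            "config": cfg,
            "skip_edges": [list(e) for e in self.skip_edges],
            "blocks": [
                {"name": b.name, "skip_output": b.skip_output,
                 "attrs": dict(b.attrs),
                 "layers": [asdict(l) for l in b.layers]}
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        config = ArchConfig(**{**d["config"],
                               "aspp_rates": tuple(d["config"]["aspp_rates"])})
        blocks = [
            BlockSpec(name=b["name"], skip_output=b["skip_output"],
                      attrs=dict(b["attrs"]),
                      layers=[LayerSpec(**l) for l in b["layers"]])
            for b in d["blocks"]
        ]
        edges = [tuple(e) for e in d["skip_edges"]]
        return cls(blocks=blocks, skip_edges=edges, config=config)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# block builders

def build_dense_block(in_channels: int, n_layers: int, growth: int,
                      dropout: float = 0.0, *, skip_output: bool = False,
                      role: str = "encoder") -> BlockSpec:
    """Dense block: ``n_layers`` x (BN -> ReLU -> 3x3 same conv -> dropout).

    Layer ``i`` consumes the concatenation of the block input and the
    outputs of layers 1..i-1, so its input width is
    ``in_channels + (i - 1) * growth``.  The block output is the
    concatenation of the new feature maps only (``n_layers * growth``
    channels); the block input is *not* re-concatenated into the output.
    """
    if in_channels < 1 or n_layers < 1 or growth < 1:
        raise ValueError("in_channels, n_layers and growth must be positive")
    layers: list[LayerSpec] = []
    for i in range(n_layers):
        c_in = in_channels + i * growth
        layers.append(LayerSpec("batch_norm", in_channels=c_in, out_channels=c_in))
        layers.append(LayerSpec("relu", in_channels=c_in, out_channels=c_in))
        layers.append(LayerSpec("conv", kernel=3, in_channels=c_in,
                                out_channels=growth))
        if dropout > 0:
            layers.append(LayerSpec("dropout", in_channels=growth,
                                    out_channels=growth))
    return BlockSpec(
        name="dense_block", layers=layers, skip_output=skip_output,
        attrs={"role": role, "n_layers": n_layers, "growth": growth,
               "dropout": dropout, "in_channels": in_channels,
               "out_channels": n_layers * growth})


def build_transition_down(in_channels: int) -> BlockSpec:
    """Transition down: 1x1 channel-conserving conv, then a 3x3 stride-2
    convolution in place of 2x2 pooling.  Halves the spatial side and
    conserves the channel count.  Counts as one layer unit."""
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    layers = [
        LayerSpec("conv", kernel=1, in_channels=in_channels,
                  out_channels=in_channels),
        LayerSpec("conv", kernel=3, stride=2, in_channels=in_channels,
                  out_channels=in_channels),
    ]
    return BlockSpec(name="transition_down", layers=layers,
                     attrs={"role": "encoder", "in_channels": in_channels,
                            "out_channels": in_channels})


def build_transition_up(in_channels: int, out_channels: int) -> BlockSpec:
    """Transition up: a single 3x3 stride-2 transposed convolution that
    doubles the spatial side.  Applied only to the feature maps produced
    by the preceding dense block, never to the running concatenation."""
    if in_channels < 1 or out_channels < 1:
        raise ValueError("channel counts must be positive")
    layers = [LayerSpec("transposed_conv", kernel=3, stride=2,
                        in_channels=in_channels, out_channels=out_channels)]
    return BlockSpec(name="transition_up", layers=layers,
                     attrs={"role": "decoder", "in_channels": in_channels,
                            "out_channels": out_channels})


def build_aspp(in_channels: int, branch_channels: int, rates: list[int],
               out_channels: int | None = None,
               feature_side: int | None = None) -> BlockSpec:
    """ASPP bottleneck: parallel 1x1 conv and one 3x3 atrous conv per rate.

    Branch outputs are concatenated together with the block input
    (``in_channels + (1 + len(rates)) * branch_channels`` maps) and fused
    by a final 1x1 convolution.  All branches preserve spatial size.
    """
    rates = list(rates)
    if not rates:
        raise ValueError("rates must be nonempty")
    if any(b >= a for b, a in zip(rates, rates[1:])):
        raise ValueError("rates must be strictly increasing")
    if out_channels is None:
        out_channels = branch_channels
    if feature_side is not None:
        for r in rates:
            if effective_kernel_size(3, r) > feature_side:
                import warnings
                warnings.warn(
                    f"ASPP rate {r}: effective kernel "
                    f"{effective_kernel_size(3, r)} exceeds feature side "
                    f"{feature_side}; branch degenerates toward 1x1",
                    stacklevel=2)
    layers = [LayerSpec("conv", kernel=1, in_channels=in_channels,
                        out_channels=branch_channels)]
    for r in rates:
        layers.append(LayerSpec("conv", kernel=3, dilation=r,
                                in_channels=in_channels,
                                out_channels=branch_channels))
    concat_ch = in_channels + (1 + len(rates)) * branch_channels
    layers.append(LayerSpec("concat", in_channels=concat_ch,
                            out_channels=concat_ch))
    layers.append(LayerSpec("conv", kernel=1, in_channels=concat_ch,
                            out_channels=out_channels))
    return BlockSpec(name="aspp", layers=layers,
                     attrs={"role": "bottleneck", "rates": rates,
                            "branch_channels": branch_channels,
                            "in_channels": in_channels,
                            "out_channels": out_channels})


# ---------------------------------------------------------------------------
# network assembly

def assemble_network(config: ArchConfig) -> NetworkSpec:
    """Assemble the full encoder/bottleneck/decoder spec from a config.

    Encoder: initial 3x3 conv, then per level a dense block whose output
    is concatenated with its input (stored as the skip tensor) followed
    by a transition down.  Bottleneck: ASPP, or a dense block for the
    baseline.  Decoder: per level a transition up, concatenation with the
    same-resolution skip, and a dense block.  The classifier consumes the
    concatenation of the last dense block's input and output and emits
    per-class logits through a 1x1 conv and softmax.
    """
    g, n_l = config.growth_rate, config.layers_per_block
    side = config.input_side
    blocks: list[BlockSpec] = []

    init = BlockSpec(
        name="initial_conv",
        layers=[LayerSpec("conv", kernel=3, in_channels=1,
                          out_channels=config.initial_features)],
        attrs={"role": "initial", "in_channels": 1,
               "out_channels": config.initial_features,
               "in_side": side, "out_side": side})
    blocks.append(init)

    ch = config.initial_features
    skip_channels: list[int] = []
    skip_sides: list[int] = []
    encoder_skip_idx: list[int] = []

    for _ in range(config.n_transitions):
        db = build_dense_block(ch, n_l, g, config.dropout_rate,
                               skip_output=True, role="encoder")
        db.attrs["in_side"] = side
        db.attrs["out_side"] = side
        encoder_skip_idx.append(len(blocks))
        blocks.append(db)
        ch = ch + n_l * g  # running concatenation [input, new features]
        skip_channels.append(ch)
        skip_sides.append(side)
        td = build_transition_down(ch)
        td.attrs["in_side"] = side
        side //= 2
        td.attrs["out_side"] = side
        blocks.append(td)

    if config.use_aspp:
        bott = build_aspp(ch, config.branch_channels, list(config.aspp_rates),
                          feature_side=side)
    else:
        bott = build_dense_block(ch, n_l, g, config.dropout_rate,
                                 role="bottleneck")
    bott.attrs["in_side"] = side
    bott.attrs["out_side"] = side
    blocks.append(bott)
    ch = bott.attrs["out_channels"]

    skip_edges: list[tuple[int, int]] = []
    for level in range(config.n_transitions - 1, -1, -1):
        tu = build_transition_up(ch, ch)
        tu.attrs["in_side"] = side
        side *= 2
        tu.attrs["out_side"] = side
        tu.attrs["skip_channels"] = skip_channels[level]
        if side != skip_sides[level]:
            raise AssertionError("decoder resolution diverged from encoder")
        skip_edges.append((encoder_skip_idx[level], len(blocks)))
        blocks.append(tu)
        ch = ch + skip_channels[level]
        last = level == 0
        db = build_dense_block(ch, n_l, g, config.dropout_rate, role="decoder")
        db.attrs["in_side"] = side
        db.attrs["out_side"] = side
        db.attrs["final_concat"] = last
        blocks.append(db)
        ch = ch + n_l * g if last else n_l * g

    clf = BlockSpec(
        name="classifier",
        layers=[LayerSpec("conv", kernel=1, in_channels=ch,
                          out_channels=config.n_classes),
                LayerSpec("softmax", in_channels=config.n_classes,
                          out_channels=config.n_classes)],
        attrs={"role": "final", "in_channels": ch,
               "out_channels": config.n_classes,
               "in_side": side, "out_side": side})
    blocks.append(clf)

    spec = NetworkSpec(blocks=blocks, skip_edges=skip_edges, config=config)
    validate(spec)
    return spec


def validate(spec: NetworkSpec) -> None:
    """Check channel bookkeeping, resolution symmetry and skip edges."""
    blocks = spec.blocks
    if blocks[0].attrs["in_side"] != blocks[-1].attrs["out_side"]:
        raise ValueError("output resolution must equal input resolution")
    n_td = sum(b.name == "transition_down" for b in blocks)
    n_tu = sum(b.name == "transition_up" for b in blocks)
    if n_td != n_tu:
        raise ValueError(f"{n_td} transition-down vs {n_tu} transition-up")
    for src, dst in spec.skip_edges:
        if blocks[src].attrs["in_side"] != blocks[dst].attrs["out_side"]:
            raise ValueError(
                f"skip edge {src}->{dst} connects different resolutions")
        if not blocks[src].skip_output:
            raise ValueError(f"skip source block {src} does not store output")
    for b in blocks:
        if b.name == "dense_block":
            c0 = b.attrs["in_channels"]
            g = b.attrs["growth"]
            for i, l in enumerate(conv_layers(b)):
                if l.in_channels != c0 + i * g:
                    raise ValueError(
                        f"dense layer {i}: declared {l.in_channels} channels, "
                        f"concatenation arithmetic gives {c0 + i * g}")
        elif b.name == "aspp":
            concat_l = next(l for l in b.layers if l.kind == "concat")
            expect = (b.attrs["in_channels"]
                      + (1 + len(b.attrs["rates"])) * b.attrs["branch_channels"])
            if concat_l.in_channels != expect:
                raise ValueError("ASPP concat width inconsistent")
    # sequential channel flow between blocks is checked by the realizer,
    # which would fail loudly on any mismatch; here we check declared attrs
    down = [b.attrs["out_side"] for b in blocks if b.name == "transition_down"]
    up = [b.attrs["in_side"] for b in blocks if b.name == "transition_up"]
    if down != list(reversed(up)):
        raise ValueError("encoder/decoder resolution sequences are asymmetric")


def conv_layers(block: BlockSpec) -> list[LayerSpec]:
    return [l for l in block.layers if l.kind in CONV_KINDS]


def count_layers(spec: NetworkSpec) -> int:
    """Counted learnable layers under the FC-DenseNet convention.

    Every convolution and transposed convolution counts, except that a
    transition down counts as a single unit even though it contains both
    the 1x1 channel-conserving conv and the stride-2 conv.  The proposed
    configuration yields 1 + 16 + 4 + 5 + 4 + 16 + 1 = 47; the baseline
    1 + 20 + 5 + 4 + 5 + 20 + 1 = 56.
    """
    total = 0
    for b in spec.blocks:
        n_conv = len(conv_layers(b))
        if b.name == "transition_down":
            total += 1 if n_conv else 0
        else:
            total += n_conv
    return total


def downsample_factor(spec: NetworkSpec) -> int:
    """Product of all encoder strides (2 per transition down)."""
    f = 1
    for b in spec.blocks:
        if b.attrs.get("role") in ("initial", "encoder"):
            for l in conv_layers(b):
                f *= l.stride
    return f
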