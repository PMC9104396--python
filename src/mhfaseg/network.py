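"""Encoder-decoder assembly with multiscale aggregation, long residual
connections and guided skip connections.

The reference design is a three-level, fully convolutional encoder-decoder
(filters 32/64/128 at the levels, a 256-channel bottleneck at one-eighth
resolution) with a 1x1 sigmoid head producing a per-pixel foreground
probability.  Five frozen configurations are provided:

* ``variation 1`` — the basic U-Net-style baseline: two plain 3x3
  convolutions per level, 2x2 max pooling / 2x2 nearest upsampling, plain
  concatenated skip connections (1,946,881 trainable parameters).
* ``variation 2`` — HFA blocks replace the plain convolution pairs at the
  three levels (branch width half the nominal level width, pointwise k=1
  branches, single-convolution bottleneck).
* ``variation 3`` — plain convolutions combined with input-anchored
  CEM/IM/LEM long residual connections; the residual design replaces
  capacity (one convolution per stage instead of two), so it has fewer
  parameters than the baseline.
* ``variation 4`` — the baseline plus guided blocks on every skip
  connection (2,119,809 trainable parameters).
* ``proposed`` — HFA blocks, MFA-based long residuals and guided skips
  combined.

Long residual connections tap the network input, transform it with the
level's MFA module (CEM at level 1, IM at level 2, LEM at level 3) and
downsample it with parameter-free max pooling (windows 2/4/8 on the encoder
side, matching the stream resolutions) before elementwise addition into the
encoder and decoder streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .blocks import HFA, MFAModule, GuidedBlock, Module
from .nn import Parameter, Tensor

__all__ = [
    "NetworkConfig",
    "ModelSummary",
    "SegmentationModel",
    "build_model",
    "build_variation",
    "count_parameters",
    "VARIANT_FLAGS",
]

# Table of component flags per frozen configuration.
VARIANT_FLAGS = {
    "variation1": dict(use_basic=True, use_hfa=False, use_mfa_residuals=False, use_guided=False),
    "variation2": dict(use_basic=False, use_hfa=True, use_mfa_residuals=False, use_guided=False),
    "variation3": dict(use_basic=True, use_hfa=False, use_mfa_residuals=True, use_guided=False),
    "variation4": dict(use_basic=True, use_hfa=False, use_mfa_residuals=False, use_guided=True),
    "proposed": dict(use_basic=True, use_hfa=True, use_mfa_residuals=True, use_guided=True),
}

_RES_KINDS = ("cem", "im", "lem")  # level 1, 2, 3


@dataclass
class NetworkConfig:
    """Architectural genotype; fully determines the parameter count."""

    depth: int = 3
    base_filters: tuple = (32, 64, 128)
    input_shape: tuple = (256, 256, 3)
    use_hfa: bool = True
    use_mfa_residuals: bool = True
    use_guided: bool = True
    # HFA details (apply when use_hfa): branch width as a fraction of the
    # level width, and how the k=1 branch is realized.
    hfa_branch_fraction: float = 0.5
    hfa_k1_mode: str = "single"
    # Guided block realization; 'pointwise' matches the reference budgets.
    guided_style: str = "pointwise"
    # Plain-convolution stages per level when the basic blocks are used:
    # 2 for the baseline, 1 when residuals replace capacity.
    convs_per_level: int = 2
    bottleneck_filters: int = 256
    bottleneck_convs: int = 2
    seed: int = 0
    name: str = "proposed"

    def __post_init__(self):
        if self.depth != len(self.base_filters):
            raise ValueError("depth must equal len(base_filters)")
        for a, b in zip(self.base_filters, self.base_filters[1:]):
            if b != 2 * a:
                raise ValueError("filters must double per level")

    @classmethod
    def for_variant(cls, variant, input_shape=(256, 256, 3), seed=0):
        """Frozen configuration for 'proposed' or variations 1-4."""
        key = f"variation{variant}" if isinstance(variant, int) else str(variant)
        if key not in VARIANT_FLAGS:
            raise ValueError(f"unknown variant {variant!r}; use 1..4 or 'proposed'")
        flags = VARIANT_FLAGS[key]
        cfg = cls(
            input_shape=tuple(input_shape),
            use_hfa=flags["use_hfa"],
            use_mfa_residuals=flags["use_mfa_residuals"],
            use_guided=flags["use_guided"],
            seed=seed,
            name=key,
        )
        if flags["use_hfa"]:
            cfg.bottleneck_convs = 1  # HFA widens the stream; one 3x3 suffices
        if flags["use_mfa_residuals"] and not flags["use_hfa"]:
            cfg.convs_per_level = 1  # residuals replace capacity
            cfg.bottleneck_convs = 1
        return cfg


@dataclass
class ModelSummary:
    total_trainable_params: int
    per_layer: list = field(default_factory=list)

    def to_dict(self):
        return asdict(self)


class Conv3x3(Module):
    def __init__(self, cin, cout, rng, activation="relu"):
        self.w = Parameter(nn.he_uniform(rng, (3, 3, cin, cout), fan_in=9 * cin))
        self.b = Parameter(np.zeros(cout, dtype=np.float32))
        self.activation = activation

    def forward(self, x):
        y = nn.conv2d(x, self.w, self.b)
        return nn.relu(y) if self.activation == "relu" else y


class Conv1x1(Module):
    def __init__(self, cin, cout, rng):
        self.w = Parameter(nn.he_uniform(rng, (1, 1, cin, cout), fan_in=cin))
        self.b = Parameter(np.zeros(cout, dtype=np.float32))

    def forward(self, x):
        return nn.conv2d(x, self.w, self.b)


class PlainBlock(Module):
    """One or two plain 3x3 convolutions with ReLU."""

    def __init__(self, cin, cout, rng, n_convs=2):
        convs = [Conv3x3(cin, cout, rng)]
        for _ in range(n_convs - 1):
            convs.append(Conv3x3(cout, cout, rng))
        self.convs = convs
        self.out_channels = cout

    def forward(self, x):
        for c in self.convs:
            x = c(x)
        return x


class SegmentationModel(Module):
    """Fully convolutional encoder-decoder built from a :class:`NetworkConfig`."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        depth = cfg.depth
        filters = cfg.base_filters
        cin = cfg.input_shape[2]

        self.enc_blocks, self.dec_blocks = [], []
        self.enc_res, self.dec_res = [], []
        self.guided = []
        widths = []  # encoder block output widths (== skip widths)

        c = cin
        for l in range(depth):
            f = filters[l]
            if cfg.use_hfa:
                bf = max(1, int(round(f * cfg.hfa_branch_fraction)))
                blk = HFA(c, bf, rng, k1_mode=cfg.hfa_k1_mode)
                out = blk.out_channels
            else:
                blk = PlainBlock(c, f, rng, n_convs=cfg.convs_per_level)
                out = f
            self.enc_blocks.append(blk)
            widths.append(out)
            if cfg.use_guided:
                self.guided.append(GuidedBlock(out, rng, style=cfg.guided_style))
            if cfg.use_mfa_residuals:
                self.enc_res.append(MFAModule(_RES_KINDS[l], cin, out, rng))
            c = out

        self.bottleneck = PlainBlock(
            c, cfg.bottleneck_filters, rng, n_convs=cfg.bottleneck_convs
        )
        c = cfg.bottleneck_filters

        for l in reversed(range(depth)):
            f = filters[l]
            cat = c + widths[l]
            if cfg.use_hfa:
                bf = max(1, int(round(f * cfg.hfa_branch_fraction)))
                blk = HFA(cat, bf, rng, k1_mode=cfg.hfa_k1_mode)
                out = blk.out_channels
            else:
                blk = PlainBlock(cat, f, rng, n_convs=cfg.convs_per_level)
                out = f
            self.dec_blocks.append(blk)  # stored deepest-first
            if cfg.use_mfa_residuals:
                self.dec_res.append(MFAModule(_RES_KINDS[l], cin, out, rng))
            c = out

        self.head = Conv1x1(c, 1, rng)
        self._widths = widths

    # ----- forward -------------------------------------------------------

    def forward(self, x):
        """Return per-pixel logits; apply sigmoid for probabilities."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.data.ndim == 3:
            x = Tensor(x.data[None])
        B, H, W, C = x.data.shape
        d = self.cfg.depth
        if H % (2 ** d) or W % (2 ** d):
            raise ValueError(
                f"input spatial dims {(H, W)} must be divisible by {2 ** d}"
            )
        cfg = self.cfg
        inp = x
        skips = []
        h = x
        for l in range(d):
            h = self.enc_blocks[l](h)
            skips.append(self.guided[l](h) if cfg.use_guided else h)
            h = nn.maxpool(h, 2)
            if cfg.use_mfa_residuals:
                # input pooled by 2/4/8 to the post-pool stream resolution
                h = nn.add(h, self.enc_res[l](nn.maxpool(inp, 2 ** (l + 1))))
        h = self.bottleneck(h)
        for i, l in enumerate(reversed(range(d))):
            h = nn.upsample(h, 2)
            h = nn.concat([h, skips[l]], axis=-1)
            h = self.dec_blocks[i](h)
            if cfg.use_mfa_residuals:
                r = inp if l == 0 else nn.maxpool(inp, 2 ** l)
                h = nn.add(h, self.dec_res[i](r))
        return self.head(h)

    def predict_proba(self, x):
        """Forward pass returning a numpy probability map strictly in (0, 1).

        The sigmoid is evaluated in float64 with the logits clipped to +-35
        so the probabilities never saturate to exactly 0 or 1.
        """
        logits = self.forward(x).data.astype(np.float64)
        return 1.0 / (1.0 + np.exp(-np.clip(logits, -35.0, 35.0)))

    # ----- accounting ----------------------------------------------------

    def summary(self):
        H, W, _ = self.cfg.input_shape
        d = self.cfg.depth
        rows = []

        def shape_at(level):
            return (H // (2 ** level), W // (2 ** level))

        for l, blk in enumerate(self.enc_blocks):
            rows.append((f"encoder{l + 1}", blk.param_count(), (*shape_at(l), _out(blk))))
            if self.cfg.use_guided:
                g = self.guided[l]
                rows.append((f"guided{l + 1}", g.param_count(), (*shape_at(l), g.channels)))
            if self.cfg.use_mfa_residuals:
                r = self.enc_res[l]
                rows.append((f"enc_residual{l + 1}", r.param_count(), (*shape_at(l + 1), r.filters)))
        rows.append(("bottleneck", self.bottleneck.param_count(), (*shape_at(d), self.cfg.bottleneck_filters)))
        for i, l in enumerate(reversed(range(d))):
            blk = self.dec_blocks[i]
            rows.append((f"decoder{l + 1}", blk.param_count(), (*shape_at(l), _out(blk))))
            if self.cfg.use_mfa_residuals:
                r = self.dec_res[i]
                rows.append((f"dec_residual{l + 1}", r.param_count(), (*shape_at(l), r.filters)))
        rows.append(("head", self.head.param_count(), (H, W, 1)))
        return ModelSummary(
            total_trainable_params=self.param_count(),
            per_layer=rows,
        )


def _out(blk):
    return blk.out_channels if hasattr(blk, "out_channels") else None


def build_model(cfg: NetworkConfig) -> SegmentationModel:
    """Build a segmentation model from a configuration."""
    return SegmentationModel(cfg)


def build_variation(n, input_shape=(256, 256, 3), seed=0) -> SegmentationModel:
    """Build ablation variation ``n`` (1..4) or the full 'proposed' model."""
    if n != "proposed" and n not in (1, 2, 3, 4):
        raise ValueError(f"variation must be in 1..4 or 'proposed', got {n!r}")
    return build_model(NetworkConfig.for_variant(n, input_shape=input_shape, seed=seed))


def count_parameters(model: SegmentationModel) -> ModelSummary:
    """Exact trainable-parameter accounting with a per-layer breakdown."""
    summary = model.summary()
    per_layer_total = sum(p for _, p, _ in summary.per_layer)
    assert per_layer_total == summary.total_trainable_params, (
        per_layer_total,
        summary.total_trainable_params,
    )
    return summary


def long_residual(x, level, module_kind, cin=3, filters=None, rng=None, module=None):
    """Standalone MFA-based long residual: module + pooled downsampling.

    ``level`` is 1-based; the input stream is transformed by the CEM/IM/LEM
    module and max-pooled by the factor needed to reach that level's
    post-pool resolution (2, 4 or 8).
    """
    if level not in (1, 2, 3):
        raise ValueError("level must be in {1, 2, 3}")
    kind = module_kind.lower()
    if kind != _RES_KINDS[level - 1]:
        raise ValueError(
            f"level {level} uses the {_RES_KINDS[level - 1].upper()} module"
        )
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=np.float32))
    if x.data.ndim == 3:
        x = Tensor(x.data[None])
    if module is None:
        module = MFAModule(
            kind,
            x.data.shape[-1],
            filters if filters is not None else 32 * 2 ** (level - 1),
            rng if rng is not None else np.random.default_rng(0),
        )
    return nn.maxpool(module(x), 2 ** level), module
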