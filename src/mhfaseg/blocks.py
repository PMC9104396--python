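"""Factorized multiscale building blocks.

The architecture is assembled from one primitive: a ``k x k`` convolution
"split" into a ``k x 1`` stage followed by a ``1 x k`` stage, each with bias
and ReLU (:class:`SepConv`).  Three multiscale feature-aggregation (MFA)
modules stack such factorized branches over different kernel sets and sum
them elementwise:

* CEM (context encoding module):  k in {1, 3, 5, 7}
* IM  (intermediate module):      k in {1, 3, 5}
* LEM (local encoding module):    k in {1, 3}

The hierarchical feature aggregation (HFA) block concatenates the CEM, IM and
LEM outputs channel-wise, tripling the width.  A guided block refines encoder
skip features with two parallel factorized paths before they reach the
decoder.  All blocks preserve spatial dimensions (same padding) and are
deterministic given a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Parameter, Tensor

__all__ = [
    "KernelBranchSpec",
    "BlockParamReport",
    "Module",
    "SepConv",
    "MFAModule",
    "CEM",
    "IM",
    "LEM",
    "HFA",
    "GuidedBlock",
    "sep_conv",
]

VALID_KERNELS = (1, 3, 5, 7)


@dataclass(frozen=True)
class KernelBranchSpec:
    """One factorized branch: kernel extent, channel fan-in/out, activation."""

    k: int
    in_channels: int
    out_channels: int
    activation: str = "relu"

    def __post_init__(self):
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError(f"kernel extent must be odd and positive, got {self.k}")
        if self.k not in VALID_KERNELS:
            raise ValueError(f"kernel extent must be one of {VALID_KERNELS}")
        if self.out_channels <= 0 or self.in_channels <= 0:
            raise ValueError("channel counts must be positive")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")


@dataclass
class BlockParamReport:
    block_name: str
    trainable_params: int
    per_branch: list = field(default_factory=list)


class Module:
    """Base class: recursive parameter collection and exact counting."""

    def sublayers(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Module):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(m for m in v if isinstance(m, Module))
        return out

    def parameters(self):
        params = [v for v in vars(self).values() if isinstance(v, Parameter)]
        for sub in self.sublayers():
            params.extend(sub.parameters())
        return params

    def param_count(self):
        return int(sum(p.size for p in self.parameters()))

    def __call__(self, x):
        return self.forward(x)


class DirectionalConv(Module):
    """A single k x 1 (axis=1) or 1 x k (axis=2) convolution with bias."""

    def __init__(self, k, cin, cout, axis, rng, activation="relu"):
        self.k, self.cin, self.cout, self.axis = k, cin, cout, axis
        self.activation = activation
        self.w = Parameter(nn.he_uniform(rng, (k, cin, cout), fan_in=k * cin))
        self.b = Parameter(np.zeros(cout, dtype=np.float32))

    def forward(self, x):
        y = nn.conv_spatial(x, self.w, self.b, self.axis)
        return nn.relu(y) if self.activation == "relu" else y


class SepConv(Module):
    """Factorized k x k convolution: k x 1 then 1 x k, ReLU after each stage.

    A k=1 branch is realized, by default, literally as two stacked 1 x 1
    stages (``k1_mode='paired'``); ``k1_mode='single'`` collapses it to one
    pointwise convolution for parameter-budget experiments.
    """

    def __init__(self, spec: KernelBranchSpec, rng, k1_mode="paired"):
        self.spec = spec
        k, cin, f = spec.k, spec.in_channels, spec.out_channels
        if k == 1 and k1_mode == "single":
            self.stages = [DirectionalConv(1, cin, f, 1, rng)]
        else:
            self.stages = [
                DirectionalConv(k, cin, f, 1, rng),
                DirectionalConv(k, f, f, 2, rng),
            ]

    def forward(self, x):
        if x.data.shape[-1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, "
                f"got {x.data.shape[-1]}"
            )
        for stage in self.stages:
            x = stage(x)
        return x


_KERNEL_SETS = {"cem": (1, 3, 5, 7), "im": (1, 3, 5), "lem": (1, 3)}


class MFAModule(Module):
    """Multiscale feature aggregation: parallel factorized branches, summed.

    ``kind`` selects the kernel set (cem/im/lem).  Branch outputs all have
    ``filters`` channels and are combined by elementwise addition, so the
    module is linear in its branch contributions before the final activations:
    zeroing one branch's weights reproduces the smaller kernel-set module.
    """

    def __init__(self, kind, cin, filters, rng, k1_mode="paired", include_k1=True):
        if filters <= 0:
            raise ValueError("filters must be positive")
        self.kind = kind
        kernels = _KERNEL_SETS[kind]
        if not include_k1:
            kernels = tuple(k for k in kernels if k != 1)
        self.branches = [
            SepConv(KernelBranchSpec(k, cin, filters), rng, k1_mode=k1_mode)
            for k in kernels
        ]
        self.filters = filters

    def forward(self, x):
        out = self.branches[0](x)
        for br in self.branches[1:]:
            out = nn.add(out, br(x))
        return out

    def report(self):
        return BlockParamReport(
            block_name=self.kind.upper(),
            trainable_params=self.param_count(),
            per_branch=[(br.spec.k, br.param_count()) for br in self.branches],
        )


def CEM(cin, filters, rng, **kw):
    return MFAModule("cem", cin, filters, rng, **kw)


def IM(cin, filters, rng, **kw):
    return MFAModule("im", cin, filters, rng, **kw)


def LEM(cin, filters, rng, **kw):
    return MFAModule("lem", cin, filters, rng, **kw)


class HFA(Module):
    """Hierarchical feature aggregation: concat of CEM, IM and LEM outputs.

    Output width is ``3 * filters``; concatenation itself adds no weights, so
    the parameter count is exactly the sum of the three modules' counts.
    """

    def __init__(self, cin, filters, rng, k1_mode="paired", include_k1=True):
        if filters <= 0:
            raise ValueError("filters must be positive")
        self.cem = CEM(cin, filters, rng, k1_mode=k1_mode, include_k1=include_k1)
        self.im = IM(cin, filters, rng, k1_mode=k1_mode, include_k1=include_k1)
        self.lem = LEM(cin, filters, rng, k1_mode=k1_mode, include_k1=include_k1)
        self.filters = filters
        self.out_channels = 3 * filters

    def forward(self, x):
        parts = [self.cem(x), self.im(x), self.lem(x)]
        shapes = {p.data.shape[1:3] for p in parts}
        if len(shapes) != 1:
            raise ValueError(f"branch spatial dims diverged: {shapes}")
        return nn.concat(parts, axis=-1)


class GuidedBlock(Module):
    """Attention-style refinement of encoder skip features.

    Two parallel channel-preserving factorized paths are summed.  The default
    ``style='pointwise'`` gives each path a directional 3-tap stage followed
    by a pointwise (1 x 1) mixing stage — the configuration whose parameter
    cost (8C^2 + 4C per block) reproduces the reference network budgets.
    ``style='paired'`` is the fully directional reading (3x1->1x3 and
    1x3->3x1; 12C^2 + 4C).
    """

    def __init__(self, channels, rng, style="pointwise"):
        C = channels
        if style == "paired":
            self.path_a = [DirectionalConv(3, C, C, 1, rng), DirectionalConv(3, C, C, 2, rng)]
            self.path_b = [DirectionalConv(3, C, C, 2, rng), DirectionalConv(3, C, C, 1, rng)]
        elif style == "pointwise":
            self.path_a = [DirectionalConv(3, C, C, 1, rng), DirectionalConv(1, C, C, 2, rng)]
            self.path_b = [DirectionalConv(3, C, C, 2, rng), DirectionalConv(1, C, C, 1, rng)]
        else:
            raise ValueError(f"unknown guided block style {style!r}")
        self.channels = C
        self.style = style

    def forward(self, x):
        a = x
        for stage in self.path_a:
            a = stage(a)
        b = x
        for stage in self.path_b:
            b = stage(b)
        return nn.add(a, b)


def sep_conv(x, spec: KernelBranchSpec, rng=None, layer=None):
    """Functional form: build (or reuse) a :class:`SepConv` and apply it.

    Returns ``(output, layer)`` so weights can be reused across calls.
    """
    if layer is None:
        layer = SepConv(spec, rng if rng is not None else np.random.default_rng(0))
    if not isinstance(x, Tensor):
        x = Tensor(x)
    return layer(x), layer
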