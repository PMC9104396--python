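"""Parameter arithmetic, shape contracts and branch-linearity oracles for
the factorized multiscale blocks."""

import numpy as np
import pytest

from mhfaseg import nn
from mhfaseg.blocks import (
    CEM,
    HFA,
    IM,
    LEM,
    GuidedBlock,
    KernelBranchSpec,
    SepConv,
)
from mhfaseg.nn import Tensor


def _x(rng, h=8, w=8, c=3):
    return Tensor(rng.random((1, h, w, c)).astype(np.float32))


# ----- parameter arithmetic ----------------------------------------------


@pytest.mark.parametrize(
    "k,cin,f,expected",
    [
        (3, 3, 4, 92),    # (3*3*4+4) + (3*4*4+4)
        (1, 3, 4, 36),    # two stacked 1x1 stages
        (5, 3, 4, 148),
        (7, 3, 4, 204),
    ],
)
def test_sep_conv_param_count(k, cin, f, expected, rng):
    layer = SepConv(KernelBranchSpec(k, cin, f), rng)
    assert layer.param_count() == expected


@pytest.mark.parametrize(
    "ctor,expected",
    [(CEM, 480), (IM, 276), (LEM, 128)],  # sums of the branch counts above
)
def test_module_param_counts(ctor, expected, rng):
    assert ctor(3, 4, rng).param_count() == expected


def test_hfa_params_are_sum_of_modules(rng):
    hfa = HFA(3, 4, rng)
    assert hfa.param_count() == 480 + 276 + 128 == 884
    assert (
        hfa.param_count()
        == hfa.cem.param_count() + hfa.im.param_count() + hfa.lem.param_count()
    )


@pytest.mark.parametrize("C,expected", [(32, 12416), (64, 49408)])  # 12C^2+4C
def test_guided_block_paired_params(C, expected, rng):
    assert GuidedBlock(C, rng, style="paired").param_count() == expected


@pytest.mark.parametrize("C", [32, 64, 128])
def test_guided_block_pointwise_params(C, rng):
    assert GuidedBlock(C, rng, style="pointwise").param_count() == 8 * C * C + 4 * C


def test_branch_report_totals(rng):
    rep = CEM(3, 4, rng).report()
    assert rep.trainable_params == sum(p for _, p in rep.per_branch) == 480
    assert [k for k, _ in rep.per_branch] == [1, 3, 5, 7]


# ----- contracts ----------------------------------------------------------


def test_even_kernel_rejected():
    with pytest.raises(ValueError, match="odd"):
        KernelBranchSpec(4, 3, 8)


def test_channel_mismatch_rejected(rng):
    layer = SepConv(KernelBranchSpec(3, 3, 4), rng)
    with pytest.raises(ValueError, match="channels"):
        layer(_x(rng, c=5))


@pytest.mark.parametrize("hw", [(8, 8), (11, 7), (64, 64), (5, 33)])
@pytest.mark.parametrize("make", [
    lambda rng: SepConv(KernelBranchSpec(5, 3, 4), rng),
    lambda rng: CEM(3, 4, rng),
    lambda rng: HFA(3, 4, rng),
    lambda rng: GuidedBlock(3, rng),
])
def test_blocks_preserve_spatial_dims(hw, make, rng):
    x = _x(rng, *hw)
    y = make(rng)(x)
    assert y.data.shape[1:3] == hw


def test_hfa_concatenates_channels(rng):
    y = HFA(3, 32, rng)(_x(rng, 16, 16))
    assert y.data.shape[-1] == 96


# ----- oracles ------------------------------------------------------------


def _copy_branch(dst, src):
    for d, s in zip(dst.parameters(), src.parameters()):
        d.data = s.data.copy()


def _zero_branch(branch):
    for p in branch.parameters():
        p.data = np.zeros_like(p.data)


def test_cem_with_k7_zeroed_equals_im(rng):
    """The modules are linear in branch contributions: dropping the k=7
    branch of CEM (by zeroing its weights) reproduces IM exactly."""
    cem = CEM(3, 4, rng)
    im = IM(3, 4, rng)
    for im_br, cem_br in zip(im.branches, cem.branches[:3]):
        _copy_branch(im_br, cem_br)
    _zero_branch(cem.branches[3])  # k=7
    x = _x(rng, 12, 12)
    np.testing.assert_allclose(cem(x).data, im(x).data, atol=1e-6)


def test_lem_with_k1_zeroed_equals_sep_conv3(rng):
    lem = LEM(3, 4, rng)
    sep = SepConv(KernelBranchSpec(3, 3, 4), rng)
    _copy_branch(sep, lem.branches[1])
    _zero_branch(lem.branches[0])  # k=1
    x = _x(rng, 10, 10)
    np.testing.assert_allclose(lem(x).data, sep(x).data, atol=1e-6)


def test_constant_input_gives_constant_output(rng):
    """On a zero image every pixel sees only the biases through the ReLUs,
    so the output is spatially constant and matches the closed form."""
    cem = CEM(3, 4, rng)
    for p in cem.parameters():
        if p.data.ndim == 1:  # biases
            p.data = rng.uniform(-0.5, 0.5, p.data.shape).astype(np.float32)
    x = Tensor(np.zeros((1, 9, 9, 3), np.float32))
    y = cem(x).data[:, 3:-3, 3:-3]  # interior: away from zero-padding
    assert np.allclose(y, y[0, 0, 0], atol=1e-6)
    y = cem(x).data
    expected = np.zeros(4, np.float32)
    for br in cem.branches:
        s1, s2 = br.stages
        h = np.maximum(s1.b.data, 0.0)
        # interior pixels: the 1xk stage sums its kernel taps over a
        # constant field
        pre = h.dot(s2.w.data.sum(axis=0)) + s2.b.data
        expected += np.maximum(pre, 0.0)
    np.testing.assert_allclose(y[0, 4, 4], expected, atol=1e-5)


def test_fixed_seed_gives_identical_weights():
    a = HFA(3, 8, np.random.default_rng(11))
    b = HFA(3, 8, np.random.default_rng(11))
    for pa, pb in zip(a.parameters(), b.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)
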