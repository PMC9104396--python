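"""Metric identities, brute-force oracles and the rank-sum harness."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhfaseg.metrics import (
    ConfusionCounts,
    acc,
    aggregate,
    compare_metrics,
    confusion,
    dsc,
    evaluate_pair,
    ji,
    wilcoxon_ranksum,
)


def brute_force_confusion(pred, truth):
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = bool(pred[i, j]), bool(truth[i, j])
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def brute_force_ranksum_p(a, b):
    """Exhaustive permutation oracle: split the pooled sample every way."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n1, N = len(a), len(pooled)
    mu = n1 * (N + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for idx in combinations(range(N), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def test_confusion_exact_cases():
    truth = np.zeros((10, 10), bool)
    truth[:2, :5] = True  # 10 foreground of 100
    c = confusion(truth, truth)
    assert (c.TP, c.TN, c.FP, c.FN) == (10, 90, 0, 0)
    assert acc(c) == 1.0 and dsc(c) == 1.0 and ji(c) == 1.0
    inv = confusion(~truth, truth)
    assert inv.TP == 0 and inv.TN == 0 and acc(inv) == 0.0


def test_confusion_matches_pixel_loop_oracle(rng):
    for _ in range(100):
        pred = rng.random((32, 32)) > 0.5
        truth = rng.random((32, 32)) > 0.7
        c = confusion(pred, truth)
        assert c == brute_force_confusion(pred, truth)
        assert c.total == 32 * 32


def test_non_binary_rejected():
    with pytest.raises(ValueError, match="binary"):
        confusion(np.array([[0.3]]), np.array([[1]]))


def test_metric_arithmetic_examples():
    c = ConfusionCounts(TP=2, TN=6, FP=1, FN=1)
    assert acc(c) == 0.8
    c = ConfusionCounts(TP=3, TN=0, FP=1, FN=1)
    assert dsc(c) == 0.75 and ji(c) == 0.6
    # dsc = 2 ji / (1 + ji)
    assert np.isclose(dsc(c), 2 * ji(c) / (1 + ji(c)))


def test_empty_mask_conventions():
    both_empty = ConfusionCounts(TP=0, FP=0, TN=100, FN=0)
    assert dsc(both_empty) == 1.0 and ji(both_empty) == 1.0
    one_empty = ConfusionCounts(TP=0, FP=5, TN=95, FN=0)
    assert dsc(one_empty) == 0.0 and ji(one_empty) == 0.0


@settings(max_examples=300, deadline=None)
@given(
    tp=st.integers(0, 10_000),
    fp=st.integers(0, 10_000),
    fn=st.integers(0, 10_000),
    tn=st.integers(0, 10_000),
)
def test_dice_jaccard_identity_property(tp, fp, fn, tn):
    c = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    d, j = dsc(c), ji(c)
    assert 0.0 <= j <= d <= 1.0
    assert abs(d - 2 * j / (1 + j)) < 1e-12


def test_identity_over_many_random_counts(rng):
    """Dense numeric sweep of the DSC/JI identity at 1e-12 tolerance."""
    counts = rng.integers(0, 100_000, size=(10_000, 3))
    for tp, fp, fn in counts:
        c = ConfusionCounts(TP=int(tp), FP=int(fp), TN=0, FN=int(fn))
        d, j = dsc(c), ji(c)
        assert abs(d - 2 * j / (1 + j)) < 1e-12
        assert j <= d <= 1.0


def test_permutation_invariance(rng):
    pred = rng.random((16, 16)) > 0.5
    truth = rng.random((16, 16)) > 0.5
    perm = rng.permutation(16 * 16)
    c1 = confusion(pred, truth)
    c2 = confusion(pred.ravel()[perm].reshape(16, 16), truth.ravel()[perm].reshape(16, 16))
    assert c1 == c2


def test_aggregate_is_mean_of_records():
    import pandas as pd

    df = pd.DataFrame(
        [evaluate_pair(np.eye(4, dtype=bool), np.eye(4, dtype=bool), "a").__dict__,
         evaluate_pair(np.zeros((4, 4), bool), np.eye(4, dtype=bool), "b").__dict__]
    )
    agg = aggregate(df)
    assert np.isclose(agg["dsc"], df["dsc"].mean())


# ----- rank-sum -----------------------------------------------------------


def test_ranksum_identical_samples():
    assert wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0
    assert wilcoxon_ranksum([5.0] * 4, [5.0] * 4) == 1.0


def test_ranksum_full_separation():
    a = list(range(10, 20))
    b = list(range(10))
    assert wilcoxon_ranksum(a, b) < 0.001


@pytest.mark.parametrize("n1", [2, 3, 4, 5])
@pytest.mark.parametrize("n2", [2, 3, 4, 5])
def test_ranksum_matches_permutation_oracle(n1, n2, rng):
    for trial in range(5):
        a = rng.random(n1)
        b = rng.random(n2)
        assert np.isclose(wilcoxon_ranksum(a, b), brute_force_ranksum_p(a, b))


def test_ranksum_with_ties_matches_oracle(rng):
    a = [1.0, 2.0, 2.0, 3.0]
    b = [2.0, 3.0, 3.0, 4.0]
    assert np.isclose(wilcoxon_ranksum(a, b), brute_force_ranksum_p(a, b))


def test_ranksum_normal_approx_close_to_scipy(rng):
    from scipy.stats import ranksums

    a = rng.standard_normal(40)
    b = rng.standard_normal(40) + 0.5
    ours = wilcoxon_ranksum(a, b)
    ref = ranksums(a, b).pvalue
    assert abs(ours - ref) < 0.02


def test_ranksum_rejects_tiny_samples():
    with pytest.raises(ValueError, match="two observations"):
        wilcoxon_ranksum([1.0], [2.0, 3.0])


def test_compare_metrics_table_and_plot(tmp_path, rng):
    import pandas as pd

    paths = []
    for name, shift in [("unet", 0.0), ("proposed", 0.05)]:
        df = pd.DataFrame(
            {"image_id": [f"i{k}" for k in range(12)],
             "acc": rng.random(12),
             "dsc": np.clip(0.8 + shift + 0.05 * rng.standard_normal(12), 0, 1),
             "ji": rng.random(12)}
        )
        p = tmp_path / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    png = tmp_path / "box.png"
    table = compare_metrics(paths, metric="dsc", out_png=png)
    assert table.shape == (1, 1)
    assert 0.0 <= table.iloc[0, 0] <= 1.0
    assert png.exists()
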