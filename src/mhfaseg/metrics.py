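"""Segmentation evaluation: pixel confusion counts, accuracy, Dice and
Jaccard, plus a Wilcoxon rank-sum harness for comparing per-image metric
distributions between models.

Conventions: metrics are computed per image and macro-averaged.  When both
prediction and truth are empty, DSC and JI are defined as 1 (0 when exactly
one is empty), so every record is well defined.  The algebraic identity
``DSC = 2 JI / (1 + JI)`` holds whenever JI is defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "confusion",
    "acc",
    "dsc",
    "ji",
    "evaluate_pair",
    "evaluate_dirs",
    "aggregate",
    "wilcoxon_ranksum",
    "compare_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self):
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricRecord:
    image_id: str
    acc: float
    dsc: float
    ji: float


def _as_binary(a, name):
    a = np.asarray(a)
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1, True, False))):
        raise ValueError(f"{name} mask must be binary, found values {vals[:5]}")
    return a.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Exact pixel tallies of a binary prediction against ground truth."""
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def acc(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty image: accuracy undefined")
    return (c.TP + c.TN) / c.total


def dsc(c: ConfusionCounts) -> float:
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        return 1.0  # both masks empty
    return 2 * c.TP / denom


def ji(c: ConfusionCounts) -> float:
    denom = c.TP + c.FP + c.FN
    if denom == 0:
        return 1.0  # both masks empty
    return c.TP / denom


def evaluate_pair(pred, truth, image_id="image") -> MetricRecord:
    c = confusion(pred, truth)
    return MetricRecord(image_id=image_id, acc=acc(c), dsc=dsc(c), ji=ji(c))


def evaluate_dirs(pred_dir, truth_dir, pattern="mask_*.png") -> pd.DataFrame:
    """Evaluate matching mask files from two directories into a DataFrame."""
    from PIL import Image

    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    rows = []
    for tpath in sorted(truth_dir.glob(pattern)):
        ppath = pred_dir / tpath.name
        if not ppath.exists():
            raise FileNotFoundError(f"missing prediction for {tpath.name}")
        t = np.asarray(Image.open(tpath).convert("L")) > 127
        p = np.asarray(Image.open(ppath).convert("L")) > 127
        rows.append(evaluate_pair(p, t, image_id=tpath.stem).__dict__)
    return pd.DataFrame(rows, columns=["image_id", "acc", "dsc", "ji"])


def aggregate(df: pd.DataFrame) -> dict:
    """Macro average of the per-image records."""
    return {m: float(df[m].mean()) for m in ("acc", "dsc", "ji")}


# ----- Wilcoxon rank-sum --------------------------------------------------


def wilcoxon_ranksum(a, b, exact_max_n=10) -> float:
    """Two-sided rank-sum p-value.

    Exact enumeration of all rank assignments when both samples have at most
    ``exact_max_n`` observations; otherwise the normal approximation with
    tie correction and continuity correction.  The two-sided exact p-value
    counts permutations whose rank-sum deviates from its permutation mean by
    at least the observed deviation.  Degenerate all-tied inputs give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per sample")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    N = n1 + n2
    mu = n1 * (N + 1) / 2.0

    if n1 <= exact_max_n and n2 <= exact_max_n:
        dev = abs(w_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(N), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                count += 1
        return count / total

    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts)
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / math.sqrt(var)
    return float(2.0 * (1.0 - norm.cdf(max(z, 0.0))))


def compare_metrics(csv_paths, metric="dsc", out_png=None):
    """Rank-sum p-value table (last model vs the others) and a box plot.

    ``csv_paths`` are per-model metric CSVs as written by the evaluator; the
    final path is treated as the reference ("proposed") model.  Returns a
    DataFrame of p-values; optionally writes a box-plot figure.
    """
    frames = {Path(p).stem: pd.read_csv(p) for p in csv_paths}
    names = list(frames)
    ref = names[-1]
    pvals = {
        f"{name} vs. {ref}": wilcoxon_ranksum(frames[name][metric], frames[ref][metric])
        for name in names[:-1]
    }
    table = pd.DataFrame([pvals], index=[metric.upper()])
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.5 * len(names) + 2, 4))
        ax.boxplot([frames[n][metric] for n in names], tick_labels=names)
        ax.set_ylabel(metric.upper())
        ax.set_title(f"Per-image {metric.upper()} by model")
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return table
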