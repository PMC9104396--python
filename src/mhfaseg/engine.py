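"""Training and inference loop.

Defaults follow the reference protocol: Adam at learning rate 0.001, batch
size 4, up to 100 epochs, validation split 0.2, per-pixel binary
cross-entropy on the sigmoid head (soft Dice available), prediction
threshold 0.5.  Training is seeded and deterministic within one
environment; the best-validation-DSC weights are retained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .metrics import confusion, dsc
from .network import NetworkConfig, SegmentationModel, build_model

__all__ = ["TrainConfig", "train", "predict", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    lr: float = 1e-3
    batch_size: int = 4
    max_epochs: int = 100
    max_steps: int = None
    val_split: float = 0.2
    loss: str = "bce"
    threshold: float = 0.5
    seed: int = 0
    early_stop_patience: int = None
    stop_at_train_dsc: float = None

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("lr, batch_size and max_epochs must be positive")
        if not (0.0 <= self.val_split < 1.0):
            raise ValueError("val_split must be in [0, 1)")
        if self.optimizer != "adam":
            raise ValueError("only adam is supported")
        if self.loss not in ("bce", "dice"):
            raise ValueError("loss must be 'bce' or 'dice'")


def _prepare(images, masks):
    x = np.asarray(images, dtype=np.float32)
    y = np.asarray(masks, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError("images must be (N, H, W, C)")
    if y.ndim == 3:
        y = y[..., None]
    y = (y > 0.5).astype(np.float32)
    if len(x) == 0:
        raise ValueError("empty dataset")
    if len(x) != len(y):
        raise ValueError("images and masks count differ")
    return x, y


def _mean_dsc(model, x, y, threshold):
    scores = []
    for i in range(len(x)):
        p = model.predict_proba(x[i : i + 1])[0, :, :, 0] > threshold
        scores.append(dsc(confusion(p, y[i, :, :, 0] > 0.5)))
    return float(np.mean(scores))


def train(model: SegmentationModel, dataset, cfg: TrainConfig, val_dataset=None):
    """Train; returns a history dict.  ``dataset`` is (images, masks).

    An explicit ``val_dataset`` takes precedence over ``val_split``.  Raises
    on an empty dataset and aborts with a diagnostic on NaN loss.
    """
    x, y = _prepare(*dataset)
    rng = np.random.default_rng(cfg.seed)
    if val_dataset is not None:
        xv, yv = _prepare(*val_dataset)
        xt, yt = x, y
    elif cfg.val_split > 0 and len(x) >= 5:
        n_val = max(1, int(round(len(x) * cfg.val_split)))
        perm = rng.permutation(len(x))
        xv, yv = x[perm[:n_val]], y[perm[:n_val]]
        xt, yt = x[perm[n_val:]], y[perm[n_val:]]
    else:
        xt, yt = x, y
        xv, yv = x, y

    loss_fn = nn.bce_with_logits if cfg.loss == "bce" else nn.dice_loss
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    history = {"epoch_loss": [], "val_dsc": [], "steps": 0}
    best = {"val_dsc": -1.0, "weights": None}
    patience_left = cfg.early_stop_patience
    step = 0
    done = False

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(xt))
        losses = []
        for b0 in range(0, len(xt), cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            logits = model.forward(nn.Tensor(xt[idx]))
            loss = loss_fn(logits, yt[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss ({float(loss.data)}) at step {step}; "
                    "lower the learning rate or check the inputs"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
            if cfg.stop_at_train_dsc is not None and step % 10 == 0:
                if _mean_dsc(model, xt, yt, cfg.threshold) >= cfg.stop_at_train_dsc:
                    done = True
                    break
            if cfg.max_steps is not None and step >= cfg.max_steps:
                done = True
                break
        history["epoch_loss"].append(float(np.mean(losses)))
        vd = _mean_dsc(model, xv, yv, cfg.threshold)
        history["val_dsc"].append(vd)
        if vd > best["val_dsc"]:
            best["val_dsc"] = vd
            best["weights"] = [p.data.copy() for p in model.parameters()]
            patience_left = cfg.early_stop_patience
        elif cfg.early_stop_patience is not None:
            patience_left -= 1
            if patience_left <= 0:
                break
        if done:
            break
    history["steps"] = step
    history["best_val_dsc"] = best["val_dsc"]
    if best["weights"] is not None:
        for p, w in zip(model.parameters(), best["weights"]):
            p.data = w
    return history


def predict(model: SegmentationModel, img, threshold=0.5, return_proba=False):
    """Binary mask prediction for one image (H, W, 3) or a batch.

    Inputs whose spatial size does not divide by the pooling factor are
    resized (with a warning) to the model's configured input shape.
    """
    from skimage.transform import resize

    arr = np.asarray(img, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    cin = model.cfg.input_shape[2]
    if arr.shape[-1] != cin:
        raise ValueError(f"expected {cin} channels, got {arr.shape[-1]}")
    d = model.cfg.depth
    H, W = arr.shape[1:3]
    if H % (2 ** d) or W % (2 ** d):
        tgt = model.cfg.input_shape[:2]
        warnings.warn(f"resizing input {(H, W)} to {tgt} for prediction")
        arr = np.stack(
            [resize(a, (*tgt, cin), order=1, preserve_range=True) for a in arr]
        ).astype(np.float32)
    proba = model.predict_proba(arr)[..., 0]
    masks = proba > threshold
    if single:
        proba, masks = proba[0], masks[0]
    return (masks, proba) if return_proba else masks


def save_checkpoint(model: SegmentationModel, path):
    """Weights as an .npz plus the architectural config as JSON."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, **arrays)
    cfgpath = str(path) + ".json"
    with open(cfgpath, "w") as fh:
        json.dump(asdict(model.cfg), fh, indent=2)


def load_checkpoint(path):
    cfg = NetworkConfig(**json.load(open(str(path) + ".json")))
    model = build_model(cfg)
    data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    params = model.parameters()
    for i, p in enumerate(params):
        p.data = data[f"p{i}"].astype(np.float32)
    return model
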