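"""Trainable nucleus segmenter: a small encoder-decoder in pure NumPy.

A one-level network of the U-Net family: a 3x3 convolution block, a 2x
downsampling to a coarser context path, upsampling back and a skip
concatenation, then a 1x1 projection to a per-pixel nucleus probability.
Training minimises a mix of binary cross-entropy and soft dice loss with
Adam.  Forward and backward passes are written directly against NumPy
(im2col-free; per-offset accumulation), which keeps the model small,
dependency-light and bit-reproducible for a fixed seed.

The classical path in ``infiltra.segmentation`` remains the default
segmenter; this model is an optional drop-in honouring the same
LayerMask contract via :meth:`SegmenterModel.segment`.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .segmentation import LayerMask, SegConfig, overlap_metrics, _label_foreground


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 6
    learning_rate: float = 5e-3
    channels: int = 8
    val_fraction: float = 0.2
    bce_weight: float = 0.5
    dice_weight: float = 0.5
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.epochs < 1 or self.channels < 1:
            raise ValueError("epochs and channels must be positive")


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding KxK convolution; x (H,W,Cin), w (K,K,Cin,Cout)."""
    k = w.shape[0]
    pad = k // 2
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    h, wd = x.shape[:2]
    out = np.broadcast_to(b, (h, wd, w.shape[3])).copy()
    for dy in range(k):
        for dx in range(k):
            out += xp[dy : dy + h, dx : dx + wd] @ w[dy, dx]
    return out


def _conv_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    k = w.shape[0]
    pad = k // 2
    h, wd = x.shape[:2]
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for dy in range(k):
        for dx in range(k):
            dw[dy, dx] = np.tensordot(xp[dy : dy + h, dx : dx + wd], dout, axes=([0, 1], [0, 1]))
            dxp[dy : dy + h, dx : dx + wd] += dout @ w[dy, dx].T
    db = dout.sum(axis=(0, 1))
    dx_ = dxp[pad : pad + h, pad : pad + wd] if pad else dxp
    return dx_, dw, db


def _pool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    return x[: h - h % 2, : w - w % 2].reshape(h // 2, 2, w // 2, 2, c).mean(axis=(1, 3))


def _pool2_backward(dout: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    h, w, c = shape
    dx = np.zeros(shape)
    up = np.repeat(np.repeat(dout, 2, axis=0), 2, axis=1) / 4.0
    dx[: up.shape[0], : up.shape[1]] = up
    return dx


def _up2(x: np.ndarray, target_hw: tuple[int, int]) -> np.ndarray:
    up = np.repeat(np.repeat(x, 2, axis=0), 2, axis=1)
    return up[: target_hw[0], : target_hw[1]]


def _up2_backward(dout: np.ndarray, source_shape: tuple[int, ...]) -> np.ndarray:
    h2, w2, c = source_shape
    full = np.zeros((h2 * 2, w2 * 2, c))
    full[: dout.shape[0], : dout.shape[1]] = dout
    return full.reshape(h2, 2, w2, 2, c).sum(axis=(1, 3))


class SegmenterModel:
    """One-level encoder-decoder; ``predict`` returns a probability map."""

    PARAM_NAMES = ("w1", "b1", "w2", "b2", "w3", "b3", "w4", "b4")

    def __init__(self, channels: int, rng: np.random.Generator):
        c = channels

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "w1": he((3, 3, 1, c), 9), "b1": np.zeros(c),
            "w2": he((3, 3, c, 2 * c), 9 * c), "b2": np.zeros(2 * c),
            "w3": he((3, 3, 3 * c, c), 27 * c), "b3": np.zeros(c),
            "w4": he((1, 1, c, 1), c), "b4": np.zeros(1),
        }
        self.channels = c
        self.history: dict[str, list[float]] = {"loss": [], "train_iou": [], "val_iou": []}

    # forward ---------------------------------------------------------------
    def _forward(self, image: np.ndarray):
        x = np.asarray(image, dtype=np.float64)[..., None]
        a1 = _conv_forward(x, self.params["w1"], self.params["b1"])
        r1 = np.maximum(a1, 0.0)
        p = _pool2(r1)
        a2 = _conv_forward(p, self.params["w2"], self.params["b2"])
        r2 = np.maximum(a2, 0.0)
        u = _up2(r2, r1.shape[:2])
        cat = np.concatenate([r1, u], axis=-1)
        a3 = _conv_forward(cat, self.params["w3"], self.params["b3"])
        r3 = np.maximum(a3, 0.0)
        logit = _conv_forward(r3, self.params["w4"], self.params["b4"])[..., 0]
        prob = 1.0 / (1.0 + np.exp(-logit))
        cache = (x, a1, r1, p, a2, r2, u, cat, a3, r3, prob)
        return prob, cache

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel nucleus probability in [0, 1]."""
        return self._forward(image)[0]

    def segment(self, image: np.ndarray, config: SegConfig | None = None,
                layer_index: int = 0, prob_threshold: float = 0.5) -> LayerMask:
        """Drop-in replacement for the classical segmenter (same contract)."""
        config = config or SegConfig(method="cnn")
        fg = self.predict(image) > prob_threshold
        labels = _label_foreground(fg, config)
        return LayerMask(labels, layer_index, provenance="cnn")

    # backward --------------------------------------------------------------
    def _backward(self, cache, target: np.ndarray, bce_w: float, dice_w: float):
        x, a1, r1, p, a2, r2, u, cat, a3, r3, prob = cache
        t = np.asarray(target, dtype=np.float64)
        n = prob.size
        eps = 1e-7
        pc = np.clip(prob, eps, 1 - eps)
        bce = -np.mean(t * np.log(pc) + (1 - t) * np.log(1 - pc))
        inter = float((prob * t).sum())
        denom = float(prob.sum() + t.sum())
        dice = (2 * inter + eps) / (denom + eps)
        loss = bce_w * bce + dice_w * (1.0 - dice)

        # d loss / d prob
        dprob = bce_w * (pc - t) / (pc * (1 - pc) * n)
        dprob += dice_w * (-(2 * t * (denom + eps) - (2 * inter + eps)) / (denom + eps) ** 2)
        dlogit = dprob * prob * (1 - prob)

        grads = {}
        dr3, grads["w4"], grads["b4"] = _conv_backward(r3, self.params["w4"], dlogit[..., None])
        da3 = dr3 * (a3 > 0)
        dcat, grads["w3"], grads["b3"] = _conv_backward(cat, self.params["w3"], da3)
        c = self.channels
        dr1 = dcat[..., :c].copy()
        du = dcat[..., c:]
        dr2 = _up2_backward(du, r2.shape)
        da2 = dr2 * (a2 > 0)
        dp, grads["w2"], grads["b2"] = _conv_backward(p, self.params["w2"], da2)
        dr1 += _pool2_backward(dp, r1.shape)
        da1 = dr1 * (a1 > 0)
        _, grads["w1"], grads["b1"] = _conv_backward(x, self.params["w1"], da1)
        return loss, grads


def _iou_at_threshold(model: SegmenterModel, pairs, threshold: float = 0.5) -> float:
    """Mean IOU of thresholded predictions over (image, mask) pairs."""
    vals = []
    for image, mask in pairs:
        pred = model.predict(image) > threshold
        vals.append(overlap_metrics(pred, mask.astype(bool))[0])
    return float(np.mean(vals))


def all_background_iou(pairs) -> float:
    """IOU of the trivial all-background prediction (the baseline to beat)."""
    vals = [overlap_metrics(np.zeros_like(mask, dtype=bool), mask.astype(bool))[0]
            for _, mask in pairs]
    return float(np.mean(vals))


def train_segmenter(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                    config: TrainConfig | None = None) -> SegmenterModel:
    """Train the encoder-decoder on (image, binary mask) pairs.

    A held-out validation split (``val_fraction`` of the pairs) is
    mandatory; training and validation IOU are recorded per epoch in
    ``model.history``.  The objective mixes binary cross-entropy with
    dice loss.  Optimisation is Adam with per-image updates; with
    ``deterministic=True`` the data order and initialisation are fixed by
    the seed, so repeated runs give identical results.
    """
    config = config or TrainConfig()
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    n_val = int(round(len(pairs) * config.val_fraction))
    if n_val < 1 or n_val >= len(pairs):
        raise ValueError("validation split is empty; adjust val_fraction")
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(pairs))
    val = [pairs[i] for i in idx[:n_val]]
    train = [pairs[i] for i in idx[n_val:]]

    model = SegmenterModel(config.channels, rng)
    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for epoch in range(config.epochs):
        order = rng.permutation(len(train)) if not config.deterministic else \
            np.random.default_rng(config.seed + 1 + epoch).permutation(len(train))
        losses = []
        for i in order:
            image, mask = train[i]
            _, cache = model._forward(image)
            loss, grads = model._backward(cache, mask, config.bce_weight, config.dice_weight)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, sample {i}: {loss!r}; "
                    "reduce the learning rate or check the inputs"
                )
            losses.append(loss)
            step += 1
            for k, g in grads.items():
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                mhat = adam_m[k] / (1 - beta1**step)
                vhat = adam_v[k] / (1 - beta2**step)
                model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        model.history["loss"].append(float(np.mean(losses)))
        model.history["train_iou"].append(_iou_at_threshold(model, train))
        model.history["val_iou"].append(_iou_at_threshold(model, val))
    return model
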