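"""Compact convolutional network for gait-image feature extraction.

A deliberately small, dependency-free numpy implementation sized for
20x100 grayscale gait windows: a stack of 1-3 conv blocks (3x3 kernels,
stride 1, same padding, ReLU, 2x2 max-pool), a dense bottleneck of 8-16
units whose ReLU activations are the extracted feature vector, and a
2-way softmax head trained with cross-entropy and Adam.  Everything is
deterministic under the constructor seed (weight init and batch order
share one Generator).

Forward/backward convolutions use im2col / col2im; at these input sizes
a full training run is a few hundred milliseconds, which is what lets a
population-based optimizer afford dozens of candidate trainings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallCnn"]

KERNEL = 3


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N, H*W, C*9) patches with same padding, stride 1."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (KERNEL, KERNEL), axis=(2, 3))  # (N,C,H,W,3,3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * KERNEL * KERNEL)


def _col2im(dpatches: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, c, h, w = shape
    d = dpatches.reshape(n, h, w, c, KERNEL, KERNEL)
    dxp = np.zeros((n, c, h + 2, w + 2))
    for i in range(KERNEL):
        for j in range(KERNEL):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, 1 : 1 + h, 1 : 1 + w]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class _ConvBlock:
    weight: np.ndarray  # (F, C*9)
    bias: np.ndarray  # (F,)


class SmallCnn:
    """Conv stack -> dense feature bottleneck -> softmax pair head."""

    def __init__(
        self,
        n_conv_layers: int = 1,
        units_per_conv: int = 16,
        n_output_features: int = 8,
        learning_rate: float = 0.001,
        epochs: int = 20,
        input_shape: tuple[int, int] = (20, 100),
        batch_size: int = 16,
        augment_shift: bool = False,
        seed: int | None = None,
    ):
        if not (1 <= n_conv_layers <= 3):
            raise ValueError("n_conv_layers must lie in [1, 3]")
        self.n_conv_layers = n_conv_layers
        self.units = units_per_conv
        self.n_features = n_output_features
        self.lr = learning_rate
        self.epochs = epochs
        self.input_shape = input_shape
        self.batch_size = batch_size
        self.augment_shift = augment_shift
        self.rng = np.random.default_rng(seed)

        self.blocks: list[_ConvBlock] = []
        c, (h, w) = 1, input_shape
        for _ in range(n_conv_layers):
            fan_in = c * KERNEL * KERNEL
            wgt = self.rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(self.units, fan_in))
            self.blocks.append(_ConvBlock(wgt, np.zeros(self.units)))
            c, h, w = self.units, h // 2, w // 2
        self.flat_dim = c * h * w
        self.out_hw = (h, w)
        self.w_feat = self.rng.normal(0.0, np.sqrt(2.0 / self.flat_dim), size=(self.n_features, self.flat_dim))
        # small positive bias keeps bottleneck ReLU units initially live
        self.b_feat = np.full(self.n_features, 0.01)
        self.w_head = self.rng.normal(0.0, np.sqrt(2.0 / self.n_features), size=(2, self.n_features))
        self.b_head = np.zeros(2)

    # ---- forward pieces -------------------------------------------------
    def _forward(self, x: np.ndarray, keep: bool = False):
        """x: (N, H, W) in [0, 1]; returns logits and (optionally) caches."""
        a = x[:, None, :, :]
        caches = []
        for blk in self.blocks:
            n, c, h, w = a.shape
            patches = _im2col(a)
            conv = patches @ blk.weight.T + blk.bias  # (N, H*W, F)
            conv = conv.reshape(n, h, w, -1).transpose(0, 3, 1, 2)
            relu = np.maximum(conv, 0.0)
            h2, w2 = (h // 2) * 2, (w // 2) * 2
            windows = relu[:, :, :h2, :w2].reshape(n, relu.shape[1], h2 // 2, 2, w2 // 2, 2)
            pooled = windows.max(axis=(3, 5))
            if keep:
                caches.append((a.shape, patches, conv, relu, windows, pooled))
            a = pooled
        flat = a.reshape(a.shape[0], -1)
        feat_pre = flat @ self.w_feat.T + self.b_feat
        feat = np.maximum(feat_pre, 0.0)
        logits = feat @ self.w_head.T + self.b_head
        if keep:
            return logits, (caches, flat, feat_pre, feat)
        return logits

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # ---- training -------------------------------------------------------
    def fit(self, images: np.ndarray, labels: np.ndarray) -> "SmallCnn":
        """images: (N, H, W) scaled to [0, 1]; labels: 0 = control, 1 = pd."""
        x = np.asarray(images, dtype=float)
        y = np.asarray(labels, dtype=int)
        params = []
        for blk in self.blocks:
            params.extend([blk.weight, blk.bias])
        params.extend([self.w_feat, self.b_feat, self.w_head, self.b_head])
        opt = _Adam(params, self.lr)

        n = x.shape[0]
        for _ in range(self.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = x[idx]
                if self.augment_shift:
                    # window phase is arbitrary: circular time shifts are
                    # label-preserving and multiply the tiny training set
                    shifts = self.rng.integers(0, x.shape[2], size=idx.size)
                    xb = np.stack([np.roll(img, s, axis=1) for img, s in zip(xb, shifts)])
                grads = self._batch_gradients(xb, y[idx])
                opt.step(grads)
        return self

    def _batch_gradients(self, xb: np.ndarray, yb: np.ndarray) -> list[np.ndarray]:
        nb = xb.shape[0]
        logits, (caches, flat, feat_pre, feat) = self._forward(xb, keep=True)
        probs = self._softmax(logits)
        dlogits = probs.copy()
        dlogits[np.arange(nb), yb] -= 1.0
        dlogits /= nb

        dw_head = dlogits.T @ feat
        db_head = dlogits.sum(axis=0)
        dfeat = (dlogits @ self.w_head) * (feat_pre > 0)
        dw_feat = dfeat.T @ flat
        db_feat = dfeat.sum(axis=0)
        da = (dfeat @ self.w_feat).reshape(nb, -1, *self.out_hw)

        conv_grads: list[np.ndarray] = []
        for blk, cache in zip(reversed(self.blocks), reversed(caches)):
            in_shape, patches, conv, relu, windows, pooled = cache
            n, c, h, w = in_shape
            f = conv.shape[1]
            h2, w2 = (h // 2) * 2, (w // 2) * 2
            hp, wp = h2 // 2, w2 // 2
            # unpool: route gradient to exactly one argmax per 2x2 window
            mask = windows == pooled[:, :, :, None, :, None]  # (n,f,hp,2,wp,2)
            flat_mask = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, f, hp, wp, 4)
            flat_mask &= np.cumsum(flat_mask, axis=-1) <= 1
            mask = flat_mask.reshape(n, f, hp, wp, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            drelu = np.zeros_like(relu)
            drelu[:, :, :h2, :w2] = (mask * da[:, :, :, None, :, None]).reshape(n, f, h2, w2)
            dconv = drelu * (conv > 0)
            dcols = dconv.transpose(0, 2, 3, 1).reshape(n, h * w, f)  # (N, HW, F)
            dw = np.einsum("npf,npk->fk", dcols, patches)
            db = dcols.sum(axis=(0, 1))
            conv_grads[:0] = [dw, db]
            da = _col2im(dcols @ blk.weight, in_shape)

        return conv_grads + [dw_feat, db_feat, dw_head, db_head]

    # ---- inference ------------------------------------------------------
    def predict(self, images: np.ndarray) -> np.ndarray:
        return np.argmax(self._forward(np.asarray(images, dtype=float)), axis=1)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self._softmax(self._forward(np.asarray(images, dtype=float)))

    def features(self, images: np.ndarray) -> np.ndarray:
        """Penultimate-layer activations: the extracted feature table."""
        x = np.asarray(images, dtype=float)
        _, (_, _, _, feat) = self._forward(x, keep=True)
        return feat
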