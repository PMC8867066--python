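"""A small convolutional network with explicit forward/backward passes.

No deep-learning framework is available in the target environment, so the
classifier is implemented directly on numpy: three 3x3 conv blocks, global
average pooling and a dense head, trained with Adam on softmax
cross-entropy.  The last convolutional activation is exposed by name for
gradient-based class activation mapping.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = ["SmallCNN", "AdamOptimizer"]


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    """(N, C, H, W) -> (N, C, H, W, k*k) sliding 3x3 windows, same padding."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return cols.reshape(*cols.shape[:4], k * k)


def _conv(x: np.ndarray, W: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Same-padding 3x3 convolution; W is (out, in, 9)."""
    cols = _im2col(x)
    out = np.einsum("nchwi,oci->nohw", cols, W, optimize=True)
    if b is not None:
        out += b[None, :, None, None]
    return out


def _conv_input_grad(dout: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. the conv input = full correlation with flipped kernels."""
    Wr = W.reshape(W.shape[0], W.shape[1], 3, 3)[:, :, ::-1, ::-1]
    Wt = np.ascontiguousarray(Wr.transpose(1, 0, 2, 3)).reshape(W.shape[1], W.shape[0], 9)
    return _conv(dout, Wt, None)


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = (xr == out[:, :, :, None, :, None]).reshape(n, c, h, w)
    return out, mask


def _maxpool_grad(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, c, h2, w2 = dout.shape
    up = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3)
    return up * mask


class AdamOptimizer:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


class SmallCNN:
    """conv1-relu-pool / conv2-relu-pool / conv3-relu / GAP / dense head.

    ``last_conv`` names the layer whose post-ReLU activation Grad-CAM uses.
    """

    last_conv = "conv3"

    def __init__(self, input_size: int = 64, channels: tuple[int, int, int] = (8, 16, 32),
                 n_classes: int = 2, seed: int = 0):
        if input_size % 4 != 0:
            raise ValueError("input_size must be divisible by 4")
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        self.input_size = input_size
        self.channels = channels
        self.n_classes = n_classes

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)

        self.params: dict[str, np.ndarray] = {
            "W1": he((c1, 3, 9), 3 * 9), "b1": np.zeros(c1),
            "W2": he((c2, c1, 9), c1 * 9), "b2": np.zeros(c2),
            "W3": he((c3, c2, 9), c2 * 9), "b3": np.zeros(c3),
            "Wd": he((c3, n_classes), c3), "bd": np.zeros(n_classes),
        }

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """x: (N, H, W, 3) float in [0, 1] -> (logits, cache)."""
        p = self.params
        x = np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=np.float64)
        z1 = _conv(x, p["W1"], p["b1"]); a1 = np.maximum(z1, 0.0)
        p1, m1 = _maxpool(a1)
        z2 = _conv(p1, p["W2"], p["b2"]); a2 = np.maximum(z2, 0.0)
        p2, m2 = _maxpool(a2)
        z3 = _conv(p2, p["W3"], p["b3"]); a3 = np.maximum(z3, 0.0)
        gap = a3.mean(axis=(2, 3))
        logits = gap @ p["Wd"] + p["bd"]
        cache = {"x": x, "z1": z1, "m1": m1, "p1": p1, "z2": z2, "m2": m2,
                 "p2": p2, "z3": z3, "a3": a3, "gap": gap}
        return logits, cache

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            logits, _ = self.forward(x[i : i + batch_size])
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.vstack(out)

    # -- backward ----------------------------------------------------------
    def _backprop(self, dlogits: np.ndarray, cache: dict,
                  need_grads: bool = True, stop_at: str | None = None):
        """Backpropagate d(objective)/d(logits).

        Returns (param grads, d(objective)/d(a3)) — ``stop_at='conv3'``
        skips the remaining conv-block gradients.
        """
        p = self.params
        grads: dict[str, np.ndarray] = {}
        n, _, h3, w3 = cache["a3"].shape
        if need_grads:
            grads["Wd"] = cache["gap"].T @ dlogits
            grads["bd"] = dlogits.sum(axis=0)
        dgap = dlogits @ p["Wd"].T
        da3 = np.broadcast_to(
            dgap[:, :, None, None] / (h3 * w3), cache["a3"].shape
        ).copy()
        if stop_at == "conv3":
            return grads, da3
        dz3 = da3 * (cache["z3"] > 0)
        cols3 = _im2col(cache["p2"])
        grads["W3"] = np.einsum("nohw,nchwi->oci", dz3, cols3, optimize=True)
        grads["b3"] = dz3.sum(axis=(0, 2, 3))
        dp2 = _conv_input_grad(dz3, p["W3"])
        da2 = _maxpool_grad(dp2, cache["m2"])
        dz2 = da2 * (cache["z2"] > 0)
        cols2 = _im2col(cache["p1"])
        grads["W2"] = np.einsum("nohw,nchwi->oci", dz2, cols2, optimize=True)
        grads["b2"] = dz2.sum(axis=(0, 2, 3))
        dp1 = _conv_input_grad(dz2, p["W2"])
        da1 = _maxpool_grad(dp1, cache["m1"])
        dz1 = da1 * (cache["z1"] > 0)
        cols1 = _im2col(cache["x"])
        grads["W1"] = np.einsum("nohw,nchwi->oci", dz1, cols1, optimize=True)
        grads["b1"] = dz1.sum(axis=(0, 2, 3))
        return grads, da3

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> tuple[float, dict]:
        logits, cache = self.forward(x)
        n = len(y)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads, _ = self._backprop(dlogits, cache)
        return loss, grads

    def loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 64) -> float:
        probs = self.predict_proba(x, batch_size)
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    def conv_activation_and_gradient(
        self, x: np.ndarray, class_idx: int, layer: str = "conv3"
    ) -> tuple[np.ndarray, np.ndarray]:
        """Post-ReLU activation of the named conv layer and the gradient of
        the target-class logit with respect to it."""
        if layer != self.last_conv:
            raise KeyError(f"unknown conv layer {layer!r}; model exposes {self.last_conv!r}")
        logits, cache = self.forward(x)
        dlogits = np.zeros_like(logits)
        dlogits[:, class_idx] = 1.0
        _, da3 = self._backprop(dlogits, cache, need_grads=False, stop_at="conv3")
        return cache["a3"], da3

    def state_dict(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.params)

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.params = copy.deepcopy(state)
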