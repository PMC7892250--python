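"""A compact convolutional network in pure numpy.

Small, CPU-trainable backbone for binary scalp-image classification:

    input (H, W, 3) in [0, 1]
      -> fixed 4x4 average pool (224 -> 56)
      -> conv 3x3, 8 filters, ReLU, max pool 2
      -> conv 3x3, 16 filters, ReLU, max pool 2
      -> flatten -> dropout -> fully-connected -> softmax

Trained with Adam on softmax cross-entropy. All randomness (init, shuffling,
dropout) comes from one seeded Generator, so training is reproducible.
"""

from __future__ import annotations

import numpy as np


def _conv2d(xp: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'same' 3x3 convolution; xp is pre-padded (N, H+2, W+2, C), w (3,3,C,F)."""
    n, hp, wp, _ = xp.shape
    h, wid = hp - 2, wp - 2
    out = np.zeros((n, h, wid, w.shape[3]), dtype=xp.dtype)
    for dy in range(3):
        for dx in range(3):
            out += xp[:, dy : dy + h, dx : dx + wid, :] @ w[dy, dx]
    return out


def _conv2d_backward(xp: np.ndarray, w: np.ndarray, dout: np.ndarray):
    """Gradients of _conv2d w.r.t. weights and (padded) input."""
    n, hp, wp, _ = xp.shape
    h, wid = hp - 2, wp - 2
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for dy in range(3):
        for dx in range(3):
            patch = xp[:, dy : dy + h, dx : dx + wid, :]
            dw[dy, dx] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, dy : dy + h, dx : dx + wid, :] += dout @ w[dy, dx].T
    return dw, dxp


def _maxpool2(x: np.ndarray):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    # gradient split equally among ties (ties are measure-zero for real data)
    mask = xr == out[:, :, None, :, None, :]
    mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
    return out, (mask, x.shape)


def _maxpool2_backward(dout: np.ndarray, cache) -> np.ndarray:
    mask, shape = cache
    return (mask * dout[:, :, None, :, None, :]).reshape(shape)


def _avgpool(x: np.ndarray, k: int) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // k, k, w // k, k, c).mean(axis=(2, 4))


class ConvNet:
    """Compact scratch CNN with a 2-way softmax head."""

    def __init__(
        self,
        input_size: int = 224,
        dropout: float = 0.6,
        rng: np.random.Generator | None = None,
        pre_pool: int = 4,
        n_filters: tuple[int, int] = (8, 16),
    ):
        if input_size % (pre_pool * 4) != 0:
            raise ValueError("input_size must be divisible by pre_pool * 4")
        self.input_size = input_size
        self.dropout = float(dropout)
        self.pre_pool = pre_pool
        rng = rng or np.random.default_rng(0)
        f1, f2 = n_filters
        s = input_size // pre_pool  # spatial size after the fixed pool
        self._flat = (s // 4) * (s // 4) * f2
        he = lambda fan_in, shape: rng.normal(0, np.sqrt(2.0 / fan_in), shape)
        self.params = {
            "w1": he(9 * 3, (3, 3, 3, f1)).astype(np.float64),
            "b1": np.zeros(f1),
            "w2": he(9 * f1, (3, 3, f1, f2)).astype(np.float64),
            "b2": np.zeros(f2),
            # zero-init head: initial logits are 0 (maximum-entropy start),
            # which keeps the fixed small learning rate effective
            "wf": np.zeros((self._flat, 2)),
            "bf": np.zeros(2),
        }

    # -- forward -----------------------------------------------------------
    def _features(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        """Forward pass; returns logits and, in training, the backprop cache."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        x = (x - 0.5) * 2.0  # center the [0, 1] pixel range
        x0 = _avgpool(x, self.pre_pool)

        p = self.params
        x0p = np.pad(x0, ((0, 0), (1, 1), (1, 1), (0, 0)))
        a1 = _conv2d(x0p, p["w1"]) + p["b1"]
        r1 = np.maximum(a1, 0)
        m1, cache1 = _maxpool2(r1)

        m1p = np.pad(m1, ((0, 0), (1, 1), (1, 1), (0, 0)))
        a2 = _conv2d(m1p, p["w2"]) + p["b2"]
        r2 = np.maximum(a2, 0)
        m2, cache2 = _maxpool2(r2)

        flat = m2.reshape(m2.shape[0], -1)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (rng.random(flat.shape) < keep) / keep
            flat_d = flat * mask
        else:
            mask = None
            flat_d = flat
        logits = flat_d @ p["wf"] + p["bf"]
        cache = (x0p, a1, cache1, m1p, a2, cache2, flat, mask, flat_d)
        return logits, cache

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        """Class probabilities, (N, 2); deterministic (no dropout)."""
        x = np.asarray(x)
        single = x.ndim == 3
        if single:
            x = x[None]
        out = []
        for i in range(0, x.shape[0], batch):
            logits, _ = self._features(x[i : i + batch], train=False, rng=None)
            out.append(_softmax(logits))
        probs = np.concatenate(out, axis=0)
        return probs[0] if single else probs

    # -- training ----------------------------------------------------------
    def train_step(self, x, y, opt_state, lr, rng, t):
        """One Adam step on a minibatch; returns the batch loss."""
        logits, cache = self._features(x, train=True, rng=rng)
        probs = _softmax(logits)
        n = x.shape[0]
        loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        p = self.params
        x0p, a1, cache1, m1p, a2, cache2, flat, mask, flat_d = cache
        grads = {}
        grads["wf"] = flat_d.T @ dlogits
        grads["bf"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["wf"].T
        if mask is not None:
            dflat = dflat * mask
        s2 = int(np.sqrt(self._flat // p["w2"].shape[3]))
        dm2 = dflat.reshape(n, s2, s2, p["w2"].shape[3])
        dr2 = _maxpool2_backward(dm2, cache2)
        da2 = dr2 * (a2 > 0)
        grads["b2"] = da2.sum(axis=(0, 1, 2))
        grads["w2"], dm1p = _conv2d_backward(m1p, p["w2"], da2)
        dm1 = dm1p[:, 1:-1, 1:-1, :]
        dr1 = _maxpool2_backward(dm1, cache1)
        da1 = dr1 * (a1 > 0)
        grads["b1"] = da1.sum(axis=(0, 1, 2))
        grads["w1"], _ = _conv2d_backward(x0p, p["w1"], da1)

        _adam_update(self.params, grads, opt_state, lr, t)
        return loss

    # -- (de)serialization ---------------------------------------------------
    def state_dict(self) -> dict:
        d = {k: v.copy() for k, v in self.params.items()}
        d["__input_size"] = np.array(self.input_size)
        d["__dropout"] = np.array(self.dropout)
        d["__pre_pool"] = np.array(self.pre_pool)
        return d

    @classmethod
    def from_state_dict(cls, d: dict) -> "ConvNet":
        f1 = d["w1"].shape[3]
        f2 = d["w2"].shape[3]
        net = cls(
            input_size=int(d["__input_size"]),
            dropout=float(d["__dropout"]),
            pre_pool=int(d["__pre_pool"]),
            n_filters=(f1, f2),
        )
        for k in net.params:
            net.params[k] = np.asarray(d[k], dtype=np.float64)
        return net


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _adam_update(params, grads, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    for k, g in grads.items():
        if k not in state:
            state[k] = (np.zeros_like(g), np.zeros_like(g))
        m, v = state[k]
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        state[k] = (m, v)
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def train(
    net: ConvNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    epochs: int,
    lr: float,
    batch_size: int,
    seed: int,
) -> list[dict]:
    """Train the network in place; returns per-epoch history."""
    rng = np.random.default_rng(seed)
    opt_state: dict = {}
    history: list[dict] = []
    n = x_train.shape[0]
    t = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            t += 1
            losses.append(net.train_step(x_train[idx], y_train[idx], opt_state, lr, rng, t))
        val_acc = float((net.predict_proba(x_val).argmax(axis=1) == y_val).mean()) if len(y_val) else float("nan")
        history.append({"epoch": epoch + 1, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc})
    return history
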