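"""A compact NumPy U-Net for 2D binary segmentation.

Three-level encoder-decoder with 3x3 convolutions, ReLU activations,
2x2 max pooling, nearest-neighbour upsampling with skip concatenation and a
sigmoid output head, trained with the Adam optimizer on a binary
cross-entropy loss.  Forward and backward passes are written directly in
NumPy (im2col + GEMM), in float32, sized for desk-scale training on
128x128 projection images.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> (N,H,W,C*k*k) patches with 'same' zero padding."""
    if k == 1:
        return np.ascontiguousarray(x.transpose(0, 2, 3, 1))
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N,C,H,W,k,k) -> (N,H,W,C,k,k)
    n, c, h, w = x.shape
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h, w, c * k * k)


class Conv2d:
    """Same-padded k x k convolution with optional fused ReLU."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 relu: bool = True):
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.c_in, self.c_out, self.relu = k, c_in, c_out, relu
        self._cols: np.ndarray | None = None
        self._mask: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols = _im2col(x, self.k)
        out = cols @ self.W + self.b  # (N,H,W,c_out)
        mask = None
        if self.relu:
            mask = out > 0
            out *= mask
        if train:
            self._cols = cols
            self._mask = mask
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray):
        d = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))  # (N,H,W,c_out)
        if self.relu:
            d = d * self._mask
        n, h, w, _ = d.shape
        dflat = d.reshape(-1, self.c_out)
        self.dW = self._cols.reshape(-1, self.c_in * self.k * self.k).T @ dflat
        self.db = dflat.sum(axis=0)
        # dx: convolve dout with the spatially flipped, transposed kernel
        Wk = self.W.reshape(self.c_in, self.k, self.k, self.c_out)
        Wflip = Wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(
            self.c_out * self.k * self.k, self.c_in
        )
        dcols = _im2col(d.transpose(0, 3, 1, 2), self.k)
        dx = (dcols @ Wflip).transpose(0, 3, 1, 2)
        self._cols = self._mask = None
        return np.ascontiguousarray(dx)


class MaxPool2:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = xr.argmax(axis=-1)
        if train:
            self._idx, self._shape = idx, (n, c, h, w)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """3-level U-Net: widths (base, 2*base, 4*base), sigmoid output."""

    def __init__(self, base_width: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        b = base_width
        self.base_width = b
        self.seed = seed
        self.enc1a = Conv2d(1, b, 3, rng)
        self.enc1b = Conv2d(b, b, 3, rng)
        self.enc2a = Conv2d(b, 2 * b, 3, rng)
        self.enc2b = Conv2d(2 * b, 2 * b, 3, rng)
        self.bot_a = Conv2d(2 * b, 4 * b, 3, rng)
        self.bot_b = Conv2d(4 * b, 4 * b, 3, rng)
        self.dec2a = Conv2d(6 * b, 2 * b, 3, rng)
        self.dec2b = Conv2d(2 * b, 2 * b, 3, rng)
        self.dec1a = Conv2d(3 * b, b, 3, rng)
        self.dec1b = Conv2d(b, b, 3, rng)
        self.head = Conv2d(b, 1, 1, rng, relu=False)
        self.pool1, self.pool2 = MaxPool2(), MaxPool2()
        self.up2, self.up1 = Upsample2(), Upsample2()

    def conv_layers(self):
        return [self.enc1a, self.enc1b, self.enc2a, self.enc2b, self.bot_a,
                self.bot_b, self.dec2a, self.dec2b, self.dec1a, self.dec1b, self.head]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N,1,H,W) with H,W divisible by 4 -> logits (N,1,H,W)."""
        e1 = self.enc1b.forward(self.enc1a.forward(x, train), train)
        e2 = self.enc2b.forward(self.enc2a.forward(self.pool1.forward(e1, train), train), train)
        bt = self.bot_b.forward(self.bot_a.forward(self.pool2.forward(e2, train), train), train)
        u2 = np.concatenate([self.up2.forward(bt, train), e2], axis=1)
        d2 = self.dec2b.forward(self.dec2a.forward(u2, train), train)
        u1 = np.concatenate([self.up1.forward(d2, train), e1], axis=1)
        d1 = self.dec1b.forward(self.dec1a.forward(u1, train), train)
        if train:
            self._nc = (bt.shape[1], e2.shape[1], d2.shape[1], e1.shape[1])
        return self.head.forward(d1, train)

    def backward(self, dlogits: np.ndarray) -> None:
        nb, ne2, nd2, ne1 = self._nc
        dd1 = self.head.backward(dlogits)
        du1 = self.dec1a.backward(self.dec1b.backward(dd1))
        dd2 = self.up1.backward(du1[:, :nd2])
        de1 = du1[:, nd2:]
        du2 = self.dec2a.backward(self.dec2b.backward(dd2))
        dbt = self.up2.backward(du2[:, :nb])
        de2 = du2[:, nb:]
        dp2 = self.bot_a.backward(self.bot_b.backward(dbt))
        de2 = de2 + self.pool2.backward(dp2)
        dp1 = self.enc2a.backward(self.enc2b.backward(de2))
        de1 = de1 + self.pool1.backward(dp1)
        self.enc1a.backward(self.enc1b.backward(de1))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities for a batch (N,1,H,W)."""
        logits = self.forward(x.astype(np.float32), train=False)
        return 1.0 / (1.0 + np.exp(-logits))

    # -- persistence ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {"base_width": np.array(self.base_width)}
        for i, layer in enumerate(self.conv_layers()):
            state[f"W{i}"] = layer.W
            state[f"b{i}"] = layer.b
        return state

    def save(self, path: str | Path) -> None:
        np.savez(str(path), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        data = np.load(str(path))
        model = cls(base_width=int(data["base_width"]))
        for i, layer in enumerate(model.conv_layers()):
            layer.W = data[f"W{i}"].astype(np.float32)
            layer.b = data[f"b{i}"].astype(np.float32)
        return model


class Adam:
    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in (l.W, l.b)] for l in layers]
        self.v = [[np.zeros_like(p) for p in (l.W, l.b)] for l in layers]

    def step(self) -> None:
        self.t += 1
        corr1 = 1 - self.b1**self.t
        corr2 = 1 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate([(layer.W, layer.dW), (layer.b, layer.db)]):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def bce_loss_and_grad(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on sigmoid(logits) and its logit gradient."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    # stable log(1+exp): log1p(exp(-|z|)) + max(z,0) - z*y
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = ((p - y) / y.size).astype(np.float32)
    return float(loss), grad


def train_unet(
    images: np.ndarray,
    masks: np.ndarray,
    epochs: int = 30,
    batch_size: int = 4,
    lr: float = 2e-3,
    base_width: int = 8,
    seed: int = 0,
) -> tuple[UNet, list[float]]:
    """Train a U-Net on (N,H,W) images and binary masks; returns epoch losses.

    The seed fixes weight initialization and per-epoch shuffling, so a rerun
    with identical inputs reproduces identical losses and weights.
    """
    x = np.asarray(images, dtype=np.float32)[:, None]
    y = np.asarray(masks, dtype=np.float32)[:, None]
    model = UNet(base_width=base_width, seed=seed)
    opt = Adam(model.conv_layers(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    n = x.shape[0]
    losses: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits = model.forward(x[idx], train=True)
            loss, grad = bce_loss_and_grad(logits, y[idx])
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    return model, losses
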