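"""Convolutional autoencoder for movement-behavior images.

A four-layer strided convolutional encoder, a fully connected bottleneck
producing the latent variables, and a mirrored four-layer transposed-
convolution decoder with a sigmoid output. Trained with Adam on mean
squared reconstruction error. Implemented directly on numpy (im2col
convolutions with hand-derived gradients); all randomness flows from the
config seed, so runs are bit-reproducible on a fixed numpy build.

Every layer uses kernel 4, stride 2, padding 1, so each encoder layer
exactly halves the spatial side and each decoder layer doubles it; the
input side must therefore be divisible by 16.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KERNEL, STRIDE, PAD = 4, 2, 1


class ConfigurationError(ValueError):
    pass


@dataclass
class CAEConfig:
    input_side: int = 224
    channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    latent_dim: int = 32
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    output_activation: str = "sigmoid"  # "sigmoid" or "linear"
    relu_slope: float = 0.0  # 0 = plain ReLU; >0 = leaky
    batch_norm: bool = True  # normalize conv activations (faster convergence)

    def __post_init__(self) -> None:
        if self.input_side % (STRIDE**4) != 0:
            raise ConfigurationError("input_side must be divisible by 16")
        if self.latent_dim < 1:
            raise ConfigurationError("latent_dim must be >= 1")
        if len(self.channels) != 4:
            raise ConfigurationError("exactly four encoder layers")


# ---------------------------------------------------------------- im2col

def _out_size(n: int) -> int:
    return (n + 2 * PAD - KERNEL) // STRIDE + 1


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, oh*ow) patch matrix."""
    n, c, h, w = x.shape
    oh, ow = _out_size(h), _out_size(w)
    xp = np.pad(x, ((0, 0), (0, 0), (PAD, PAD), (PAD, PAD)))
    cols = np.empty((n, c, KERNEL, KERNEL, oh, ow), dtype=x.dtype)
    for i in range(KERNEL):
        for j in range(KERNEL):
            cols[:, :, i, j] = xp[:, :, i : i + STRIDE * oh : STRIDE, j : j + STRIDE * ow : STRIDE]
    return cols.reshape(n, c * KERNEL * KERNEL, oh * ow)


def _col2im(cols: np.ndarray, c: int, h: int, w: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patches back, accumulating."""
    n = cols.shape[0]
    oh, ow = _out_size(h), _out_size(w)
    colsr = cols.reshape(n, c, KERNEL, KERNEL, oh, ow)
    xp = np.zeros((n, c, h + 2 * PAD, w + 2 * PAD), dtype=cols.dtype)
    for i in range(KERNEL):
        for j in range(KERNEL):
            xp[:, :, i : i + STRIDE * oh : STRIDE, j : j + STRIDE * ow : STRIDE] += colsr[:, :, i, j]
    return xp[:, :, PAD : PAD + h, PAD : PAD + w]


# ---------------------------------------------------------------- layers

class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]


class _Conv(_Layer):
    """Strided convolution (downsampling by 2)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * KERNEL * KERNEL
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.c_in = c_in

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x)
        n = x.shape[0]
        oh, ow = _out_size(x.shape[2]), _out_size(x.shape[3])
        y = np.einsum("fk,nkp->nfp", self.w, self._cols) + self.b[None, :, None]
        return y.reshape(n, -1, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, f = dy.shape[:2]
        dyf = dy.reshape(n, f, -1)
        self.grads[0][...] = np.einsum("nfp,nkp->fk", dyf, self._cols)
        self.grads[1][...] = dyf.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfp->nkp", self.w, dyf)
        _, c, h, w = self._x_shape
        return _col2im(dcols, c, h, w)


class _ConvT(_Layer):
    """Transposed convolution (upsampling by 2); adjoint of :class:`_Conv`."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * KERNEL * KERNEL // (STRIDE * STRIDE)
        self.w = rng.normal(
            0, np.sqrt(2.0 / max(fan_in, 1)), (c_in, c_out * KERNEL * KERNEL)
        ).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.c_out = c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._x = x
        ho, wo = STRIDE * h, STRIDE * w
        xr = x.reshape(n, c, h * w)
        cols = np.einsum("ck,ncp->nkp", self.w, xr)
        y = _col2im(cols, self.c_out, ho, wo)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x.shape
        dcols = _im2col(dy)  # (n, c_out*k*k, h*w)
        xr = self._x.reshape(n, c, h * w)
        self.grads[0][...] = np.einsum("ncp,nkp->ck", xr, dcols)
        self.grads[1][...] = dy.sum(axis=(0, 2, 3))
        dx = np.einsum("ck,nkp->ncp", self.w, dcols)
        return dx.reshape(n, c, h, w)


class _Dense(_Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0, np.sqrt(2.0 / d_in), (d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


class _ReLU(_Layer):
    params: list = []
    grads: list = []

    def __init__(self, slope: float = 0.0):
        self.slope = slope

    def forward(self, x):
        self._scale = np.where(x > 0, 1.0, self.slope).astype(x.dtype)
        return x * self._scale

    def backward(self, dy):
        return dy * self._scale


class _BatchNorm(_Layer):
    """Per-channel batch normalization for (N, C, H, W) activations.

    Uses batch statistics during training and exponential running
    averages at inference, so encoding is deterministic after training.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu[None, :, None, None]) * self._inv_std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads[0][...] = np.sum(dy * self._xhat, axis=(0, 2, 3))
        self.grads[1][...] = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = np.sum(dxhat * self._xhat, axis=(0, 2, 3), keepdims=True)
        return (self._inv_std[None, :, None, None] / n) * (
            n * dxhat - s1 - self._xhat * s2
        )


class _Identity(_Layer):
    params: list = []
    grads: list = []

    def forward(self, x):
        return x

    def backward(self, dy):
        return dy


class ConvAutoencoder:
    """Encoder: 4 strided convolutions + dense bottleneck; decoder mirrors."""

    def __init__(self, config: CAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.channels
        side = config.input_side // STRIDE**4
        self._bottleneck_shape = (c[3], side, side)
        flat = c[3] * side * side
        self.enc_convs = [
            _Conv(3, c[0], rng), _Conv(c[0], c[1], rng),
            _Conv(c[1], c[2], rng), _Conv(c[2], c[3], rng),
        ]
        self.enc_relus = [_ReLU(config.relu_slope) for _ in range(4)]
        norm = _BatchNorm if config.batch_norm else (lambda ch: _Identity())
        self.enc_norms = [norm(c[0]), norm(c[1]), norm(c[2]), norm(c[3])]
        self.fc_enc = _Dense(flat, config.latent_dim, rng)
        self.fc_dec = _Dense(config.latent_dim, flat, rng)
        self.dec_relu0 = _ReLU(config.relu_slope)
        self.dec_convs = [
            _ConvT(c[3], c[2], rng), _ConvT(c[2], c[1], rng),
            _ConvT(c[1], c[0], rng), _ConvT(c[0], 3, rng),
        ]
        self.dec_norms = [norm(c[2]), norm(c[1]), norm(c[0])]
        self.dec_relus = [_ReLU(config.relu_slope) for _ in range(3)]
        self.layers: list[_Layer] = (
            self.enc_convs + self.enc_relus + self.enc_norms
            + [self.fc_enc, self.fc_dec, self.dec_relu0]
            + self.dec_convs + self.dec_norms + self.dec_relus
        )

    def set_training(self, training: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                layer.training = training

    # ------------------------------------------------------------ forward

    def _encode_batch(self, x: np.ndarray) -> np.ndarray:
        h = x
        for conv, bn, relu in zip(self.enc_convs, self.enc_norms, self.enc_relus):
            h = relu.forward(bn.forward(conv.forward(h)))
        self._pre_flat_shape = h.shape
        return self.fc_enc.forward(h.reshape(h.shape[0], -1))

    def _decode_batch(self, z: np.ndarray) -> np.ndarray:
        h = self.dec_relu0.forward(self.fc_dec.forward(z))
        h = h.reshape(z.shape[0], *self._bottleneck_shape)
        for i, conv in enumerate(self.dec_convs):
            h = conv.forward(h)
            if i < 3:
                h = self.dec_relus[i].forward(self.dec_norms[i].forward(h))
        self._logits = h
        if self.config.output_activation == "linear":
            return h
        return 1.0 / (1.0 + np.exp(-np.clip(h, -30, 30)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] != self.config.input_side or x.shape[3] != self.config.input_side:
            raise ValueError(
                f"expected {self.config.input_side}x{self.config.input_side} input, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        self._recon = self._decode_batch(self._encode_batch(x))
        return self._recon

    def backward(self, dy: np.ndarray) -> None:
        if self.config.output_activation == "linear":
            d = dy
        else:
            d = dy * self._recon * (1.0 - self._recon)  # sigmoid
        for i in range(3, -1, -1):
            if i < 3:
                d = self.dec_norms[i].backward(self.dec_relus[i].backward(d))
            d = self.dec_convs[i].backward(d)
        d = self.dec_relu0.backward(d.reshape(d.shape[0], -1))
        d = self.fc_dec.backward(d)
        d = self.fc_enc.backward(d)
        d = d.reshape(self._pre_flat_shape)
        for conv, bn, relu in zip(
            reversed(self.enc_convs), reversed(self.enc_norms), reversed(self.enc_relus)
        ):
            d = conv.backward(bn.backward(relu.backward(d)))

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


def build_cae(config: CAEConfig) -> ConvAutoencoder:
    return ConvAutoencoder(config)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _to_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4 or images.shape[3] != 3:
        raise ValueError("images must be (n, side, side, 3)")
    return np.transpose(images, (0, 3, 1, 2))


def train_cae(
    model: ConvAutoencoder, images: np.ndarray, config: CAEConfig | None = None
) -> tuple[ConvAutoencoder, list[float]]:
    """Train to minimize mean squared reconstruction error.

    ``images`` is (n, side, side, 3) in [0,1]. Returns the model and the
    per-epoch mean training loss (the learning curve).
    """
    config = config or model.config
    if len(images) == 0:
        raise ValueError("no training images")
    x_all = _to_nchw(images)
    n = len(x_all)
    model.set_training(True)
    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model.parameters, config.learning_rate)
    curve: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = x_all[idx]
            recon = model.forward(x)
            err = recon - x
            loss = float(np.mean(err**2))
            model.backward(2.0 * err / err.size)
            opt.step(model.gradients)
            total += loss * len(idx)
        curve.append(total / n)
    model.set_training(False)
    return model, curve


def encode(model: ConvAutoencoder, images: np.ndarray) -> np.ndarray:
    """Latent matrix (n, latent_dim); deterministic, preserves input order."""
    model.set_training(False)
    x = _to_nchw(images)
    out = []
    for start in range(0, len(x), 64):
        out.append(model._encode_batch(x[start : start + 64]))
    return np.concatenate(out, axis=0).astype(np.float64)


def reconstruct(model: ConvAutoencoder, images: np.ndarray) -> np.ndarray:
    """Reconstructions as (n, side, side, 3) in [0,1]."""
    model.set_training(False)
    x = _to_nchw(images)
    out = []
    for start in range(0, len(x), 64):
        xb = x[start : start + 64]
        out.append(np.transpose(model.forward(xb), (0, 2, 3, 1)))
    return np.concatenate(out, axis=0).astype(np.float64)


def _state_arrays(model: ConvAutoencoder) -> list[np.ndarray]:
    extra = []
    for layer in model.layers:
        if isinstance(layer, _BatchNorm):
            extra += [layer.running_mean, layer.running_var]
    return model.parameters + extra


def save_model(model: ConvAutoencoder, path) -> None:
    np.savez(path, *_state_arrays(model))


def load_model(path, config: CAEConfig) -> ConvAutoencoder:
    data = np.load(path)
    model = ConvAutoencoder(config)
    keys = sorted((k for k in data.files if k.startswith("arr_")),
                  key=lambda k: int(k.split("_")[1]))
    state = _state_arrays(model)
    if len(keys) != len(state):
        raise ValueError("checkpoint does not match the model configuration")
    for arr, k in zip(state, keys):
        arr[...] = data[k]
    model.set_training(False)
    return model
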