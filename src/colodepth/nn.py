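"""Minimal convolutional network engine (numpy, CPU).

Implements exactly the pieces the depth-prediction cGAN needs: strided
convolution and transposed convolution with hand-derived backward passes,
leaky-ReLU / ReLU / tanh / sigmoid activations, inverted dropout, a U-Net
encoder-decoder generator with skip connections (layer i concatenated to
layer L+1-i) and *no* batch normalization, a patch discriminator whose
per-patch sigmoid outputs are mean-aggregated to one scalar per image, and
an Adam optimizer.

All tensors are NCHW float64. Layers cache their forward inputs and expose
``backward(grad_out) -> grad_in`` which also accumulates parameter
gradients in ``self.grads``. Dropout is active at inference as well as
training (it plays the role of the generator's noise input z) and is
seeded through the ``rng`` handed to ``forward``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "UNetGenerator",
    "PatchDiscriminator",
    "Adam",
    "sigmoid",
]

INIT_STD = 0.02  # zero-mean normal weight init, pix2pix convention


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base: parameters and their gradients live in two parallel dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self):
        for g in self.grads.values():
            g[...] = 0.0


class Conv2d(Layer):
    """2-D cross-correlation, kernel k, stride s, symmetric zero padding p."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None):
        super().__init__()
        self.cin, self.cout, self.k, self.s, self.p = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, INIT_STD, (cout, cin, k, k))
        self.params["b"] = np.zeros(cout)
        self.grads = {n: np.zeros_like(v) for n, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, cin, h, w = x.shape
        k, s, p = self.k, self.s, self.p
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        W = self.params["W"]
        y = np.zeros((n, self.cout, ho, wo))
        for u in range(k):
            for v in range(k):
                xs = xp[:, :, u : u + s * ho : s, v : v + s * wo : s]
                y += np.einsum("ncij,oc->noij", xs, W[:, :, u, v], optimize=True)
        y += self.params["b"][None, :, None, None]
        self._cache = (xp, x.shape, ho, wo)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, xshape, ho, wo = self._cache
        k, s, p = self.k, self.s, self.p
        W = self.params["W"]
        dxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                xs = xp[:, :, u : u + s * ho : s, v : v + s * wo : s]
                self.grads["W"][:, :, u, v] += np.einsum(
                    "noij,ncij->oc", dy, xs, optimize=True
                )
                dxp[:, :, u : u + s * ho : s, v : v + s * wo : s] += np.einsum(
                    "noij,oc->ncij", dy, W[:, :, u, v], optimize=True
                )
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ConvTranspose2d(Layer):
    """Transposed convolution; with k=4, s=2, p=1 it exactly doubles H and W."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None):
        super().__init__()
        self.cin, self.cout, self.k, self.s, self.p = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, INIT_STD, (cin, cout, k, k))
        self.params["b"] = np.zeros(cout)
        self.grads = {n: np.zeros_like(v) for n, v in self.params.items()}

    def out_size(self, h):
        return (h - 1) * self.s - 2 * self.p + self.k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, cin, h, w = x.shape
        k, s, p = self.k, self.s, self.p
        ho, wo = self.out_size(h), self.out_size(w)
        W = self.params["W"]
        yp = np.zeros((n, self.cout, ho + 2 * p, wo + 2 * p))
        for u in range(k):
            for v in range(k):
                yp[:, :, u : u + s * (h - 1) + 1 : s, v : v + s * (w - 1) + 1 : s] += (
                    np.einsum("ncij,co->noij", x, W[:, :, u, v], optimize=True)
                )
        y = yp[:, :, p : p + ho, p : p + wo] + self.params["b"][None, :, None, None]
        self._cache = (x, ho, wo)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, ho, wo = self._cache
        n, cin, h, w = x.shape
        k, s, p = self.k, self.s, self.p
        W = self.params["W"]
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
        dx = np.zeros_like(x)
        for u in range(k):
            for v in range(k):
                dyps = dyp[
                    :, :, u : u + s * (h - 1) + 1 : s, v : v + s * (w - 1) + 1 : s
                ]
                dx += np.einsum("noij,co->ncij", dyps, W[:, :, u, v], optimize=True)
                self.grads["W"][:, :, u, v] += np.einsum(
                    "ncij,noij->co", x, dyps, optimize=True
                )
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        return dx


# ---- stateless activations (caches kept per call on the owning module) ----


def _leaky_relu(x, alpha):
    return np.where(x >= 0, x, alpha * x)


def _leaky_relu_grad(x, alpha):
    return np.where(x >= 0, 1.0, alpha)


class UNetGenerator:
    """Encoder-decoder with skip connections mapping RGB -> depth in [-1, 1].

    ``n_levels`` stride-2 encoder convolutions halve the image down to a
    bottleneck; the decoder mirrors them with transposed convolutions and
    concatenates the matching encoder activation onto each decoder level.
    Dropout (default p=0.5) is applied on decoder levels and stays active at
    inference, providing the stochastic input z. No batch normalization.
    """

    def __init__(
        self,
        in_channels=3,
        out_channels=1,
        n_levels=3,
        base_channels=8,
        max_channels=64,
        dropout_p=0.5,
        leak=0.2,
        seed=0,
    ):
        rng = np.random.default_rng(seed)
        self.n_levels = n_levels
        self.dropout_p = dropout_p
        self.leak = leak
        ch = [min(base_channels * 2**i, max_channels) for i in range(n_levels)]
        self.enc_channels = ch
        self.enc = []
        prev = in_channels
        for c in ch:
            self.enc.append(Conv2d(prev, c, 4, 2, 1, rng=rng))
            prev = c
        self.dec = []
        for i in range(n_levels - 1, 0, -1):
            self.dec.append(ConvTranspose2d(prev, ch[i - 1], 4, 2, 1, rng=rng))
            prev = 2 * ch[i - 1]  # after skip concatenation
        self.final = ConvTranspose2d(prev, out_channels, 4, 2, 1, rng=rng)

    # -- parameter plumbing -------------------------------------------------
    def layers(self):
        return [*self.enc, *self.dec, self.final]

    def zero_grad(self):
        for l in self.layers():
            l.zero_grad()

    def state_dict(self):
        out = {}
        for i, l in enumerate(self.layers()):
            for n, v in l.params.items():
                out[f"layer{i}.{n}"] = v.copy()
        return out

    def load_state_dict(self, sd):
        for i, l in enumerate(self.layers()):
            for n in l.params:
                l.params[n][...] = sd[f"layer{i}.{n}"]

    # -- forward / backward -------------------------------------------------
    def forward(self, c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Map an (N,3,H,W) image batch to an (N,1,H,W) map in [-1,1].

        H and W must be divisible by 2**n_levels. ``rng`` drives the dropout
        masks; pass a freshly seeded generator for reproducible outputs.
        """
        h = c.shape[2]
        if h % (2**self.n_levels) or c.shape[3] % (2**self.n_levels):
            raise ValueError(
                f"image size {c.shape[2:]} not divisible by 2^{self.n_levels}"
            )
        skips = []
        pre_acts = []
        x = c
        for conv in self.enc:
            z = conv.forward(x)
            pre_acts.append(z)
            x = _leaky_relu(z, self.leak)
            skips.append(x)
        dec_caches = []
        p = self.dropout_p
        for i, deconv in enumerate(self.dec):
            z = deconv.forward(x)
            a = np.maximum(z, 0.0)
            if p > 0:
                mask = (rng.random(a.shape) >= p) / (1.0 - p)
            else:
                mask = np.ones_like(a)
            d = a * mask
            skip = skips[self.n_levels - 2 - i]
            x = np.concatenate([d, skip], axis=1)
            dec_caches.append((z, mask, skip.shape[1]))
        zf = self.final.forward(x)
        y = np.tanh(zf)
        self._cache = (pre_acts, dec_caches, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(output); returns d(loss)/d(input image)."""
        pre_acts, dec_caches, y = self._cache
        dz = dy * (1.0 - y * y)
        dx = self.final.backward(dz)
        dskips = [None] * self.n_levels
        for i in range(len(self.dec) - 1, -1, -1):
            z, mask, skip_ch = dec_caches[i]
            dd = dx[:, : dx.shape[1] - skip_ch]
            dskip = dx[:, dx.shape[1] - skip_ch :]
            dskips[self.n_levels - 2 - i] = dskip
            da = dd * mask
            dz = da * (z > 0)
            dx = self.dec[i].backward(dz)
        for i in range(self.n_levels - 1, -1, -1):
            if dskips[i] is not None:
                dx = dx + dskips[i]
            dz = dx * _leaky_relu_grad(pre_acts[i], self.leak)
            dx = self.enc[i].backward(dz)
        return dx


class PatchDiscriminator:
    """Conditional patch discriminator.

    Input is the channel concatenation of the RGB condition image with a
    depth-like map. ``n_layers`` stride-2 convolutions with leaky-ReLU feed a
    final 1-channel convolution producing a logit per patch; patch sigmoids
    are mean-aggregated ('mean_patch', default) or the logits global-averaged
    before the sigmoid ('global'). Output: one probability in (0,1) per image.
    """

    def __init__(
        self,
        in_channels=4,
        n_layers=2,
        base_channels=8,
        max_channels=64,
        leak=0.2,
        aggregation="mean_patch",
        seed=0,
    ):
        if aggregation not in ("mean_patch", "global"):
            raise ValueError(f"unknown aggregation {aggregation!r}")
        rng = np.random.default_rng(seed)
        self.leak = leak
        self.aggregation = aggregation
        ch = [min(base_channels * 2**i, max_channels) for i in range(n_layers)]
        self.convs = []
        prev = in_channels
        for c in ch:
            self.convs.append(Conv2d(prev, c, 4, 2, 1, rng=rng))
            prev = c
        self.head = Conv2d(prev, 1, 3, 1, 1, rng=rng)

    def layers(self):
        return [*self.convs, self.head]

    def zero_grad(self):
        for l in self.layers():
            l.zero_grad()

    def state_dict(self):
        out = {}
        for i, l in enumerate(self.layers()):
            for n, v in l.params.items():
                out[f"layer{i}.{n}"] = v.copy()
        return out

    def load_state_dict(self, sd):
        for i, l in enumerate(self.layers()):
            for n in l.params:
                l.params[n][...] = sd[f"layer{i}.{n}"]

    def forward(self, c: np.ndarray, m: np.ndarray) -> np.ndarray:
        """Score (N,3,H,W) conditions against (N,1,H,W) maps -> (N,) probs."""
        if c.shape[0] != m.shape[0] or c.shape[2:] != m.shape[2:]:
            raise ValueError(f"condition {c.shape} and map {m.shape} misaligned")
        x = np.concatenate([c, m], axis=1)
        pre_acts = []
        for conv in self.convs:
            z = conv.forward(x)
            pre_acts.append(z)
            x = _leaky_relu(z, self.leak)
        logits = self.head.forward(x)  # (N,1,hp,wp)
        if self.aggregation == "mean_patch":
            s = sigmoid(logits)
            p = s.mean(axis=(1, 2, 3))
        else:
            pooled = logits.mean(axis=(1, 2, 3))
            p = sigmoid(pooled)
        self._cache = (pre_acts, logits, c.shape[1])
        return p

    def backward(self, dp: np.ndarray):
        """Backprop d(loss)/dp; returns (d_condition, d_map) input grads."""
        pre_acts, logits, c_ch = self._cache
        npatch = logits[0].size
        if self.aggregation == "mean_patch":
            s = sigmoid(logits)
            dlogits = dp[:, None, None, None] * s * (1.0 - s) / npatch
        else:
            pooled = logits.mean(axis=(1, 2, 3))
            sp = sigmoid(pooled)
            dlogits = np.broadcast_to(
                (dp * sp * (1.0 - sp) / npatch)[:, None, None, None], logits.shape
            ).copy()
        dx = self.head.backward(dlogits)
        for i in range(len(self.convs) - 1, -1, -1):
            dz = dx * _leaky_relu_grad(pre_acts[i], self.leak)
            dx = self.convs[i].backward(dz)
        return dx[:, :c_ch], dx[:, c_ch:]


class Adam:
    """Adam over a list of layers; beta1=0.5 (GAN convention), beta2=0.999."""

    def __init__(self, layers, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.layers = list(layers)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {n: np.zeros_like(v) for n, v in l.params.items()} for l in self.layers
        ]
        self.v = [
            {n: np.zeros_like(v) for n, v in l.params.items()} for l in self.layers
        ]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, l in enumerate(self.layers):
            for n, p in l.params.items():
                g = l.grads[n]
                self.m[i][n] = self.b1 * self.m[i][n] + (1 - self.b1) * g
                self.v[i][n] = self.b2 * self.v[i][n] + (1 - self.b2) * g * g
                mhat = self.m[i][n] / b1t
                vhat = self.v[i][n] / b2t
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
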