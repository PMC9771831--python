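"""A small 2D encoder-decoder segmentation network, implemented in numpy.

This is the package's reference per-view model: a U-Net-style fully
convolutional network with skip connections and an optional local
competition activation (paired-channel maximum, a maxout over channel
pairs).  It maps a 7-channel slice stack to a per-pixel class-probability
field and is small enough to train on a CPU in minutes while honoring the
same input/output contract a full-scale architecture would.

Convolutions are evaluated as im2col + BLAS matrix products with a
channels-last activation layout (batch, height, width, channels), which
keeps the patch assembly cache-friendly; every layer implements its own
backward pass, so training needs no external deep-learning runtime.

The model internally appends normalized in-plane coordinate channels and a
slice-position channel to its input (a CoordConv-style positional
encoding), which lets a shallow network resolve spatially defined
structures such as lobule wedges; the external contract (stacks in,
probabilities out) is unchanged.

All parameters are initialized deterministically from a seed and can be
serialized to an ``.npz`` checkpoint with a JSON config sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

VIEWS = ("axial", "coronal", "sagittal")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture configuration for one per-view network."""

    n_classes: int
    view: str
    in_channels: int = 7
    levels: int = 2
    base_filters: int = 16
    competition_enabled: bool = True
    coord_features: bool = True
    crop_side: int = 128  # working-crop side the model was trained on
    protocol_hash: str = ""

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.levels < 1 or self.base_filters < 1 or self.in_channels < 1:
            raise ValueError("levels, base_filters and in_channels must be positive")


# ---------------------------------------------------------------------------
# layers (channels-last: activations are (B, H, W, C))


class Conv2d:
    """k x k convolution with 'same' zero padding (stride 1)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = (rng.standard_normal((k * k * cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout, self.k = cin, cout, k
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.skip_dx = False  # set on the input layer, whose dx is unused
        self._cols: np.ndarray | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((b, h, w, k * k * c), dtype=x.dtype)
        for di in range(k):
            for dj in range(k):
                j = (di * k + dj) * c
                cols[..., j : j + c] = xp[:, di : di + h, dj : dj + w, :]
        return cols

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        cols = self._im2col(x) if self.k > 1 else x
        flat = cols.reshape(-1, cols.shape[-1])
        y = flat @ self.w + self.b
        if train:
            self._cols = flat
            self._in_shape = x.shape
        return y.reshape(b, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, _ = dy.shape
        dy2 = dy.reshape(-1, self.cout)
        self.dw += self._cols.T @ dy2
        self.db += dy2.sum(axis=0)
        self._cols = None
        if self.skip_dx:
            return None
        dcols = dy2 @ self.w.T
        if self.k == 1:
            return dcols.reshape(self._in_shape)
        k, p, c = self.k, self.k // 2, self.cin
        dcols = dcols.reshape(b, h, w, k * k * c)
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=dy.dtype)
        for di in range(k):
            for dj in range(k):
                j = (di * k + dj) * c
                dxp[:, di : di + h, dj : dj + w, :] += dcols[..., j : j + c]
        return dxp[:, p : p + h, p : p + w, :]

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class BatchNorm:
    """Per-channel batch normalization (channels-last).

    Training uses batch statistics over (B, H, W) and keeps exponential
    running estimates for inference.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2), dtype=np.float64)
            var = x.var(axis=(0, 1, 2), dtype=np.float64)
            self.run_mean += self.momentum * (mean.astype(np.float32) - self.run_mean)
            self.run_var += self.momentum * (var.astype(np.float32) - self.run_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.astype(x.dtype)) * inv.astype(x.dtype)
            self._xhat = xhat
            self._inv = inv.astype(x.dtype)
            self._n = x.shape[0] * x.shape[1] * x.shape[2]
            return xhat * self.gamma + self.beta
        inv = 1.0 / np.sqrt(self.run_var + self.eps)
        return (x - self.run_mean) * (inv * self.gamma) + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, n = self._xhat, self._inv, self._n
        self.dgamma += (dy * xhat).sum(axis=(0, 1, 2))
        self.dbeta += dy.sum(axis=(0, 1, 2))
        mean_dy = dy.mean(axis=(0, 1, 2))
        mean_dy_xhat = (dy * xhat).mean(axis=(0, 1, 2))
        dx = (self.gamma * inv) * (dy - mean_dy - xhat * mean_dy_xhat)
        self._xhat = None
        return dx.astype(dy.dtype)

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]


class Maxout2:
    """Local competition: maximum over adjacent channel pairs (2F -> F)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        a, b = x[..., 0::2], x[..., 1::2]
        if train:
            self._take_a = a >= b
        return np.maximum(a, b)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(dy.shape[:-1] + (dy.shape[-1] * 2,), dtype=dy.dtype)
        dx[..., 0::2] = np.where(self._take_a, dy, 0)
        dx[..., 1::2] = np.where(self._take_a, 0, dy)
        return dx

    def params(self):
        return []


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._neg = x < 0
        return np.where(x < 0, np.float32(self.slope) * x, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.copy()
        dy[self._neg] *= self.slope
        return dy

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, implemented as two pairwise maxima."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        a, b = x[:, 0::2], x[:, 1::2]
        m1 = np.maximum(a, b)
        c, d = m1[:, :, 0::2], m1[:, :, 1::2]
        out = np.maximum(c, d)
        if train:
            self._row_a = a >= b
            self._col_c = c >= d
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b_, h2, w2, c = dy.shape
        dm1 = np.zeros((b_, h2, w2 * 2, c), dtype=dy.dtype)
        dm1[:, :, 0::2] = np.where(self._col_c, dy, 0)
        dm1[:, :, 1::2] = np.where(self._col_c, 0, dy)
        dx = np.zeros((b_, h2 * 2, w2 * 2, c), dtype=dy.dtype)
        dx[:, 0::2] = np.where(self._row_a, dm1, 0)
        dx[:, 1::2] = np.where(self._row_a, 0, dm1)
        return dx

    def params(self):
        return []


class Upsample2:
    """Nearest-neighbor x2 upsampling."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = dy.shape
        return dy.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))

    def params(self):
        return []


class _Block:
    """Two convolutions, each batch-normalized, with the configured activation."""

    def __init__(self, cin: int, cout: int, competition: bool, rng):
        mult = 2 if competition else 1
        act = Maxout2 if competition else LeakyReLU
        self.layers = [
            Conv2d(cin, cout * mult, 3, rng), BatchNorm(cout * mult), act(),
            Conv2d(cout, cout * mult, 3, rng), BatchNorm(cout * mult), act(),
        ]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def params(self):
        out = []
        for li, l in enumerate(self.layers):
            for name, w, g in l.params():
                out.append((f"l{li}.{name}", w, g))
        return out


class ReferenceNet:
    """Encoder-decoder segmentation network satisfying the per-view contract.

    ``forward_logits`` and ``predict_proba`` take (B, 7, H, W) stacks and
    return (B, n_classes, H, W) fields; internally activations are
    channels-last.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        cf = config
        cin = cf.in_channels + (self.N_COORD_FEATURES if cf.coord_features else 0)
        f = [min(cf.base_filters * 2 ** i, 128) for i in range(cf.levels + 1)]
        self.enc = []
        c = cin
        for i in range(cf.levels):
            self.enc.append(_Block(c, f[i], cf.competition_enabled, rng))
            c = f[i]
        self.pools = [MaxPool2() for _ in range(cf.levels)]
        self.bottleneck = _Block(c, f[cf.levels], cf.competition_enabled, rng)
        self.proj = []
        self.ups = []
        self.dec = []
        c = f[cf.levels]
        for i in reversed(range(cf.levels)):
            self.proj.append(Conv2d(c, f[i], 1, rng))
            self.ups.append(Upsample2())
            self.dec.append(_Block(f[i], f[i], cf.competition_enabled, rng))
            c = f[i]
        self.classifier = Conv2d(c, cf.n_classes, 1, rng)
        self.enc[0].layers[0].skip_dx = True  # input gradient is never used
        self._coord_cache: dict[tuple[int, int], np.ndarray] = {}
        self._dtype = np.float32  # float64 only for numerical verification

    # -- plumbing -----------------------------------------------------
    def _modules(self):
        return (
            self.enc + self.pools + [self.bottleneck]
            + self.proj + self.ups + self.dec + [self.classifier]
        )

    def parameters(self):
        out = []
        for mi, m in enumerate(self._modules()):
            for name, w, g in m.params():
                out.append((f"m{mi}.{name}", w, g))
        return out

    def zero_grad(self) -> None:
        for _, _, g in self.parameters():
            g[...] = 0.0

    N_COORD_FEATURES = 6  # yy, xx, r, cos(theta), sin(theta), slice position

    def _with_coords(self, x: np.ndarray, slice_pos: np.ndarray | None) -> np.ndarray:
        """Append positional channels: in-plane coordinates on [-1, 1], the
        polar radius/angle about the slice center, and the normalized slice
        position along the view axis."""
        if not self.config.coord_features:
            return x
        b, h, w, _ = x.shape
        key = (h, w)
        if key not in self._coord_cache:
            yy, xx = np.meshgrid(
                np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij"
            )
            rr = np.sqrt(yy ** 2 + xx ** 2)
            th = np.arctan2(yy, xx)
            feats = np.stack([yy, xx, rr, np.cos(th), np.sin(th)], axis=-1)
            self._coord_cache[key] = feats.astype(np.float32)
        coords = np.broadcast_to(self._coord_cache[key], (b, h, w, 5))
        if slice_pos is None:
            slice_pos = np.zeros(b, dtype=np.float32)
        pos = np.asarray(slice_pos, np.float32).reshape(b, 1, 1, 1)
        pos = np.broadcast_to(pos, (b, h, w, 1))
        return np.concatenate([x, coords, pos], axis=-1)

    # -- forward / backward -------------------------------------------
    def forward_logits(
        self, x: np.ndarray, slice_pos: np.ndarray | None = None, train: bool = False
    ) -> np.ndarray:
        """Logits (B, n_classes, H, W) for stacks (B, in_channels, H, W)."""
        x = np.asarray(x, self._dtype)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (B, {self.config.in_channels}, H, W) input, got {x.shape}"
            )
        h, w = x.shape[2:]
        if h % 2 ** self.config.levels or w % 2 ** self.config.levels:
            raise ValueError("spatial size must be divisible by 2^levels")
        y = self._forward_cl(np.ascontiguousarray(x.transpose(0, 2, 3, 1)),
                             slice_pos, train)
        return y.transpose(0, 3, 1, 2)

    def _forward_cl(self, x, slice_pos, train):
        x = self._with_coords(x, slice_pos)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for proj, up, dec, skip in zip(self.proj, self.ups, self.dec, reversed(skips)):
            x = proj.forward(x, train)
            x = up.forward(x, train)
            x = x + skip
            x = dec.forward(x, train)
        return self.classifier.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients for (B, n_classes, H, W) dlogits."""
        self._backward_cl(np.ascontiguousarray(dlogits.transpose(0, 2, 3, 1)))

    def _backward_cl(self, dy):
        dy = self.classifier.backward(dy)
        dskips = []
        for proj, up, dec in zip(
            reversed(self.proj), reversed(self.ups), reversed(self.dec)
        ):
            dy = dec.backward(dy)
            dskips.append(dy)  # gradient into the skip addition
            dy = up.backward(dy)
            dy = proj.backward(dy)
        dy = self.bottleneck.backward(dy)
        # dskips were collected shallowest-first; encoder backward runs deepest-first
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy)
            dy = dy + dskip
            dy = blk.backward(dy)

    def predict_proba(
        self, x: np.ndarray, slice_pos: np.ndarray | None = None
    ) -> np.ndarray:
        """Softmax class probabilities, shape (B, n_classes, H, W)."""
        logits = self.forward_logits(x, slice_pos, train=False)
        return softmax_channels(logits)

    # channels-last fast path used by the training loop and view prediction
    def forward_logits_cl(self, x, slice_pos=None, train=False):
        """Logits (B, H, W, n_classes) for stacks (B, in_channels, H, W)."""
        x = np.asarray(x, self._dtype)
        return self._forward_cl(
            np.ascontiguousarray(x.transpose(0, 2, 3, 1)), slice_pos, train
        )

    def predict_proba_cl(self, x, slice_pos=None):
        """Probabilities (B, H, W, n_classes) for stacks (B, in_channels, H, W)."""
        return softmax_channels(self.forward_logits_cl(x, slice_pos), axis=-1)

    # -- serialization -------------------------------------------------
    def _state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {name: w for name, w, _ in self.parameters()}
        for mi, m in enumerate(self._modules()):
            layers = getattr(m, "layers", [m])
            for li, l in enumerate(layers):
                if isinstance(l, BatchNorm):
                    arrays[f"m{mi}.l{li}.run_mean"] = l.run_mean
                    arrays[f"m{mi}.l{li}.run_var"] = l.run_var
        return arrays

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self._state_arrays())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config), indent=1))

    @classmethod
    def load(cls, path) -> "ReferenceNet":
        path = Path(path)
        config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        net = cls(config, np.random.default_rng(0))
        with np.load(path.with_suffix(".npz")) as data:
            for name, arr in net._state_arrays().items():
                arr[...] = data[name]
        return net

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._state_arrays().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, arr in self._state_arrays().items():
            arr[...] = state[name]


def softmax_channels(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax over the class axis."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=axis, keepdims=True)


def build_reference_model(config: ModelConfig, rng: np.random.Generator) -> ReferenceNet:
    """Construct a deterministic, seed-initialized reference network."""
    return ReferenceNet(config, rng)
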