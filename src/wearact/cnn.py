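"""Three convolutional layouts for end-to-end window classification.

All three networks consume the same 68-sample, 9-channel windows and differ
only in how the channels are arranged for convolution:

* **CNN1** — 1-D temporal convolution, 5x1 kernel, the 9 channels stacked
  in the depth dimension (input 68 x 1 x 9).
* **CNN2** — 2-D convolution, 5x3 kernel over time x sensor (accelerometer,
  gyroscope, magnetometer rows), the x/y/z axes in depth (input 68 x 3 x 3).
* **CNN3** — a "2-D signal image": rows acc xyz, gyr xyz, mag xyz, acc xyz
  again (height 12, depth 1), 5x6 kernel with stride 1x3 in the first layer
  so every sensor pair is seen while axis bundles stay together.

Each of the three conv blocks is conv -> batch norm -> ReLU (valid
convolutions, no pooling), followed by a ReLU dense layer with dropout and
a 5-way softmax.  Training is plain SGD with an L2 penalty.  When a deeper
layer's kernel no longer fits the remaining height, the kernel height
clamps to that height (the kernel width stays 5) and the stride reverts to
1x1; this is the minimal reading of "the same kernels in subsequent layers"
that keeps all three layouts buildable.

The layer stack is implemented directly on numpy arrays (float32, BLAS
matmuls via im2col); at protocol-cohort scale it trains in minutes on one
CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .core_io import ActivityLabel

N_CLASSES = 5
WINDOW_LEN = 68
LABELS = [l.value for l in ActivityLabel]


class CnnLayout(str, Enum):
    CNN1 = "CNN1"
    CNN2 = "CNN2"
    CNN3 = "CNN3"


class ArchitectureError(ValueError):
    """Raised when the spatial dimensions underflow while stacking layers."""


class LayoutError(ValueError):
    """Raised when input windows lack the channels a layout needs."""


@dataclass
class CnnSpec:
    """Architecture + optimizer hyperparameters for one layout."""

    layout: CnnLayout
    kernel_wh: tuple[int, int]
    stride_first: tuple[int, int]
    filters: tuple[int, int, int]
    dense_size: int
    dropout_p: float
    learning_rate: float
    l2_reg: float
    batch: int
    epochs: int
    n_classes: int = N_CLASSES


#: tuned defaults per layout (SGD throughout)
DEFAULT_SPECS = {
    CnnLayout.CNN1: CnnSpec(
        layout=CnnLayout.CNN1, kernel_wh=(5, 1), stride_first=(1, 1),
        filters=(65, 100, 45), dense_size=583, dropout_p=0.6,
        learning_rate=0.0330, l2_reg=0.0030, batch=100, epochs=100,
    ),
    CnnLayout.CNN2: CnnSpec(
        layout=CnnLayout.CNN2, kernel_wh=(5, 3), stride_first=(1, 1),
        filters=(100, 57, 10), dense_size=1000, dropout_p=0.39,
        learning_rate=0.0480, l2_reg=0.0001, batch=100, epochs=100,
    ),
    CnnLayout.CNN3: CnnSpec(
        layout=CnnLayout.CNN3, kernel_wh=(5, 6), stride_first=(1, 3),
        filters=(59, 94, 58), dense_size=773, dropout_p=0.6,
        learning_rate=0.1000, l2_reg=0.0001, batch=59, epochs=100,
    ),
}

#: input geometry per layout: (height, depth)
LAYOUT_SHAPES = {
    CnnLayout.CNN1: (1, 9),
    CnnLayout.CNN2: (3, 3),
    CnnLayout.CNN3: (12, 1),
}


def layout_input(windows: np.ndarray, layout: CnnLayout) -> np.ndarray:
    """Rearrange (N, 68, 9) windows into the layout's (N, W, H, D) tensor.

    Channel order in the input follows the canonical 9-channel order
    (acc xyz, gyr xyz, mag xyz).
    """
    x = np.asarray(windows, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.shape[-1] != 9:
        raise LayoutError(f"need 9 channels, got {x.shape[-1]}")
    n, w, _ = x.shape
    if layout is CnnLayout.CNN1:
        return x.reshape(n, w, 1, 9)
    if layout is CnnLayout.CNN2:
        # height = sensor (acc, gyr, mag), depth = axis (x, y, z)
        return x.reshape(n, w, 3, 3)
    if layout is CnnLayout.CNN3:
        img = np.concatenate([x, x[..., :3]], axis=-1)   # repeat acc rows
        return img.reshape(n, w, 12, 1)
    raise LayoutError(f"unknown layout {layout}")


def inverse_layout(tensor: np.ndarray, layout: CnnLayout) -> np.ndarray:
    """Inverse of :func:`layout_input` (drops CNN3's duplicated rows)."""
    t = np.asarray(tensor)
    n, w = t.shape[:2]
    if layout is CnnLayout.CNN1:
        return t.reshape(n, w, 9)
    if layout is CnnLayout.CNN2:
        return t.reshape(n, w, 9)
    if layout is CnnLayout.CNN3:
        return t.reshape(n, w, 12)[..., :9]
    raise LayoutError(f"unknown layout {layout}")


# ---------------------------------------------------------------------------
# numpy layers


class _Conv:
    def __init__(self, kw, kh, cin, cout, stride, rng):
        fan_in = kw * kh * cin
        self.W = rng.normal(0, np.sqrt(2.0 / fan_in), size=(kw * kh * cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.kw, self.kh, self.cin, self.cout = kw, kh, cin, cout
        self.sw, self.sh = stride
        self.params = [("W", "dW"), ("b", "db")]

    def out_shape(self, w, h):
        ow = (w - self.kw) // self.sw + 1
        oh = (h - self.kh) // self.sh + 1
        if ow < 1 or oh < 1:
            raise ArchitectureError(
                f"kernel {self.kw}x{self.kh} does not fit input {w}x{h}"
            )
        return ow, oh

    def _im2col(self, x):
        n, w, h, c = x.shape
        ow, oh = self.out_shape(w, h)
        view = np.lib.stride_tricks.sliding_window_view(x, (self.kw, self.kh), axis=(1, 2))
        view = view[:, :: self.sw, :: self.sh]          # (n, ow, oh, c, kw, kh)
        cols = view.transpose(0, 1, 2, 4, 5, 3).reshape(n * ow * oh, self.kw * self.kh * c)
        return np.ascontiguousarray(cols), ow, oh

    def forward(self, x, train):
        self.x_shape = x.shape
        cols, ow, oh = self._im2col(x)
        self.cols = cols
        out = cols @ self.W + self.b
        return out.reshape(x.shape[0], ow, oh, self.cout)

    def backward(self, grad):
        n, ow, oh, cout = grad.shape
        g = grad.reshape(n * ow * oh, cout)
        self.dW = self.cols.T @ g
        self.db = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, ow, oh, self.kw, self.kh, self.cin)
        dx = np.zeros(self.x_shape, dtype=np.float32)
        for a in range(self.kw):
            for b in range(self.kh):
                dx[:, a : a + ow * self.sw : self.sw, b : b + oh * self.sh : self.sh] += dcols[:, :, :, a, b]
        return dx


class _BatchNorm:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.params = [("gamma", "dgamma"), ("beta", "dbeta")]

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self.std = np.sqrt(var + self.eps)
        self.xhat = (x - mean) / self.std
        self.axes = axes
        self.m = x.size // x.shape[-1]
        return self.gamma * self.xhat + self.beta

    def backward(self, grad):
        self.dgamma = (grad * self.xhat).sum(axis=self.axes)
        self.dbeta = grad.sum(axis=self.axes)
        g = grad * self.gamma
        dx = (
            g
            - g.mean(axis=self.axes)
            - self.xhat * (g * self.xhat).mean(axis=self.axes)
        ) / self.std
        return dx.astype(np.float32)


class _ReLU:
    params: list = []

    def forward(self, x, train):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class _Flatten:
    params: list = []

    def forward(self, x, train):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.shape)


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [("W", "dW"), ("b", "db")]

    def forward(self, x, train):
        self.x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self.x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


class _Dropout:
    params: list = []

    def __init__(self, p, rng):
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            self.mask = None
            return x
        self.mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class LayerInfo:
    name: str
    output_shape: tuple
    n_params: int


class CnnModel:
    """A built network: ordered layer stack plus its shape descriptor."""

    def __init__(self, spec: CnnSpec, seed: int = 0):
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        h, d = LAYOUT_SHAPES[spec.layout]
        w = WINDOW_LEN
        kw, kh = spec.kernel_wh
        self.layers: list = []
        self.info: list[LayerInfo] = []
        cin = d
        stride = spec.stride_first
        for i, cout in enumerate(spec.filters):
            k_h = min(kh, h)        # clamp kernel height to remaining height
            conv = _Conv(kw, k_h, cin, cout, stride, self.rng)
            w, h = conv.out_shape(w, h)
            self.layers += [conv, _BatchNorm(cout), _ReLU()]
            self.info.append(
                # conv weights + bias, batch-norm gamma + beta
                LayerInfo(f"conv{i + 1}", (w, h, cout), conv.W.size + conv.b.size + 2 * cout)
            )
            cin, stride = cout, (1, 1)  # stride reverts after the first layer
        self.layers.append(_Flatten())
        flat = w * h * cin
        dense = _Dense(flat, spec.dense_size, self.rng)
        self.layers += [dense, _ReLU(), _Dropout(spec.dropout_p, self.rng)]
        self.info.append(LayerInfo("dense", (spec.dense_size,), dense.W.size + dense.b.size))
        out = _Dense(spec.dense_size, spec.n_classes, self.rng)
        self.layers.append(out)
        self.info.append(LayerInfo("softmax", (spec.n_classes,), out.W.size + out.b.size))

    @property
    def n_params(self) -> int:
        return sum(li.n_params for li in self.info)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        x = layout_input(windows, self.spec.layout)
        return _softmax(self.forward(x, train=False))

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return self.predict_proba(windows).argmax(axis=1)

    def _step(self, xb: np.ndarray, yb: np.ndarray) -> tuple[float, float]:
        logits = self.forward(xb, train=True)
        probs = _softmax(logits)
        n = len(yb)
        loss = float(-np.log(probs[np.arange(n), yb] + 1e-12).mean())
        acc = float((probs.argmax(axis=1) == yb).mean())
        grad = probs.copy()
        grad[np.arange(n), yb] -= 1.0
        grad = (grad / n).astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        lr, l2 = self.spec.learning_rate, self.spec.l2_reg
        for layer in self.layers:
            for pname, gname in layer.params:
                p = getattr(layer, pname)
                g = getattr(layer, gname)
                if pname in ("W",):  # weight decay on weights only
                    g = g + l2 * p
                setattr(layer, pname, (p - lr * g).astype(np.float32))
        return loss, acc


def build_network(spec: CnnSpec, seed: int = 0) -> CnnModel:
    """Instantiate a layout; raises ArchitectureError on shape underflow."""
    return CnnModel(spec, seed=seed)


def encode_labels(labels: Sequence) -> np.ndarray:
    """Map ActivityLabel values to integer class ids (fixed order)."""
    index = {lab: i for i, lab in enumerate(LABELS)}
    return np.array([index[l.value if isinstance(l, ActivityLabel) else str(l)] for l in labels])


def train_cnn(
    model: CnnModel,
    windows: np.ndarray,
    labels: Sequence,
    *,
    epochs: Optional[int] = None,
    seed: int = 0,
) -> list[dict]:
    """SGD training with seeded shuffling; returns the per-epoch history."""
    spec = model.spec
    x = layout_input(windows, spec.layout)
    y = encode_labels(labels)
    n = len(y)
    epochs = spec.epochs if epochs is None else epochs
    rng = np.random.default_rng(seed)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, accs = [], []
        for lo in range(0, n, spec.batch):
            idx = order[lo : lo + spec.batch]
            loss, acc = model._step(x[idx], y[idx])
            losses.append(loss)
            accs.append(acc)
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": float(np.mean(accs))}
        )
    return history


def evaluate_cnn(
    model: CnnModel, windows: np.ndarray, labels: Sequence
) -> tuple[float, np.ndarray]:
    """Overall accuracy and row-normalized (percent) 5x5 confusion matrix."""
    y = encode_labels(labels)
    pred = model.predict(windows)
    acc = float((pred == y).mean())
    cm = np.zeros((N_CLASSES, N_CLASSES))
    for yi, pi in zip(y, pred):
        cm[yi, pi] += 1
    rows = cm.sum(axis=1, keepdims=True)
    cm = np.divide(cm, rows, out=np.zeros_like(cm), where=rows > 0) * 100.0
    return acc, cm
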