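"""Minimal NumPy layer library with hand-derived backpropagation.

Covers exactly what the denoiser architecture needs: strided 2-D convolution
with explicit asymmetric padding, transposed convolution, batch
normalization with running statistics, leaky-rectifier and tanh
activations, and a sequential container. Arrays are (batch, features,
height, width); "height" is the electrode axis and "width" the time axis.

Every layer implements ``forward(x, train)`` and ``backward(grad_out)``;
``backward`` returns the gradient with respect to the input and stores
parameter gradients next to the parameters. Correctness of each backward
pass is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

Pad2D = tuple[tuple[int, int], tuple[int, int]]  # ((top, bottom), (left, right))


class Layer:
    """Base class; layers without parameters only implement the two passes."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def gradients(self) -> dict[str, np.ndarray]:
        return {}

    def state(self) -> dict[str, np.ndarray]:
        """Everything needed to restore the layer (parameters + buffers)."""
        return self.parameters()

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.state().items():
            v[...] = state[k]


def conv_out_len(n: int, k: int, s: int, pad: tuple[int, int]) -> int:
    return (n + pad[0] + pad[1] - k) // s + 1


def _im2col(xp: np.ndarray, kernel: tuple[int, int], stride: tuple[int, int],
            out_hw: tuple[int, int]) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C*kh*kw, oh*ow) patch matrix (one copy)."""
    n, c, _, _ = xp.shape
    (kh, kw), (sh, sw) = kernel, stride
    oh, ow = out_hw
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, s2 * sh, s3 * sw), writeable=False)
    return view.reshape(n, c * kh * kw, oh * ow)


def _col2im_add(dxp: np.ndarray, dcols: np.ndarray, kernel: tuple[int, int],
                stride: tuple[int, int], out_hw: tuple[int, int]) -> None:
    """Scatter-add the adjoint of :func:`_im2col` into ``dxp`` in place."""
    n, c = dxp.shape[0], dxp.shape[1]
    (kh, kw), (sh, sw) = kernel, stride
    oh, ow = out_hw
    dview = dcols.reshape(n, c, kh, kw, oh, ow)
    for u in range(kh):
        for v in range(kw):
            dxp[:, :, u:u + sh * oh:sh, v:v + sw * ow:sw] += dview[:, :, u, v]


class Conv2D(Layer):
    """Strided cross-correlation with explicit per-side zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 stride: tuple[int, int], pad: Pad2D, gain: float = np.sqrt(2.0),
                 dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.gain = gain
        self.W = np.zeros((out_ch, in_ch, *kernel), dtype=dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None
        self._cols: np.ndarray | None = None
        self._out_hw: tuple[int, int] = (0, 0)

    def init_params(self, rng: np.random.Generator) -> None:
        fan_in = self.in_ch * self.kernel[0] * self.kernel[1]
        self.W[...] = rng.normal(0.0, self.gain / np.sqrt(fan_in), self.W.shape)
        self.b[...] = 0.0

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return (conv_out_len(h, self.kernel[0], self.stride[0], self.pad[0]),
                conv_out_len(w, self.kernel[1], self.stride[1], self.pad[1]))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.W.dtype)
        xp = np.pad(x, ((0, 0), (0, 0), self.pad[0], self.pad[1]))
        oh, ow = self.out_shape(x.shape[2], x.shape[3])
        cols = _im2col(xp, self.kernel, self.stride, (oh, ow))
        w2 = self.W.reshape(self.out_ch, -1)
        out = (w2[None] @ cols).reshape(x.shape[0], self.out_ch, oh, ow)
        out += self.b[None, :, None, None]
        if train:
            self._xp = xp
            self._cols = cols
            self._out_hw = (oh, ow)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._xp is not None, "backward before forward"
        oh, ow = self._out_hw
        n = grad.shape[0]
        g2 = grad.reshape(n, self.out_ch, oh * ow)
        self.dW[...] = np.tensordot(g2, self._cols, axes=([0, 2], [0, 2])).reshape(
            self.W.shape)
        self.db[...] = g2.sum(axis=(0, 2))
        w2 = self.W.reshape(self.out_ch, -1)
        dcols = w2.T[None] @ g2
        dxp = np.zeros_like(self._xp)
        _col2im_add(dxp, dcols, self.kernel, self.stride, (oh, ow))
        (pt, pb), (pl, pr) = self.pad
        h, w = dxp.shape[2] - pt - pb, dxp.shape[3] - pl - pr
        return dxp[:, :, pt:pt + h, pl:pl + w]

    def parameters(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def gradients(self) -> dict[str, np.ndarray]:
        return {"W": self.dW, "b": self.db}


class ConvTranspose2D(Layer):
    """Transposed (fractionally strided) convolution.

    ``pad`` crops the full scatter output on each side; ``output_padding``
    appends zero rows/columns at the bottom/right, mirroring the usual
    transposed-convolution output-size formula
    ``(in - 1) * stride + kernel - pad_total + output_padding``.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 stride: tuple[int, int], pad: Pad2D,
                 output_padding: tuple[int, int] = (0, 0),
                 gain: float = np.sqrt(2.0), dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.output_padding = output_padding
        self.gain = gain
        self.W = np.zeros((in_ch, out_ch, *kernel), dtype=dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def init_params(self, rng: np.random.Generator) -> None:
        fan_in = self.in_ch * self.kernel[0] * self.kernel[1]
        self.W[...] = rng.normal(0.0, self.gain / np.sqrt(fan_in), self.W.shape)
        self.b[...] = 0.0

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        (kh, kw), (sh, sw) = self.kernel, self.stride
        (pt, pb), (pl, pr) = self.pad
        oph, opw = self.output_padding
        return ((h - 1) * sh + kh - pt - pb + oph,
                (w - 1) * sw + kw - pl - pr + opw)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.W.dtype)
        (kh, kw), (sh, sw) = self.kernel, self.stride
        n, _, h, w = x.shape
        hf, wf = (h - 1) * sh + kh, (w - 1) * sw + kw
        # scatter-add of per-input-position kernel copies = adjoint of im2col
        x2 = x.reshape(n, self.in_ch, h * w)
        w2 = self.W.reshape(self.in_ch, self.out_ch * kh * kw)
        cols = w2.T[None] @ x2          # (n, out_ch*kh*kw, h*w)
        full = np.zeros((n, self.out_ch, hf, wf), dtype=self.W.dtype)
        _col2im_add(full, cols, self.kernel, self.stride, (h, w))
        (pt, pb), (pl, pr) = self.pad
        out = full[:, :, pt:hf - pb, pl:wf - pr]
        oph, opw = self.output_padding
        if oph or opw:
            out = np.pad(out, ((0, 0), (0, 0), (0, oph), (0, opw)))
        out = out + self.b[None, :, None, None]
        if train:
            self._x = x
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None, "backward before forward"
        x = self._x
        (kh, kw), (sh, sw) = self.kernel, self.stride
        (pt, pb), (pl, pr) = self.pad
        oph, opw = self.output_padding
        self.db[...] = grad.sum(axis=(0, 2, 3))
        if oph or opw:
            grad = grad[:, :, :grad.shape[2] - oph, :grad.shape[3] - opw]
        n, _, h, w = x.shape
        hf, wf = (h - 1) * sh + kh, (w - 1) * sw + kw
        dfull = np.zeros((n, self.out_ch, hf, wf), dtype=self.W.dtype)
        dfull[:, :, pt:hf - pb, pl:wf - pr] = grad
        dcols = _im2col(dfull, self.kernel, self.stride, (h, w))
        x2 = x.reshape(n, self.in_ch, h * w)
        w2 = self.W.reshape(self.in_ch, -1)
        dx = (w2[None] @ dcols).reshape(x.shape)
        self.dW[...] = np.tensordot(x2, dcols, axes=([0, 2], [0, 2])).reshape(
            self.W.shape)
        return dx

    def parameters(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def gradients(self) -> dict[str, np.ndarray]:
        return {"W": self.dW, "b": self.db}


class BatchNorm2D(Layer):
    """Per-feature-map batch normalization with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.n_ch = n_ch
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(n_ch, dtype=dtype)
        self.beta = np.zeros(n_ch, dtype=dtype)
        self.dgamma = np.zeros(n_ch, dtype=dtype)
        self.dbeta = np.zeros(n_ch, dtype=dtype)
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self._cache: tuple | None = None

    def init_params(self, rng: np.random.Generator) -> None:
        self.gamma[...] = 1.0
        self.beta[...] = 0.0
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
        if train:
            self._cache = (xhat, ivar, x.shape[0] * x.shape[2] * x.shape[3])
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cache is not None, "backward before forward"
        xhat, ivar, m = self._cache
        axes = (0, 2, 3)
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        dxhat = grad * self.gamma[None, :, None, None]
        # standard batch-norm backward, folded form
        dx = (ivar[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=axes)[None, :, None, None]
            - xhat * (dxhat * xhat).sum(axes)[None, :, None, None]
        )
        return dx

    def parameters(self) -> dict[str, np.ndarray]:
        return {"gamma": self.gamma, "beta": self.beta}

    def gradients(self) -> dict[str, np.ndarray]:
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self) -> dict[str, np.ndarray]:
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean, "running_var": self.running_var}


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x >= 0
        return np.where(x >= 0, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return np.where(self._mask, grad, self.slope * grad)


class Tanh(Layer):
    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.tanh(x)
        if train:
            self._y = y
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._y is not None
        return grad * (1.0 - self._y ** 2)


class Sequential:
    """Ordered layer stack with named layers for checkpointing."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers

    def init_params(self, rng: np.random.Generator) -> None:
        for _, layer in self.layers:
            if hasattr(layer, "init_params"):
                layer.init_params(rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for _, layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def named_parameters(self):
        """Yields (qualified_name, param, grad) triplets for the optimizer."""
        for name, layer in self.layers:
            params, grads = layer.parameters(), layer.gradients()
            for key in params:
                yield f"{name}.{key}", params[key], grads[key]

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, layer in self.layers:
            for key, val in layer.state().items():
                out[f"{name}.{key}"] = val.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            layer.load_state({k.split(".", 1)[1]: v for k, v in state.items()
                              if k.startswith(name + ".")})


class Residual:
    """Residual block: activation(main(x) + shortcut(x)).

    Both branches are Sequentials; the projection shortcut must produce the
    main branch's output shape. Parameter names are flattened with
    ``main.``/``shortcut.`` prefixes so the block nests transparently inside
    a :class:`Sequential`.
    """

    def __init__(self, main: "Sequential", shortcut: "Sequential", activation: Layer):
        self.main = main
        self.shortcut = shortcut
        self.activation = activation

    def init_params(self, rng: np.ndarray) -> None:
        self.main.init_params(rng)
        self.shortcut.init_params(rng)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        a = self.main.forward(x, train)
        b = self.shortcut.forward(x, train)
        if a.shape != b.shape:
            raise ValueError(
                f"residual branch shapes differ: main {a.shape} vs "
                f"shortcut {b.shape}")
        return self.activation.forward(a + b, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.activation.backward(grad)
        return self.main.backward(g) + self.shortcut.backward(g)

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, seq in (("main", self.main), ("shortcut", self.shortcut)):
            for name, p, _ in seq.named_parameters():
                out[f"{prefix}.{name}"] = p
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, seq in (("main", self.main), ("shortcut", self.shortcut)):
            for name, _, g in seq.named_parameters():
                out[f"{prefix}.{name}"] = g
        return out

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, seq in (("main", self.main), ("shortcut", self.shortcut)):
            for name, val in seq.state_dict().items():
                out[f"{prefix}.{name}"] = val
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.main.load_state_dict(
            {k[5:]: v for k, v in state.items() if k.startswith("main.")})
        self.shortcut.load_state_dict(
            {k[9:]: v for k, v in state.items() if k.startswith("shortcut.")})
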