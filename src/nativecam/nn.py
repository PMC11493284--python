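"""Compact CPU substrate for small 3D convolutional networks.

Layers carry their own explicit forward and backward passes in NumPy
(float64).  This explicitness is load-bearing for the attribution code:
Grad-CAM needs the activations of a named convolutional layer together
with the gradient of a class score with respect to them, and guided
backpropagation needs to *modify* the ReLU backward rule (transmit a
gradient only where the forward input was positive AND the incoming
gradient is positive).  Both are first-class operations here rather than
hooks bolted onto an opaque autodiff graph.

Array convention: activations are ``(N, C, D, H, W)``; convolutions use
odd cubic kernels with symmetric zero padding.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "ReLU",
    "GlobalAvgPool",
    "Linear",
    "Network",
    "Adam",
    "softmax",
    "cross_entropy_with_grad",
]

STANDARD = "standard"
GUIDED = "guided"


class Layer:
    """Base layer: stateless apart from parameters and the forward cache."""

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def gradients(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray, mode: str = STANDARD) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution (cross-correlation) with cubic kernel, stride, zero pad.

    Implemented as a sum over the k^3 kernel offsets of strided views, which
    keeps memory flat and is fast enough at the grid sizes this package
    trains on.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int = 1, rng: np.random.Generator | None = None):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size**3
        # He initialisation, appropriate for ReLU stacks
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                 size=(out_channels, in_channels, kernel_size, kernel_size, kernel_size))
        self.bias = np.zeros(out_channels)
        self._x_padded: np.ndarray | None = None
        self._grad_w = np.zeros_like(self.weight)
        self._grad_b = np.zeros_like(self.bias)

    def parameters(self):
        return {"weight": self.weight, "bias": self.bias}

    def gradients(self):
        return {"weight": self._grad_w, "bias": self._grad_b}

    def _out_spatial(self, in_shape):
        return tuple((n + 2 * self.padding - self.k) // self.stride + 1 for n in in_shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, *spatial = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        out_spatial = self._out_spatial(spatial)
        if any(m < 1 for m in out_spatial):
            raise ValueError(f"input spatial shape {tuple(spatial)} too small for kernel "
                             f"{self.k} stride {self.stride} padding {self.padding}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        self._x_padded = xp
        od, oh, ow = out_spatial
        s = self.stride
        out = np.zeros((n, self.out_channels, od, oh, ow))
        for i in range(self.k):
            for j in range(self.k):
                for l in range(self.k):
                    view = xp[:, :, i:i + s * od:s, j:j + s * oh:s, l:l + s * ow:s]
                    out += np.einsum("ncdhw,oc->nodhw", view, self.weight[:, :, i, j, l], optimize=True)
        return out + self.bias[None, :, None, None, None]

    def backward(self, grad_out: np.ndarray, mode: str = STANDARD) -> np.ndarray:
        xp = self._x_padded
        if xp is None:
            raise RuntimeError("backward called before forward")
        n, _, od, oh, ow = grad_out.shape
        s, p = self.stride, self.padding
        grad_xp = np.zeros_like(xp)
        gw = np.zeros_like(self.weight)
        for i in range(self.k):
            for j in range(self.k):
                for l in range(self.k):
                    view = xp[:, :, i:i + s * od:s, j:j + s * oh:s, l:l + s * ow:s]
                    gw[:, :, i, j, l] = np.einsum("nodhw,ncdhw->oc", grad_out, view, optimize=True)
                    grad_xp[:, :, i:i + s * od:s, j:j + s * oh:s, l:l + s * ow:s] += np.einsum(
                        "nodhw,oc->ncdhw", grad_out, self.weight[:, :, i, j, l], optimize=True)
        self._grad_w = gw
        self._grad_b = grad_out.sum(axis=(0, 2, 3, 4))
        if p:
            return grad_xp[:, :, p:-p, p:-p, p:-p]
        return grad_xp


class BatchNorm3d(Layer):
    """Per-channel batch normalisation with running statistics.

    Training mode normalises by the batch moments over (N, D, H, W) and
    updates exponential running averages; evaluation mode uses the
    running averages, so inference (and attribution) is deterministic
    per sample.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = True
        self._cache: tuple | None = None
        self._grad_gamma = np.zeros(channels)
        self._grad_beta = np.zeros(channels)

    def parameters(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean, "running_var": self.running_var}

    def gradients(self):
        # running stats are buffers: zero gradient keeps optimisers away
        return {"gamma": self._grad_gamma, "beta": self._grad_beta,
                "running_mean": np.zeros_like(self.running_mean),
                "running_var": np.zeros_like(self.running_var)}

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean[None, :, None, None, None]) * inv_std[None, :, None, None, None]
        self._cache = (x_hat, inv_std)
        return self.gamma[None, :, None, None, None] * x_hat + self.beta[None, :, None, None, None]

    def backward(self, grad_out: np.ndarray, mode: str = STANDARD) -> np.ndarray:
        x_hat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        self._grad_gamma = (grad_out * x_hat).sum(axis=axes)
        self._grad_beta = grad_out.sum(axis=axes)
        g = self.gamma[None, :, None, None, None] * grad_out
        if self.training:
            mean_g = g.mean(axis=axes)[None, :, None, None, None]
            mean_gx = (g * x_hat).mean(axis=axes)[None, :, None, None, None]
            return inv_std[None, :, None, None, None] * (g - mean_g - x_hat * mean_gx)
        return inv_std[None, :, None, None, None] * g


class ReLU(Layer):
    """Rectifier; in guided mode the backward pass also gates on the sign
    of the incoming gradient."""

    def __init__(self):
        self._pos_mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pos_mask = x > 0
        return np.where(self._pos_mask, x, 0.0)

    def backward(self, grad_out: np.ndarray, mode: str = STANDARD) -> np.ndarray:
        if self._pos_mask is None:
            raise RuntimeError("backward called before forward")
        grad = np.where(self._pos_mask, grad_out, 0.0)
        if mode == GUIDED:
            grad = np.where(grad > 0, grad, 0.0)
        elif mode != STANDARD:
            raise ValueError(f"unknown backprop mode {mode!r}")
        return grad


class GlobalAvgPool(Layer):
    """(N, C, D, H, W) -> (N, C): mean over the spatial axes."""

    def __init__(self):
        self._spatial: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad_out: np.ndarray, mode: str = STANDARD) -> np.ndarray:
        d, h, w = self._spatial
        scale = 1.0 / (d * h * w)
        return np.broadcast_to(
            grad_out[:, :, None, None, None] * scale, grad_out.shape + (d, h, w)
        ).copy()


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / in_features)
        self.weight = rng.uniform(-bound, bound, size=(out_features, in_features))
        self.bias = np.zeros(out_features)
        self._x: np.ndarray | None = None
        self._grad_w = np.zeros_like(self.weight)
        self._grad_b = np.zeros_like(self.bias)

    def parameters(self):
        return {"weight": self.weight, "bias": self.bias}

    def gradients(self):
        return {"weight": self._grad_w, "bias": self._grad_b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, grad_out: np.ndarray, mode: str = STANDARD) -> np.ndarray:
        self._grad_w = grad_out.T @ self._x
        self._grad_b = grad_out.sum(axis=0)
        return grad_out @ self.weight


class Network:
    """An ordered chain of named layers with introspectable backprop.

    ``forward`` caches every layer's output; ``backward`` then propagates a
    seed gradient from the logits down to the input, recording the gradient
    with respect to each layer's *output* along the way.  Attribution code
    reads activations and gradients by layer name.
    """

    def __init__(self, layers: list[tuple[str, Layer]]):
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.layers = layers
        self._activations: dict[str, np.ndarray] = {}
        self._input: np.ndarray | None = None

    @property
    def layer_names(self) -> list[str]:
        return [n for n, _ in self.layers]

    def layer(self, name: str) -> Layer:
        for n, l in self.layers:
            if n == name:
                return l
        raise KeyError(f"no layer named {name!r}; have {self.layer_names}")

    @property
    def first_conv_name(self) -> str:
        for n, l in self.layers:
            if isinstance(l, Conv3d):
                return n
        raise ValueError("network has no convolutional layer")

    def set_training(self, flag: bool) -> None:
        """Switch train/eval behaviour of normalisation layers."""
        for _, layer in self.layers:
            if hasattr(layer, "training"):
                layer.training = flag
            for sub in layer.__dict__.values():
                if isinstance(sub, Layer) and hasattr(sub, "training"):
                    sub.training = flag

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._input = x
        self._activations = {}
        for name, layer in self.layers:
            x = layer.forward(x)
            self._activations[name] = x
        return x

    def activation(self, name: str) -> np.ndarray:
        if name not in self._activations:
            raise KeyError(f"no cached activation for layer {name!r}; run forward first")
        return self._activations[name]

    def backward(self, grad_logits: np.ndarray, mode: str = STANDARD) -> dict[str, np.ndarray]:
        """Propagate ``grad_logits`` back to the input.

        Returns a dict mapping each layer name to the gradient w.r.t. that
        layer's output, plus ``"input"`` for the gradient w.r.t. the
        network input.
        """
        grads: dict[str, np.ndarray] = {}
        g = grad_logits
        for name, layer in reversed(self.layers):
            grads[name] = g
            g = layer.backward(g, mode=mode)
        grads["input"] = g
        return grads

    def class_score_gradients(self, x: np.ndarray, target_class: int,
                              mode: str = STANDARD) -> dict[str, np.ndarray]:
        """Gradients of the target-class logit w.r.t. every layer output."""
        logits = self.forward(x)
        seed = np.zeros_like(logits)
        seed[:, target_class] = 1.0
        return self.backward(seed, mode=mode)

    def parameters(self) -> list[tuple[str, str, np.ndarray]]:
        out = []
        for name, layer in self.layers:
            for pname, p in layer.parameters().items():
                out.append((name, pname, p))
        return out

    def gradients(self) -> list[tuple[str, str, np.ndarray]]:
        out = []
        for name, layer in self.layers:
            for pname, g in layer.gradients().items():
                out.append((name, pname, g))
        return out

    def num_parameters(self) -> int:
        return sum(p.size for _, _, p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": p.copy() for ln, pn, p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for ln, pn, p in self.parameters():
            key = f"{ln}.{pn}"
            if key not in state:
                raise KeyError(f"missing parameter {key} in state dict")
            if state[key].shape != p.shape:
                raise ValueError(f"shape mismatch for {key}")
            p[...] = state[key]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), targets] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adam optimiser over a network's parameter list (fixed learning rate)."""

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = {f"{ln}.{pn}": np.zeros_like(p) for ln, pn, p in net.parameters()}
        self._v = {f"{ln}.{pn}": np.zeros_like(p) for ln, pn, p in net.parameters()}

    def step(self) -> None:
        self.t += 1
        params = {f"{ln}.{pn}": p for ln, pn, p in self.net.parameters()}
        grads = {f"{ln}.{pn}": g for ln, pn, g in self.net.gradients()}
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for key, p in params.items():
            g = grads[key]
            m = self._m[key] = self.beta1 * self._m[key] + (1 - self.beta1) * g
            v = self._v[key] = self.beta2 * self._v[key] + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
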