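"""Minimal NumPy neural-network layers used by the spectral denoiser.

Only what the redundant convolutional encoder-decoder needs: 1-D
convolution along the frequency axis (with "same" padding so the 129-bin
dimension is preserved), per-channel batch normalization, and ReLU.
Forward and backward passes are written directly against BLAS-backed
matmuls (im2col), which is fast enough for the desk-scale experiments here
and keeps the determinism contract trivial: everything flows from one
``numpy.random.Generator``.

Data layout is (batch, channels, length) throughout.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_and_grads(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return []

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All arrays needed to restore the layer (parameters + buffers)."""
        return {name: p for name, p, _ in self.params_and_grads()}


class Conv1d(Layer):
    """Cross-correlation along the last axis with same-length zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        if kernel < 1:
            raise ParameterError("kernel size must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        bound = 1.0 / np.sqrt(in_channels * kernel)  # uniform fan-in scaling
        self.weight = rng.uniform(-bound, bound, size=(out_channels, in_channels, kernel))
        self.bias = rng.uniform(-bound, bound, size=out_channels)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, length = x.shape
        if c != self.in_channels:
            raise ParameterError(
                f"expected {self.in_channels} input channels, got {c}"
            )
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        # (b, c, length, kernel) view -> (b*length, c*kernel) design matrix
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        cols = windows.transpose(0, 2, 1, 3).reshape(b * length, c * self.kernel)
        out = cols @ self.weight.reshape(self.out_channels, -1).T + self.bias
        if training:
            self._cols = cols
            self._in_shape = x.shape
        return out.reshape(b, length, self.out_channels).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._in_shape is not None
        b, _, length = grad.shape
        g = grad.transpose(0, 2, 1).reshape(b * length, self.out_channels)
        self.dweight = (g.T @ self._cols).reshape(self.weight.shape)
        self.dbias = g.sum(axis=0)
        dcols = (g @ self.weight.reshape(self.out_channels, -1)).reshape(
            b, length, self.in_channels, self.kernel
        )
        dxp = np.zeros((b, self.in_channels, length + self.kernel - 1))
        for k in range(self.kernel):
            dxp[:, :, k : k + length] += dcols[:, :, :, k].transpose(0, 2, 1)
        self._cols = None
        return dxp[:, :, self.pad_left : self.pad_left + length]

    def params_and_grads(self):
        return [("weight", self.weight, self.dweight), ("bias", self.bias, self.dbias)]

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, length); running stats at eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_sd[None, :, None]
        if training:
            self._cache = (xhat, inv_sd)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv_sd = self._cache
        m = grad.shape[0] * grad.shape[2]
        self.dgamma = np.sum(grad * xhat, axis=(0, 2))
        self.dbeta = np.sum(grad, axis=(0, 2))
        gg = grad * self.gamma[None, :, None]
        dx = (
            gg
            - gg.mean(axis=(0, 2), keepdims=True)
            - xhat * np.mean(gg * xhat, axis=(0, 2), keepdims=True)
        ) * inv_sd[None, :, None]
        # note: means above divide by m = batch*length, matching train-time stats
        del m
        self._cache = None
        return dx

    def params_and_grads(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def state_arrays(self):
        return {
            "gamma": self.gamma,
            "beta": self.beta,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        out = grad * self._mask
        self._mask = None
        return out


class Network:
    """A plain feed-forward stack of layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params_and_grads(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, p, g in layer.params_and_grads():
                out.append((f"layer{i}.{name}", p, g))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.state_arrays().items():
                out[f"layer{i}.{name}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, arr in layer.state_arrays().items():
                key = f"layer{i}.{name}"
                if key not in state:
                    raise ParameterError(f"checkpoint missing array {key}")
                arr[...] = state[key]

    @property
    def n_params(self) -> int:
        return sum(getattr(layer, "n_params", 0) for layer in self.layers)


class SGDMomentum:
    """Classical momentum: v <- mu*v - lr*g; w <- w + v."""

    def __init__(self, network: Network, lr: float, momentum: float):
        self.network = network
        self.lr = lr
        self.momentum = momentum
        self.velocity = {name: np.zeros_like(p) for name, p, _ in network.params_and_grads()}

    def step(self) -> None:
        for name, p, g in self.network.params_and_grads():
            v = self.velocity[name]
            v *= self.momentum
            v -= self.lr * g
            p += v
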