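"""Learnable layers built on the autodiff tape.

Initialization: affine and attention weights use uniform fan-in scaling
(U[-1/sqrt(fan_in), 1/sqrt(fan_in)]); recurrent hidden-to-hidden matrices
are orthogonal.  All parameters are float64 by default for exact gradient
checks; training casts to float32 via ``Module.astype``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Tiny parameter-container base class."""

    def __init__(self):
        self.training = True

    #: names of non-learnable state arrays (e.g. running statistics)
    _buffer_names: tuple[str, ...] = ()

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}[{i}]")

    def named_buffers(self, prefix: str = ""):
        for name in self._buffer_names:
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            yield full, name, self
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}[{i}]")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def astype(self, dtype):
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for name, value in vars(m).items():
                if isinstance(value, np.ndarray) and value.dtype.kind == "f":
                    setattr(m, name, value.astype(dtype))
        return self

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for full, attr, module in self.named_buffers():
            out[full] = np.asarray(getattr(module, attr)).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        buffers = {full: (attr, module) for full, attr, module in self.named_buffers()}
        expected = set(own) | set(buffers)
        if expected != set(state):
            missing = expected ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()
        for full, (attr, module) in buffers.items():
            setattr(module, attr, state[full].copy())


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def _orthogonal(rng: np.random.Generator, shape) -> np.ndarray:
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    return q if shape[0] >= shape[1] else q.T


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_uniform_fan_in(rng, in_features, (in_features, out_features)))
        self.bias = Parameter(_uniform_fan_in(rng, in_features, (out_features,))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = ad.add(out, self.bias)
        return out


class GATConv(Module):
    """Single-head graph attention convolution on child->parent edges.

    Implements x'_i = alpha_ii Theta_s x_i + sum_{j in N(i)} alpha_ij Theta_t x_j
    with alpha the softmax over N(i) ∪ {i} of a . LeakyReLU(Theta_s x_i +
    Theta_t x_j) (negative slope 0.2), where N(i) is the set of children of
    node i.  Leaves therefore reduce to Theta_s x_i (+ bias).
    """

    NEGATIVE_SLOPE = 0.2

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.theta_s = Parameter(_uniform_fan_in(rng, in_features, (in_features, out_features)))
        self.theta_t = Parameter(_uniform_fan_in(rng, in_features, (in_features, out_features)))
        self.att = Parameter(_uniform_fan_in(rng, out_features, (out_features,)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def __call__(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        """``x``: (N_nodes, d); ``edge_index``: (2, E) rows (child, parent)."""
        child = np.asarray(edge_index[0], dtype=np.int64)
        parent = np.asarray(edge_index[1], dtype=np.int64)
        return ad.gat_conv_fused(
            x, self.theta_s, self.theta_t, self.att, self.bias,
            child, parent, self.NEGATIVE_SLOPE,
        )


class LayerNorm(Module):
    """Normalization over the feature axis of each row."""

    def __init__(self, num_features: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))

    def __call__(self, x: Tensor) -> Tensor:
        mu = ad.mean(x, axis=-1, keepdims=True)
        xc = ad.add(x, ad.mul(mu, -1.0))
        var = ad.mean(ad.mul(xc, xc), axis=-1, keepdims=True)
        inv = ad.power(ad.add(var, self.eps), -0.5)
        return ad.add(ad.mul(ad.mul(xc, inv), self.weight), self.bias)


class BatchNorm1d(Module):
    """Batch normalization with running statistics (standard semantics)."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = ad.mean(x, axis=0, keepdims=True)
            xc = ad.add(x, ad.mul(mu, -1.0))
            var = ad.mean(ad.mul(xc, xc), axis=0, keepdims=True)
            n = x.shape[0]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.reshape(-1)
            )
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            inv = ad.power(ad.add(var, self.eps), -0.5)
            return ad.add(ad.mul(ad.mul(xc, inv), self.weight), self.bias)
        xc = ad.add(x, Tensor(-self.running_mean))
        inv = Tensor(1.0 / np.sqrt(self.running_var + self.eps))
        return ad.add(ad.mul(ad.mul(xc, inv), self.weight), self.bias)


class GRU(Module):
    """Single-layer unidirectional gated recurrent unit.

    Gate order follows the common (reset, update, candidate) convention;
    parameter count is 3(IH + H^2 + 2H).
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        H = hidden_size
        self.w_ih = Parameter(_uniform_fan_in(rng, input_size, (input_size, 3 * H)))
        self.w_hh = Parameter(
            np.concatenate([_orthogonal(rng, (H, H)) for _ in range(3)], axis=1)
        )
        self.b_ih = Parameter(np.zeros(3 * H))
        self.b_hh = Parameter(np.zeros(3 * H))

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        H = self.hidden_size
        gi = ad.add(ad.matmul(x_t, self.w_ih), self.b_ih)
        gh = ad.add(ad.matmul(h, self.w_hh), self.b_hh)
        r = ad.sigmoid(ad.add(gi[:, 0:H], gh[:, 0:H]))
        z = ad.sigmoid(ad.add(gi[:, H : 2 * H], gh[:, H : 2 * H]))
        n = ad.tanh(ad.add(gi[:, 2 * H : 3 * H], ad.mul(r, gh[:, 2 * H : 3 * H])))
        one_minus_z = ad.add(ad.mul(z, -1.0), 1.0)
        return ad.add(ad.mul(one_minus_z, n), ad.mul(z, h))

    def __call__(self, x: Tensor, lengths: np.ndarray | None = None) -> Tensor:
        """Run over axis 1 of ``x`` (batch, steps, features); return final hidden.

        ``lengths`` masks padded steps: the hidden state stops updating after
        each row's true length, so the returned hidden equals the hidden at
        the last true step regardless of padding.
        """
        return ad.gru_sequence(x, self.w_ih, self.w_hh, self.b_ih, self.b_hh, lengths)
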