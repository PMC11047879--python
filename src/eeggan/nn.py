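"""Neural-network layers and optimizer built on :mod:`eeggan.autodiff`.

Layers follow the usual conventions: ``train()`` / ``eval()`` switch batch
normalization between batch and running statistics and toggle dropout;
parameters are ``Tensor`` leaves with ``requires_grad=True``.  The recurrent
layer implements the peephole LSTM update

    i_t = sigma(W_ix x_t + W_ih h_{t-1} + w_ic * c_{t-1} + b_i)
    f_t = sigma(W_fx x_t + W_fh h_{t-1} + w_fc * c_{t-1} + b_f)
    o_t = sigma(W_ox x_t + W_oh h_{t-1} + w_oc * c_{t-1} + b_o)
    c_t = f_t * c_{t-1} + i_t * tanh(W_cx x_t + W_ch h_{t-1} + b_c)
    h_t = o_t * tanh(c_t)

with elementwise (diagonal) peephole weights and all gates reading the
previous cell state, exactly as the gate equations above are written.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: parameter registry, train/eval mode, seedable RNGs."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, array: np.ndarray) -> Tensor:
        p = Tensor(array, requires_grad=True)
        self._params[name] = p
        return p

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for m in self._modules.values():
            out.extend(m.modules())
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def seed_rngs(self, seed: int):
        """Reseed every stochastic layer (dropout) deterministically."""
        ss = np.random.SeedSequence(seed)
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rng = np.random.default_rng(ss.spawn(1)[0])
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for n, p in self.named_parameters():
            p.data = np.asarray(state[n], dtype=np.float64).reshape(p.shape)
        return self

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.W = self.register("W", _glorot(rng, in_features, out_features, (in_features, out_features)))
        self.b = self.register("b", np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.W), self.b)


class Conv1d(Module):
    """1-D convolution via unfold + matmul; zero padding keeps control of length."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 dilation: int = 1):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.padding, self.dilation = kernel, stride, padding, dilation
        fan_in = in_channels * kernel
        self.W = self.register("W", _glorot(rng, fan_in, out_channels, (out_channels, fan_in)))
        self.b = self.register("b", np.zeros(out_channels))

    def out_length(self, length: int) -> int:
        eff = self.dilation * (self.kernel - 1) + 1
        return (length + 2 * self.padding - eff) // self.stride + 1

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, C, L)
        B, C, L = x.shape
        if self.padding:
            pad = Tensor(np.zeros((B, C, self.padding)))
            x = ad.concat([pad, x, pad], axis=2)
            L = L + 2 * self.padding
        l_out = (L - (self.dilation * (self.kernel - 1) + 1)) // self.stride + 1
        starts = np.arange(l_out) * self.stride
        taps = np.arange(self.kernel) * self.dilation
        idx = starts[None, :] + taps[:, None]          # (K, L_out)
        cols = ad.take(x, (slice(None), slice(None), idx))  # (B, C, K, L_out)
        cols = ad.reshape(cols, (B, C * self.kernel, l_out))
        y = ad.matmul(self.W, cols)                    # (B, O, L_out) via broadcast
        return ad.add(y, ad.reshape(self.b, (1, self.out_channels, 1)))


class BatchNorm(Module):
    """Batch normalization over all axes except ``feature_axis``."""

    def __init__(self, num_features: int, feature_axis: int = 1,
                 eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features, self.feature_axis = num_features, feature_axis
        self.eps, self.momentum = eps, momentum
        self.gamma = self.register("gamma", np.ones(num_features))
        self.beta = self.register("beta", np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        axis = self.feature_axis % x.ndim
        red = tuple(i for i in range(x.ndim) if i != axis)
        shape = tuple(self.num_features if i == axis else 1 for i in range(x.ndim))
        if self.training:
            m = ad.tmean(x, axis=red, keepdims=True)
            v = ad.tmean(ad.power(ad.add(x, ad.mul(m, -1.0)), 2.0), axis=red, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * m.data.reshape(-1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * v.data.reshape(-1)
        else:
            m = Tensor(self.running_mean.reshape(shape))
            v = Tensor(self.running_var.reshape(shape))
        xhat = ad.mul(ad.add(x, ad.mul(m, -1.0)), ad.power(ad.add(v, self.eps), -0.5))
        return ad.add(ad.mul(xhat, ad.reshape(self.gamma, shape)), ad.reshape(self.beta, shape))


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return ad.mul(x, Tensor(mask))


class LeakyReLU(Module):
    def __init__(self, slope: float):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ad.leaky_relu(x, self.slope)


class ELU(Module):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        return ad.elu(x, self.alpha)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.tanh(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.sigmoid(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Reshape(Module):
    def __init__(self, shape: tuple):
        super().__init__()
        self.shape = shape  # without batch axis

    def forward(self, x: Tensor) -> Tensor:
        return ad.reshape(x, (x.shape[0],) + tuple(self.shape))


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.reshape(x, (x.shape[0], -1))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class LSTM(Module):
    """Single peephole-LSTM layer applied over (B, T, F) sequences.

    States start at zero for every sequence; no statefulness across batches.
    The forget-gate bias is initialized to 1 (standard practice easing early
    gradient flow through the cell state).
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.input_size, self.hidden_size = input_size, hidden_size
        H, F = hidden_size, input_size
        for gate in ("i", "f", "o", "c"):
            self.register(f"Wx_{gate}", _glorot(rng, F, H, (F, H)))
            self.register(f"Wh_{gate}", _glorot(rng, H, H, (H, H)))
            self.register(f"b_{gate}", np.ones(H) if gate == "f" else np.zeros(H))
        for gate in ("i", "f", "o"):
            self.register(f"wc_{gate}", np.zeros(H))  # peephole, diagonal

    def forward(self, x: Tensor) -> Tensor:
        B, T, F = x.shape
        p = self._params
        H = self.hidden_size
        # input contributions for every step at once: (B, T, H) each
        xi = ad.matmul(x, p["Wx_i"])
        xf = ad.matmul(x, p["Wx_f"])
        xo = ad.matmul(x, p["Wx_o"])
        xc = ad.matmul(x, p["Wx_c"])
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(T):
            sl = (slice(None), t, slice(None))
            i = ad.sigmoid(ad.add(ad.add(ad.take(xi, sl), ad.matmul(h, p["Wh_i"])),
                                  ad.add(ad.mul(c, p["wc_i"]), p["b_i"])))
            f = ad.sigmoid(ad.add(ad.add(ad.take(xf, sl), ad.matmul(h, p["Wh_f"])),
                                  ad.add(ad.mul(c, p["wc_f"]), p["b_f"])))
            o = ad.sigmoid(ad.add(ad.add(ad.take(xo, sl), ad.matmul(h, p["Wh_o"])),
                                  ad.add(ad.mul(c, p["wc_o"]), p["b_o"])))
            g = ad.tanh(ad.add(ad.add(ad.take(xc, sl), ad.matmul(h, p["Wh_c"])), p["b_c"]))
            c = ad.add(ad.mul(f, c), ad.mul(i, g))
            h = ad.mul(o, ad.tanh(c))
            outs.append(h)
        return ad.stack(outs, axis=1)  # (B, T, H)


class Adam:
    """Adam optimizer with externally scheduled learning rate."""

    def __init__(self, params: list[Tensor], lr: float, betas: tuple[float, float] = (0.5, 0.9),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
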