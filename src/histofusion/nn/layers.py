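"""Neural-network modules built on the autodiff core.

Follows the familiar Module/Parameter idiom: submodules and parameters are
registered on attribute assignment, ``state_dict``/``load_state_dict`` move
weights in and out, and ``train()``/``eval()`` toggle dropout and batch-norm
behaviour.  Randomness (init, dropout) draws from a module-level generator
seeded with :func:`manual_seed` so runs are reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat

_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the generator used for parameter init and dropout masks."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def _kaiming(shape, fan_in):
    std = math.sqrt(2.0 / fan_in)
    return _RNG.normal(0.0, std, size=shape).astype(np.float32)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():  # batch-norm running stats
            out[name] = buf.copy()
        return out

    def named_buffers(self, prefix: str = ""):
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")
        if isinstance(self, BatchNorm2d):
            yield prefix + "running_mean", self.running_mean
            yield prefix + "running_var", self.running_var

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = dict(self._buffer_refs())
        for name, arr in state.items():
            if name in params:
                params[name].data = np.asarray(arr, dtype=np.float32).copy()
            elif name in buffers:
                owner, attr = buffers[name]
                setattr(owner, attr, np.asarray(arr, dtype=np.float32).copy())
            else:
                raise KeyError(f"unexpected entry in state dict: {name}")

    def _buffer_refs(self, prefix: str = ""):
        for name, m in self._modules.items():
            yield from m._buffer_refs(prefix + name + ".")
        if isinstance(self, BatchNorm2d):
            yield prefix + "running_mean", (self, "running_mean")
            yield prefix + "running_var", (self, "running_var")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._seq = []
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
            self._seq.append(m)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._seq)


class Identity(Module):
    def forward(self, x):
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.weight = Tensor(_kaiming((in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


# --------------------------------------------------------------- convolution

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    B, C, H, W = x.shape
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (B, C, kh, kw, oh, ow),
        (s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride))
    return np.ascontiguousarray(view).reshape(B, C * kh * kw, oh * ow), oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation; weight has shape (OC, C, kh, kw)."""
    OC, C, kh, kw = weight.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
    cols, oh, ow = _im2col(xd, kh, kw, stride)
    w2 = weight.data.reshape(OC, C * kh * kw)
    out = (w2 @ cols).reshape(xd.shape[0], OC, oh, ow)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gf = g.reshape(g.shape[0], OC, oh * ow)
        gw = np.einsum("bol,bkl->ok", gf, cols,
                       optimize=True).reshape(weight.shape)
        dcols = np.einsum("ok,bol->bkl", w2, gf, optimize=True)
        dcols = dcols.reshape(g.shape[0], C, kh, kw, oh, ow)
        dxp = np.zeros_like(xd)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + stride * oh:stride,
                    j:j + stride * ow:stride] += dcols[:, :, i, j]
        if padding:
            dxp = dxp[:, :, padding:-padding or None, padding:-padding or None]
        grads = [(x, dxp), (weight, gw)]
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return Tensor._make(out, parents, backward)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        k = kernel_size
        self.stride, self.padding = stride, padding
        self.weight = Tensor(_kaiming((out_ch, in_ch, k, k), in_ch * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.k, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        k, st, p = self.k, self.stride, self.padding
        xd = x.data
        if p:
            xd = np.pad(xd, ((0, 0), (0, 0), (p,) * 2, (p,) * 2),
                        constant_values=-np.inf)
        B, C, H, W = xd.shape
        oh = (H - k) // st + 1
        ow = (W - k) // st + 1
        s = xd.strides
        view = np.lib.stride_tricks.as_strided(
            xd, (B, C, k, k, oh, ow),
            (s[0], s[1], s[2], s[3], s[2] * st, s[3] * st))
        windows = np.ascontiguousarray(view).reshape(B, C, k * k, oh, ow)
        arg = windows.argmax(axis=2)
        out = np.take_along_axis(windows, arg[:, :, None], axis=2)[:, :, 0]

        def backward(g):
            di, dj = np.divmod(arg, k)
            oi = di + np.arange(oh)[None, None, :, None] * st
            oj = dj + np.arange(ow)[None, None, None, :] * st
            dxp = np.zeros((B, C, H, W), np.float32)
            bi = np.arange(B)[:, None, None, None]
            ci = np.arange(C)[None, :, None, None]
            np.add.at(dxp, (bi, ci, oi, oj), g)
            if p:
                dxp = dxp[:, :, p:-p, p:-p]
            return ((x, dxp),)

        return Tensor._make(out, (x,), backward)


# ------------------------------------------------------------- normalization

class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(num_features, np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, np.float32),
                           requires_grad=True)
        self.running_mean = np.zeros(num_features, np.float32)
        self.running_var = np.ones(num_features, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            rm = self.running_mean[None, :, None, None]
            rv = self.running_var[None, :, None, None]
            xhat = (x - Tensor(rm)) * Tensor(1.0 / np.sqrt(rv + self.eps))
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class LayerNorm(Module):
    """Normalizes over the last dimension with a learnable affine map.

    For a zero-variance (constant) input row the epsilon guard makes the
    normalized value 0, so the output collapses to the shift ``bias``.
    """

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Tensor(np.ones(dim, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * ((var + self.eps) ** -0.5)
        return xhat * self.weight + self.bias


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (_RNG.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


# -------------------------------------------------------------- functional

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # shift-invariant
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def multi_head_attention(q: Tensor, k: Tensor, v: Tensor, n_heads: int,
                         return_weights: bool = False):
    """Scaled dot-product attention over (B, T, d) with per-head d_k scaling."""
    B, T, d = q.shape
    if d % n_heads:
        raise ValueError(f"model dim {d} not divisible by {n_heads} heads")
    dk = d // n_heads

    def split(t):
        return t.reshape(B, T, n_heads, dk).transpose(0, 2, 1, 3)

    qh, kh, vh = split(q), split(k), split(v)
    scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dk))
    attn = softmax(scores, axis=-1)  # (B, h, T, T), rows sum to 1
    out = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, T, d)
    if return_weights:
        return out, attn.data
    return out


# ---------------------------------------------------------------- optimizer

class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params, lr: float = 2e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)


def cosine_warmup_lr(epoch: int, peak_lr: float, warmup_epochs: int,
                     total_epochs: int, floor: float = 0.0) -> float:
    """Linear warmup to ``peak_lr`` then cosine annealing toward ``floor``.

    The schedule reaches exactly ``peak_lr`` at the end of warmup
    (``epoch == warmup_epochs``).
    """
    if warmup_epochs > 0 and epoch < warmup_epochs:
        return peak_lr * (epoch + 1) / warmup_epochs
    span = max(total_epochs - warmup_epochs, 1)
    prog = min((epoch - warmup_epochs) / span, 1.0)
    return floor + 0.5 * (peak_lr - floor) * (1.0 + math.cos(math.pi * prog))
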