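"""Neural-network building blocks on top of the autograd engine.

Layout conventions: volumetric features are ``(C, D, H, W)`` without a batch
axis (the trainer feeds one patch per step); token sequences are
``(N_tokens, dim)``.
"""
from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, cat, softmax, unfold3d

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "PatchEmbed3d",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "ReLU",
    "GELU",
    "Sequential",
]


class Module:
    """Minimal module base: parameter discovery, train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.append(v)
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.append(item)
                        out.extend(item.modules())
        return out

    def named_parameters(self):
        out = []
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend((f"{name}.{n}", p) for n, p in v.named_parameters())
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend((f"{name}.{i}.{n}", p) for n, p in item.named_parameters())
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self):
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm3d):
                d[f"__bn{i}.running_mean"] = m.running_mean.copy()
                d[f"__bn{i}.running_var"] = m.running_var.copy()
        return d

    def load_state_dict(self, d):
        for name, p in self.named_parameters():
            p.data = np.asarray(d[name]).astype(p.data.dtype).reshape(p.data.shape)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm3d):
                m.running_mean = np.asarray(d[f"__bn{i}.running_mean"]).copy()
                m.running_var = np.asarray(d[f"__bn{i}.running_var"]).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in, n_out, rng, std=None, dtype=np.float32):
        super().__init__()
        std = std if std is not None else np.sqrt(2.0 / (n_in + n_out))
        self.W = Parameter(rng.normal(0, std, (n_in, n_out)).astype(dtype))
        self.b = Parameter(np.zeros(n_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.g = Parameter(np.ones(dim, dtype=dtype))
        self.b = Parameter(np.zeros(dim, dtype=dtype))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=-1, keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (v + self.eps).sqrt() * self.g + self.b


class MultiHeadSelfAttention(Module):
    def __init__(self, dim, heads, rng, dtype=np.float32):
        super().__init__()
        assert dim % heads == 0
        self.dim, self.heads, self.dh = dim, heads, dim // heads
        self.qkv = Linear(dim, 3 * dim, rng, std=0.02, dtype=dtype)
        self.proj = Linear(dim, dim, rng, std=0.02, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        qkv = self.qkv(x).reshape(n, 3, self.heads, self.dh).transpose(1, 2, 0, 3)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (heads, n, dh)
        att = softmax((q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.dh)), axis=-1)
        out = (att @ v).transpose(1, 0, 2).reshape(n, self.dim)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm ViT block: x + MHSA(LN(x)); x + MLP(LN(x))."""

    def __init__(self, dim, heads, ffn_dim, rng, dtype=np.float32):
        super().__init__()
        self.ln1 = LayerNorm(dim, dtype=dtype)
        self.attn = MultiHeadSelfAttention(dim, heads, rng, dtype=dtype)
        self.ln2 = LayerNorm(dim, dtype=dtype)
        self.fc1 = Linear(dim, ffn_dim, rng, std=0.02, dtype=dtype)
        self.fc2 = Linear(ffn_dim, dim, rng, std=0.02, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).gelu())


class PatchEmbed3d(Module):
    """Flatten non-overlapping cubic patches and project to the hidden dim."""

    def __init__(self, in_ch, patch_edge, hidden, grid, rng, dtype=np.float32):
        super().__init__()
        self.p = patch_edge
        self.grid = grid  # (gz, gy, gx)
        n_tok = int(np.prod(grid))
        self.proj = Linear(in_ch * patch_edge**3, hidden, rng, std=0.02, dtype=dtype)
        self.pos = Parameter(rng.normal(0, 0.02, (n_tok, hidden)).astype(dtype))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[0]
        gz, gy, gx = self.grid
        p = self.p
        t = x.reshape(c, gz, p, gy, p, gx, p)
        t = t.transpose(1, 3, 5, 0, 2, 4, 6).reshape(gz * gy * gx, c * p**3)
        return self.proj(t) + self.pos


class Conv3d(Module):
    """3D convolution, kernel 1 or 3 (pad preserves shape), stride 1.

    Channels-first im2col: out = W @ col, avoiding large permuted copies.
    """

    def __init__(self, c_in, c_out, k, rng, std=None, dtype=np.float32):
        super().__init__()
        assert k in (1, 3)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        fan_in = c_in * k**3
        std = np.sqrt(2.0 / fan_in) if std is None else std  # He for ReLU interiors
        self.W = Parameter(rng.normal(0, std, (c_out, fan_in)).astype(dtype))
        self.b = Parameter(np.zeros((c_out, 1), dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        C, D, H, W = x.shape
        if self.k == 1:
            col = x.reshape(C, D * H * W)
        else:
            col = unfold3d(x, 3, 1)
        out = self.W @ col + self.b
        return out.reshape(self.c_out, D, H, W)


class ConvTranspose3d(Module):
    """Transposed convolution with kernel 2, stride 2 (exact x2 upsampling)."""

    def __init__(self, c_in, c_out, rng, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.W = Parameter(rng.normal(0, np.sqrt(2.0 / c_in), (c_out * 8, c_in)).astype(dtype))
        self.b = Parameter(np.zeros((c_out, 1, 1, 1), dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        C, D, H, W = x.shape
        flat = self.W @ x.reshape(C, D * H * W)  # (c_out*8, DHW)
        t = flat.reshape(self.c_out, 2, 2, 2, D, H, W)
        t = t.transpose(0, 4, 1, 5, 2, 6, 3).reshape(self.c_out, 2 * D, 2 * H, 2 * W)
        return t + self.b


class BatchNorm3d(Module):
    """Per-channel normalization over the spatial axes of a single volume."""

    def __init__(self, c, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.g = Parameter(np.ones((c, 1, 1, 1), dtype=dtype))
        self.b = Parameter(np.zeros((c, 1, 1, 1), dtype=dtype))
        self.running_mean = np.zeros((c, 1, 1, 1), dtype=dtype)
        self.running_var = np.ones((c, 1, 1, 1), dtype=dtype)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            m = x.mean(axis=(1, 2, 3), keepdims=True)
            xc = x - m
            v = (xc * xc).mean(axis=(1, 2, 3), keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * m.data
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * v.data
            xhat = xc / (v + self.eps).sqrt()
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.g + self.b


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
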