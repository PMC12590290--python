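"""Neural-network building blocks on top of the autograd core.

Follows the familiar Module/Parameter pattern: parameters are discovered by
recursing over attributes, ``state_dict`` / ``load_state_dict`` move plain
numpy arrays, and ``train()`` / ``eval()`` toggle dropout. Weight matrices are
Xavier-initialized by default, matching the detector's training recipe.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, conv2d, dropout, max_pool2d, softmax

_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the generator used for initialization and dropout."""
    global _rng
    _rng = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _rng


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def xavier_uniform(fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return _rng.uniform(-bound, bound, size=shape if shape is not None else (fan_out, fan_in))


def kaiming_uniform(fan_in: int, shape) -> np.ndarray:
    """He init (ReLU gain): preserves activation scale through conv+ReLU stacks."""
    bound = math.sqrt(6.0 / fan_in)
    return _rng.uniform(-bound, bound, size=shape)


class Module:
    def __init__(self):
        self.training = True

    # attribute-walking discovery keeps the implementation small
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        buffers = getattr(self, "_buffers", {})
        for name, value in buffers.items():
            yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, array in state.items():
            if name in own:
                if own[name].data.shape != array.shape:
                    raise ValueError(f"shape mismatch for {name}")
                own[name].data = np.asarray(array, dtype=np.float64)
            elif name in buffers:
                buffers[name][...] = array
            else:
                raise KeyError(f"unexpected key {name!r} in state dict")
        missing = (set(own) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(xavier_uniform(in_features, out_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose()
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int):
        super().__init__()
        self.weight = Parameter(_rng.normal(0.0, 1.0, size=(num_embeddings, dim)))

    def forward(self, indices) -> Tensor:
        return self.weight[np.asarray(indices)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.weight + self.bias


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.training, _rng)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(kaiming_uniform(
            fan_in, shape=(out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class FrozenBatchNorm2d(Module):
    """Batch norm with statistics and affine terms frozen as buffers.

    Nothing here is trainable and no batch statistics are ever computed, so
    the layer is a fixed per-channel affine map — the small-batch training
    regime this detector targets makes live batch statistics unreliable.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5):
        super().__init__()
        self._buffers = {
            "weight": np.ones(num_channels),
            "bias": np.zeros(num_channels),
            "running_mean": np.zeros(num_channels),
            "running_var": np.ones(num_channels),
        }
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        b = self._buffers
        scale = (b["weight"] / np.sqrt(b["running_var"] + self.eps)).reshape(1, -1, 1, 1)
        shift = (b["bias"] - b["running_mean"] * scale.ravel()).reshape(1, -1, 1, 1)
        return x * scale + shift


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel_size, self.stride, self.padding)


class MultiheadAttention(Module):
    """Scaled dot-product attention over (L, B, C) sequences.

    ``attn_mask`` is an additive float mask broadcastable to
    ``(B*heads, L_q, L_k)``; ``-inf`` entries forbid attention.
    """

    def __init__(self, embed_dim: int, num_heads: int, dropout_p: float = 0.0):
        super().__init__()
        if embed_dim % num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")
        self.embed_dim = embed_dim
        self.num_heads = num_heads
        self.head_dim = embed_dim // num_heads
        self.q_proj = Linear(embed_dim, embed_dim)
        self.k_proj = Linear(embed_dim, embed_dim)
        self.v_proj = Linear(embed_dim, embed_dim)
        self.out_proj = Linear(embed_dim, embed_dim)
        self.dropout = Dropout(dropout_p)

    def _split(self, x: Tensor, length: int, batch: int) -> Tensor:
        # (L, B, C) -> (B*heads, L, head_dim)
        return (x.reshape(length, batch, self.num_heads, self.head_dim)
                 .transpose(1, 2, 0, 3)
                 .reshape(batch * self.num_heads, length, self.head_dim))

    def forward(self, query: Tensor, key: Tensor, value: Tensor,
                attn_mask=None) -> Tensor:
        lq, batch, _ = query.shape
        lk = key.shape[0]
        q = self._split(self.q_proj(query), lq, batch)
        k = self._split(self.k_proj(key), lk, batch)
        v = self._split(self.v_proj(value), lk, batch)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(self.head_dim))
        if attn_mask is not None:
            # plain arrays are constants; Tensor masks keep their gradient
            # path (used for the differentiable reference-point bias)
            if not isinstance(attn_mask, Tensor):
                attn_mask = np.asarray(attn_mask, dtype=np.float64)
            scores = scores + attn_mask
        attn = self.dropout(softmax(scores, axis=-1))
        out = attn @ v  # (B*heads, Lq, head_dim)
        out = (out.reshape(batch, self.num_heads, lq, self.head_dim)
                  .transpose(2, 0, 1, 3)
                  .reshape(lq, batch, self.embed_dim))
        return self.out_proj(out)


class MLP(Module):
    """Simple feed-forward stack with ReLU between hidden layers."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int, num_layers: int):
        super().__init__()
        dims = [in_dim] + [hidden_dim] * (num_layers - 1) + [out_dim]
        self.layers = [Linear(a, b) for a, b in zip(dims[:-1], dims[1:])]

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x
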