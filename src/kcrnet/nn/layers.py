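"""Neural-network layers built on the autodiff engine.

Initialization follows the common uniform fan-in scheme
U(-1/sqrt(fan_in), 1/sqrt(fan_in)); every layer draws from the
``numpy.random.Generator`` it is given, so a model seed fully determines
all parameters.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, stack

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "Dropout",
    "Embedding",
    "LSTM",
    "BiLSTM",
    "MultiheadSelfAttention",
]


class Module:
    """Minimal container: tracks parameters, children and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in (self, *self.modules()):
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}

        def walk(mod: "Module", prefix: str):
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    out[f"{prefix}{k}"] = v
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    k = 1.0 / math.sqrt(fan_in)
    return Tensor(rng.uniform(-k, k, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _uniform(rng, (in_features, out_features), in_features)
        self.bias = _uniform(rng, (out_features,), in_features)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int,
        padding: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.weight = _uniform(rng, (out_channels, in_channels, kernel_size), fan_in)
        self.bias = _uniform(rng, (out_channels,), fan_in)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, self.stride, self.padding)


class Dropout(Module):
    """Inverted dropout: active only in training mode; identity in eval."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class Embedding(Module):
    """Trainable lookup table: integer IDs -> dense vectors."""

    def __init__(self, num_embeddings: int, embedding_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            rng.standard_normal((num_embeddings, embedding_dim)), requires_grad=True
        )

    def __call__(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids, dtype=np.intp)
        return self.weight[ids]


class LSTM(Module):
    """Single-direction LSTM over (B, T, F) input; returns (B, T, H).

    Gate layout in the packed weight matrices is (input, forget, output,
    cell-candidate), so the three sigmoid gates occupy one contiguous block.
    The input projection for all timesteps is computed as a single matmul;
    the recurrence only multiplies by the hidden-to-hidden weights.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        H = hidden_size
        self.hidden_size = H
        self.w_ih = _uniform(rng, (input_size, 4 * H), H)
        self.w_hh = _uniform(rng, (H, 4 * H), H)
        self.bias = _uniform(rng, (4 * H,), H)

    def __call__(self, x: Tensor) -> Tensor:
        from .autodiff import get_dtype

        B, T, _ = x.shape
        H = self.hidden_size
        xz = x @ self.w_ih + self.bias  # (B, T, 4H), one big matmul
        h = Tensor(np.zeros((B, H), dtype=get_dtype()))
        c = Tensor(np.zeros((B, H), dtype=get_dtype()))
        outs = []
        for t in range(T):
            z = xz[:, t, :] + h @ self.w_hh
            gates = z[:, 0 : 3 * H].sigmoid()
            i = gates[:, 0:H]
            f = gates[:, H : 2 * H]
            o = gates[:, 2 * H : 3 * H]
            g = z[:, 3 * H : 4 * H].tanh()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return stack(outs, axis=1)


class BiLSTM(Module):
    """Bidirectional LSTM; concatenates forward and backward states per position."""

    def __init__(self, input_size: int, hidden_per_direction: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(input_size, hidden_per_direction, rng)
        self.bwd = LSTM(input_size, hidden_per_direction, rng)

    def __call__(self, x: Tensor) -> Tensor:
        y_f = self.fwd(x)
        y_b = self.bwd(x.flip(1)).flip(1)
        return concat([y_f, y_b], axis=-1)


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention with h heads over (B, T, E).

    Plain attention block: no residual connection, positional encoding or
    layer normalization; all T positions are kept in the output.
    """

    def __init__(self, embed_dim: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        if embed_dim % num_heads:
            raise ValueError(
                f"embed_dim {embed_dim} not divisible by num_heads {num_heads}"
            )
        self.embed_dim = embed_dim
        self.num_heads = num_heads
        self.head_dim = embed_dim // num_heads
        self.in_proj = Linear(embed_dim, 3 * embed_dim, rng)
        self.out_proj = Linear(embed_dim, embed_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, E = x.shape
        h, d = self.num_heads, self.head_dim
        qkv = self.in_proj(x)  # (B, T, 3E)
        q = qkv[:, :, 0:E].reshape(B, T, h, d).transpose(0, 2, 1, 3)
        k = qkv[:, :, E : 2 * E].reshape(B, T, h, d).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * E : 3 * E].reshape(B, T, h, d).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(d))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, E)
        return self.out_proj(ctx)
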