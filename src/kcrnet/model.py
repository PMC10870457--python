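"""The Kcr-site network and its ablation/comparison variants.

The full architecture runs two branches over the same 29x21 one-hot input:

* a convolutional branch — three 1-D conv layers (kernel 5; strides 1, 2, 2;
  output channels 32, 32, 29; ReLU; dropout 0.30 each), positions
  29 -> 29 -> 15 -> 8, flattened to 29 x 8 = 232 features;
* a recurrent branch — a BiLSTM (64 hidden units per direction -> 128 per
  position, dropout 0.90) followed by 8-head self-attention over the 29
  positions (dropout 0.50), flattened to 29 x 128 = 3712 features.

The two flattened outputs are concatenated into a 3944-dimensional vector,
passed through a 3944 -> 128 linear layer with ReLU, and a 128 -> 2 output
layer with softmax; output index 1 is the positive (crotonylated) class.

Convolution padding is 2 on all three layers.  This is forced by the layer
arithmetic: with kernel 5 and strides (1, 2, 2) the published position
counts 29 -> 29 -> 15 -> 8 and the fused width 3944 = 232 + 3712 hold only
with padding 2 everywhere (zero padding would give 25 -> 11 -> 4 and 3828).
The attention block keeps all 29 positions and adds no residual connection,
positional encoding or layer normalization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .alphabet import ALPHABET, WINDOW_LENGTH
from .nn.autodiff import Tensor, concat

__all__ = [
    "ModelConfig",
    "ShapeTrace",
    "shape_trace",
    "build_model",
    "build_variant",
    "export_activations",
    "KcrNet",
    "save_checkpoint",
    "load_checkpoint",
    "VARIANTS",
    "input_channels",
]

VARIANTS = (
    "full",
    "no_linear",
    "no_cnn",
    "no_mhsa",
    "cnn_only",
    "lstm",
    "bilstm",
    "cnn_we",
    "cnn_generic",
)

#: feature width per position for each matrix encoding usable by the networks
_SCHEME_CHANNELS = {"be": 21, "blosum62": 21, "aaindex": 29}


def input_channels(config: "ModelConfig") -> int:
    if config.variant == "cnn_we" or config.input_scheme == "we":
        return config.embed_dim
    try:
        return _SCHEME_CHANNELS[config.input_scheme]
    except KeyError:
        raise ValueError(
            f"encoding {config.input_scheme!r} is not a per-position matrix encoding; "
            f"networks accept one of {sorted(_SCHEME_CHANNELS)} or 'we'"
        ) from None


@dataclass
class ModelConfig:
    """Architecture description; defaults are the published full model."""

    conv_channels: tuple[int, int, int] = (32, 32, 29)
    kernel_size: int = 5
    conv_strides: tuple[int, int, int] = (1, 2, 2)
    conv_padding: tuple[int, int, int] = (2, 2, 2)
    conv_dropout: float = 0.30
    bilstm_out: int = 128  # total across both directions
    attn_heads: int = 8
    bilstm_dropout: float = 0.90
    attn_dropout: float = 0.50
    linear_in: int = 3944
    linear_out: int = 128
    n_classes: int = 2
    variant: str = "full"
    input_scheme: str = "be"
    embed_dim: int = 10

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.bilstm_out % 2:
            raise ValueError("bilstm_out must be even (split across two directions)")
        if self.bilstm_out % self.attn_heads:
            raise ValueError(
                f"attention input size {self.bilstm_out} not divisible by "
                f"{self.attn_heads} heads"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("conv_channels", "conv_strides", "conv_padding"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ShapeTrace:
    """Ordered (layer name, output shape) pairs, batch axis omitted."""

    layers: list[tuple[str, tuple[int, ...]]]

    def __getitem__(self, name: str) -> tuple[int, ...]:
        for n, s in self.layers:
            if n == name:
                return s
        raise KeyError(name)

    @property
    def flatten_size(self) -> int:
        return self["flatten"][0]


def _conv_len(l_in: int, kernel: int, stride: int, padding: int) -> int:
    return (l_in + 2 * padding - kernel) // stride + 1


def shape_trace(config: ModelConfig) -> ShapeTrace:
    """Compute every layer's output shape without building the network.

    Raises a validation error if ``linear_in`` disagrees with the computed
    flatten width for the variant.
    """
    ch = input_channels(config)
    layers: list[tuple[str, tuple[int, ...]]] = [("input", (WINDOW_LENGTH, ch))]
    variant = config.variant

    conv_flat = 0
    if variant in ("full", "no_mhsa", "cnn_only", "cnn_we", "cnn_generic"):
        L = WINDOW_LENGTH
        for i, (c_out, s, p) in enumerate(
            zip(config.conv_channels, config.conv_strides, config.conv_padding), start=1
        ):
            L = _conv_len(L, config.kernel_size, s, p)
            if L < 1:
                raise ValueError(f"conv{i} output length collapsed to {L}")
            layers.append((f"conv{i}", (c_out, L)))
        conv_flat = config.conv_channels[-1] * L

    rec_flat = 0
    if variant in ("full", "no_linear", "no_cnn", "no_mhsa", "lstm", "bilstm"):
        if variant == "no_linear":
            # same two branches as the full model
            L = WINDOW_LENGTH
            for i, (c_out, s, p) in enumerate(
                zip(config.conv_channels, config.conv_strides, config.conv_padding), start=1
            ):
                L = _conv_len(L, config.kernel_size, s, p)
                layers.append((f"conv{i}", (c_out, L)))
            conv_flat = config.conv_channels[-1] * L
        if variant == "lstm":
            layers.append(("lstm", (WINDOW_LENGTH, config.bilstm_out)))
        else:
            layers.append(("bilstm", (WINDOW_LENGTH, config.bilstm_out)))
        if variant in ("full", "no_linear", "no_cnn"):
            layers.append(("mhsa", (WINDOW_LENGTH, config.bilstm_out)))
        rec_flat = WINDOW_LENGTH * config.bilstm_out

    flat = conv_flat + rec_flat
    layers.append(("flatten", (flat,)))
    if variant != "no_linear":
        if config.linear_in != flat:
            raise ValueError(
                f"linear_in={config.linear_in} but the computed flatten size is {flat}"
            )
        layers.append(("linear", (config.linear_out,)))
    layers.append(("output", (config.n_classes,)))
    return ShapeTrace(layers)


class KcrNet(nn.Module):
    """Configurable network covering the full model and all variants."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = seed
        self.trace = shape_trace(config)  # validates the shape contract
        rng = np.random.default_rng(seed)
        v = config.variant
        ch = input_channels(config)
        self.has_conv = v in ("full", "no_linear", "no_mhsa", "cnn_only", "cnn_we", "cnn_generic")
        self.has_recurrent = v in ("full", "no_linear", "no_cnn", "no_mhsa", "lstm", "bilstm")
        self.has_attention = v in ("full", "no_linear", "no_cnn")
        self.has_linear = v != "no_linear"
        self.uses_embedding = v == "cnn_we" or config.input_scheme == "we"

        if self.uses_embedding:
            self.embedding = nn.Embedding(len(ALPHABET), config.embed_dim, rng)
        if self.has_conv:
            convs = []
            c_in = ch
            for c_out, s, p in zip(config.conv_channels, config.conv_strides, config.conv_padding):
                convs.append(nn.Conv1d(c_in, c_out, config.kernel_size, s, p, rng))
                c_in = c_out
            self.convs = convs
            self.conv_drop = nn.Dropout(config.conv_dropout, rng)
        if self.has_recurrent:
            if v == "lstm":
                self.rnn = nn.LSTM(ch, config.bilstm_out, rng)
            else:
                self.rnn = nn.BiLSTM(ch, config.bilstm_out // 2, rng)
            self.rnn_drop = nn.Dropout(config.bilstm_dropout, rng)
        if self.has_attention:
            self.attn = nn.MultiheadSelfAttention(config.bilstm_out, config.attn_heads, rng)
            self.attn_drop = nn.Dropout(config.attn_dropout, rng)
        flat = self.trace.flatten_size
        if self.has_linear:
            self.linear = nn.Linear(flat, config.linear_out, rng)
            self.output = nn.Linear(config.linear_out, config.n_classes, rng)
        else:
            self.output = nn.Linear(flat, config.n_classes, rng)

    # ------------------------------------------------------------------ passes
    def _branches(self, x: np.ndarray) -> dict[str, Tensor]:
        """Forward pass returning the named intermediate tensors."""
        if self.uses_embedding:
            t = self.embedding(np.asarray(x, dtype=np.intp))  # (B, 29, E)
        else:
            t = Tensor(x)
        B = t.shape[0]
        parts: list[Tensor] = []
        acts: dict[str, Tensor] = {"input": t}
        if self.has_conv:
            h = t.transpose(0, 2, 1)  # (B, C, L)
            for conv in self.convs:
                h = self.conv_drop(conv(h).relu())
            parts.append(h.reshape(B, -1))
        if self.has_recurrent:
            r = self.rnn_drop(self.rnn(t))
            if self.has_attention:
                r = self.attn_drop(self.attn(r))
            parts.append(r.reshape(B, -1))
        flat = parts[0] if len(parts) == 1 else concat(parts, axis=1)
        acts["flatten"] = flat
        if self.has_linear:
            lin = self.linear(flat).relu()
            acts["linear"] = lin
        else:
            lin = flat
        acts["probs"] = self.output(lin).softmax(axis=1)
        return acts

    def forward(self, x: np.ndarray) -> Tensor:
        """Class probabilities (B, 2); column 1 is the positive class."""
        return self._branches(x)["probs"]

    __call__ = forward

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Positive-class probability per sample, in evaluation mode."""
        was_training = self.training
        self.eval()
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i : i + batch_size]).data[:, 1].copy())
        if was_training:
            self.train()
        return np.concatenate(out) if out else np.empty(0)


def build_model(config: ModelConfig, seed: int = 0) -> KcrNet:
    """Construct the network for `config` with all parameters seeded."""
    return KcrNet(config, seed=seed)


def build_variant(config: ModelConfig, seed: int = 0) -> KcrNet:
    """Construct an ablation/comparison variant (config.variant selects it).

    The shape contract (``linear_in``) is recomputed for the variant, so a
    config written for the full model can be rebuilt for any variant without
    restating the flatten width.
    """
    trial = ModelConfig(**{**config.to_dict()})
    try:
        shape_trace(trial)
    except ValueError:
        d = trial.to_dict()
        d["linear_in"] = _flatten_for(trial)
        trial = ModelConfig.from_dict(d)
    return KcrNet(trial, seed=seed)


def _flatten_for(config: ModelConfig) -> int:
    d = config.to_dict()
    d["linear_in"] = 1  # placeholder; recompute below
    probe = ModelConfig.from_dict(d)
    ch = input_channels(probe)
    L = WINDOW_LENGTH
    conv_flat = 0
    if probe.variant in ("full", "no_linear", "no_mhsa", "cnn_only", "cnn_we", "cnn_generic"):
        for s, p in zip(probe.conv_strides, probe.conv_padding):
            L = _conv_len(L, probe.kernel_size, s, p)
        conv_flat = probe.conv_channels[-1] * L
    rec_flat = (
        WINDOW_LENGTH * probe.bilstm_out
        if probe.variant in ("full", "no_linear", "no_cnn", "no_mhsa", "lstm", "bilstm")
        else 0
    )
    return conv_flat + rec_flat


def export_activations(model: KcrNet, x: np.ndarray, layer: str, batch_size: int = 512) -> np.ndarray:
    """Per-sample activations at `layer` in {input, flatten, linear}.

    Shapes for the default model: input -> (n, 609), flatten -> (n, 3944),
    linear -> (n, 128).  Intended for external embedding/visualization.
    """
    if layer not in ("input", "flatten", "linear"):
        raise ValueError(f"unknown layer {layer!r}; choose input, flatten or linear")
    if layer == "linear" and not model.has_linear:
        raise ValueError("this variant has no linear layer")
    was_training = model.training
    model.eval()
    rows = []
    for i in range(0, len(x), batch_size):
        acts = model._branches(x[i : i + batch_size])
        t = acts[layer]
        rows.append(t.data.reshape(t.shape[0], -1).copy())
    if was_training:
        model.train()
    return np.concatenate(rows) if rows else np.empty((0, 0))


def save_checkpoint(model: KcrNet, path: str | Path) -> None:
    """Single-file checkpoint: parameters plus config, alphabet and seed."""
    meta = {
        "config": model.config.to_dict(),
        "alphabet": ALPHABET,
        "seed": model.seed,
        "format": 1,
    }
    arrays = {f"param/{k}": v.data for k, v in model.named_parameters().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> KcrNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("alphabet") != ALPHABET:
            raise ValueError("checkpoint alphabet does not match this package's alphabet")
        model = KcrNet(ModelConfig.from_dict(meta["config"]), seed=meta["seed"])
        params = model.named_parameters()
        for key in z.files:
            if key.startswith("param/"):
                name = key[len("param/") :]
                params[name].data = z[key].astype(params[name].data.dtype)
    return model
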