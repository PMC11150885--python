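"""Architecture families for base-wise coverage prediction.

Three families are built from the same parts:

* ``unet`` — a stack of strided convolutions followed by a mirrored stack of
  transposed convolutions, giving base-wise output;
* ``hybrid`` — the same with a block of unidirectional LSTM layers at the
  downsampled bottleneck;
* ``bihybrid`` — the hybrid with bidirectional LSTM layers.

Every (transposed) convolution is followed by ReLU, then batch normalisation
when enabled; dropout sits after each recurrent layer except the last. As in
the standard U-Net design, additive skip connections link each encoder level
to the decoder level of matching resolution (configurable); they carry
positional detail past the bottleneck and shortcut gradients to the early
motif-detecting filters. The network output is in log space: predicted
coverage rates are its exponential, which pairs with the Poisson likelihood
and keeps rates strictly positive. A 1×1 projection maps the last feature
maps to the requested number of output datasets; it is a linear head, not
counted in the convolutional layer census.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from chromacast.errors import ConfigError, DataError
from chromacast.genome import EncodedChunk
from chromacast.nn.layers import (
    BatchNorm1d,
    BiLSTM,
    Conv1d,
    ConvTranspose1d,
    Dropout,
    Layer,
    LSTM,
    ReLU,
    conv_padding,
)

CHECKPOINT_SCHEMA = "chromacast-checkpoint-1"

FAMILIES = ("unet", "hybrid", "bihybrid")


@dataclass
class ModelConfig:
    """Architecture family and hyperparameters of one model."""

    family: str = "bihybrid"
    n_conv: int = 3
    filters: list[int] = field(default_factory=lambda: [64, 128, 256])
    kernel: int = 9
    step: int = 2
    n_lstm: int = 2
    lstm_units: int = 64
    batch_norm: bool = True
    dropout_p: float = 0.3
    n_outputs: int = 1
    subseq_len: int = 21_384
    #: additive encoder→decoder skip connections at matching resolutions
    skip_connections: bool = True

    @property
    def n_tconv(self) -> int:
        # the transposed stack always mirrors the convolutional stack
        return self.n_conv

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        if len(self.filters) != self.n_conv:
            raise ConfigError(
                f"filters has {len(self.filters)} entries for {self.n_conv} conv layers"
            )
        if self.subseq_len % (self.step ** self.n_conv):
            raise ConfigError(
                f"subseq_len {self.subseq_len} is not divisible by "
                f"step^n_conv = {self.step ** self.n_conv}"
            )
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigError(f"dropout_p must be in [0, 1), got {self.dropout_p}")
        if self.family != "unet" and self.n_lstm < 1:
            raise ConfigError("hybrid/bihybrid need at least one recurrent layer")
        conv_padding(self.kernel, self.step)  # raises if no exact geometry exists


def compute_conv_geometry(L: int, kernel: int, step: int) -> dict[str, int]:
    """Padding parameters for an exact ``L → L/step → L`` round trip.

    Returns left/right padding (total ``kernel − step``) and the downsampled
    length. Raises :class:`ConfigError` when ``L`` is not divisible by
    ``step`` or no integer padding exists (``kernel < step``).
    """
    if step < 1:
        raise ConfigError(f"step must be ≥ 1, got {step}")
    if L % step:
        raise ConfigError(f"length {L} is not divisible by step {step}")
    left, right = conv_padding(kernel, step)
    return {"pad_left": left, "pad_right": right, "out_len": L // step}


class SequenceModel:
    """An assembled encoder(-recurrent)-decoder model with explicit backprop."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        cfg.validate()
        self.cfg = cfg
        n = cfg.n_conv
        conv_blocks: list[list[Layer]] = []
        c_in = 4
        for c_out in cfg.filters:
            block: list[Layer] = [Conv1d(c_in, c_out, cfg.kernel, cfg.step, rng), ReLU()]
            if cfg.batch_norm:
                block.append(BatchNorm1d(c_out))
            conv_blocks.append(block)
            c_in = c_out
        rec_stack: list[Layer] = []
        if cfg.family in ("hybrid", "bihybrid"):
            bidirectional = cfg.family == "bihybrid"
            d_in = c_in
            for i in range(cfg.n_lstm):
                if bidirectional:
                    rec_stack.append(BiLSTM(d_in, cfg.lstm_units, rng))
                    d_in = 2 * cfg.lstm_units
                else:
                    rec_stack.append(LSTM(d_in, cfg.lstm_units, rng))
                    d_in = cfg.lstm_units
                if cfg.dropout_p > 0 and i < cfg.n_lstm - 1:
                    rec_stack.append(Dropout(cfg.dropout_p))
            c_in = d_in
        # decoder block j upsamples to the resolution of encoder level
        # n-2-j; its channel count matches that level so skips can be added
        tconv_blocks: list[list[Layer]] = []
        decoder_channels = [cfg.filters[n - 2 - j] if j < n - 1 else cfg.filters[0]
                            for j in range(n)]
        for c_out in decoder_channels:
            block = [ConvTranspose1d(c_in, c_out, cfg.kernel, cfg.step, rng), ReLU()]
            if cfg.batch_norm:
                block.append(BatchNorm1d(c_out))
            tconv_blocks.append(block)
            c_in = c_out
        self.conv_blocks = conv_blocks
        self.rec_stack = rec_stack
        self.tconv_blocks = tconv_blocks
        self.head = Conv1d(c_in, cfg.n_outputs, 1, 1, rng)

    @property
    def conv_stack(self) -> list[Layer]:
        return [layer for block in self.conv_blocks for layer in block]

    @property
    def tconv_stack(self) -> list[Layer]:
        return [layer for block in self.tconv_blocks for layer in block]

    # -- bookkeeping ---------------------------------------------------------

    def _all_layers(self) -> list[tuple[str, Layer]]:
        named: list[tuple[str, Layer]] = []
        for prefix, stack in (
            ("conv", self.conv_stack),
            ("rec", self.rec_stack),
            ("tconv", self.tconv_stack),
        ):
            for i, layer in enumerate(stack):
                if isinstance(layer, BiLSTM):
                    named.append((f"{prefix}{i}.fwd", layer.fwd))
                    named.append((f"{prefix}{i}.bwd", layer.bwd))
                else:
                    named.append((f"{prefix}{i}", layer))
        named.append(("head", self.head))
        return named

    def named_params(self) -> Iterator[tuple[str, np.ndarray, dict, str]]:
        """Yield (qualified name, parameter array, grads dict, key)."""
        for lname, layer in self._all_layers():
            for pname, arr in layer.params.items():
                yield f"{lname}.{pname}", arr, layer.grads, pname

    def layer_census(self) -> dict[str, int]:
        """Count layers by kind, the way architecture variants are described."""
        census = {"conv": 0, "tconv": 0, "lstm": 0, "bilstm": 0,
                  "batch_norm": 0, "dropout": 0}
        for stack in (self.conv_stack, self.rec_stack, self.tconv_stack):
            for layer in stack:
                if isinstance(layer, Conv1d):
                    census["conv"] += 1
                elif isinstance(layer, ConvTranspose1d):
                    census["tconv"] += 1
                elif isinstance(layer, BiLSTM):
                    census["bilstm"] += 1
                elif isinstance(layer, LSTM):
                    census["lstm"] += 1
                elif isinstance(layer, BatchNorm1d):
                    census["batch_norm"] += 1
                elif isinstance(layer, Dropout):
                    census["dropout"] += 1
        return census

    def n_params(self) -> int:
        return sum(arr.size for _, arr, _, _ in self.named_params())

    # -- computation ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Map a ``(B, L, 4)`` encoded batch to ``(B, L, n_outputs)`` log rates."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[2] != 4:
            raise DataError(f"expected input of shape (B, L, 4), got {x.shape}")
        if x.shape[1] != self.cfg.subseq_len:
            raise DataError(
                f"input length {x.shape[1]} != configured subseq_len {self.cfg.subseq_len}"
            )
        n = self.cfg.n_conv
        use_skip = self.cfg.skip_connections
        h = x.transpose(0, 2, 1)
        enc_acts: list[np.ndarray] = []
        for block in self.conv_blocks:
            for layer in block:
                h = layer.forward(h, train, rng)
            enc_acts.append(h)
        if self.rec_stack:
            ht = np.ascontiguousarray(h.transpose(0, 2, 1))
            for layer in self.rec_stack:
                ht = layer.forward(ht, train, rng)
            h = ht.transpose(0, 2, 1)
        for j, block in enumerate(self.tconv_blocks):
            for layer in block:
                h = layer.forward(h, train, rng)
            k = n - 2 - j
            if use_skip and k >= 0:
                h = h + enc_acts[k]
        h = self.head.forward(h, train, rng)
        return h.transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> None:
        """Backpropagate ``(B, L, n_outputs)`` loss gradients into layer grads."""
        n = self.cfg.n_conv
        use_skip = self.cfg.skip_connections
        skip_grads: dict[int, np.ndarray] = {}
        d = dout.transpose(0, 2, 1)
        d = self.head.backward(d)
        for j in range(len(self.tconv_blocks) - 1, -1, -1):
            k = n - 2 - j
            if use_skip and k >= 0:
                # the addition node passes the same gradient to both branches
                skip_grads[k] = d
            for layer in reversed(self.tconv_blocks[j]):
                d = layer.backward(d)
        if self.rec_stack:
            dt = np.ascontiguousarray(d.transpose(0, 2, 1))
            for layer in reversed(self.rec_stack):
                dt = layer.backward(dt)
            d = dt.transpose(0, 2, 1)
        for i in range(len(self.conv_blocks) - 1, -1, -1):
            for layer in reversed(self.conv_blocks[i]):
                d = layer.backward(d)
            if i - 1 in skip_grads:
                d = d + skip_grads[i - 1]


def build_model(cfg: ModelConfig, seed: int | np.random.Generator = 0) -> SequenceModel:
    """Build one of the architecture families from its configuration."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return SequenceModel(cfg, rng)


# ---------------------------------------------------------------------------
# Prediction over chunk pairs and stitching back to genome coordinates


def predict_rates(
    model: SequenceModel,
    plus_chunks: list[EncodedChunk],
    minus_chunks: list[EncodedChunk],
    batch_size: int = 8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predict coverage rates for paired plus/minus chunks of one genome.

    Minus-strand outputs are re-reversed into plus coordinates before the two
    strands are averaged. Returns ``(rates_plus, rates_minus, rates_avg)``,
    each of shape ``(n_chunks, L, n_outputs)`` in plus coordinates.
    """
    if len(plus_chunks) != len(minus_chunks):
        raise DataError("plus/minus chunk lists differ in length")
    for p, m in zip(plus_chunks, minus_chunks):
        if (p.seq_id, p.start, p.end) != (m.seq_id, m.start, m.end) or \
                p.strand != "+" or m.strand != "-":
            raise DataError(
                f"unpaired strands for window {p.seq_id}:{p.start}-{p.end}"
            )
    Xp = np.stack([c.matrix for c in plus_chunks])
    Xm = np.stack([c.matrix for c in minus_chunks])
    log_p = _batched_forward(model, Xp, batch_size)
    log_m = _batched_forward(model, Xm, batch_size)
    rates_p = np.exp(log_p)
    rates_m = np.exp(log_m)[:, ::-1, :]  # back to plus coordinates
    return rates_p, rates_m, 0.5 * (rates_p + rates_m)


def _batched_forward(model: SequenceModel, X: np.ndarray, batch_size: int) -> np.ndarray:
    outs = [model.forward(X[i: i + batch_size]) for i in range(0, len(X), batch_size)]
    return np.concatenate(outs, axis=0)


def stitch_chunks(
    per_chunk: np.ndarray, chunks: list[EncodedChunk], seq_length: int
) -> np.ndarray:
    """Concatenate per-chunk arrays (plus coordinates) into one genome track,
    dropping padded tail positions."""
    n_out = per_chunk.shape[2]
    track = np.zeros((seq_length, n_out))
    for arr, chunk in zip(per_chunk, chunks):
        track[chunk.start: chunk.end] = arr[: chunk.end - chunk.start]
    return track


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(model: SequenceModel, path: str | Path,
                    extra: dict | None = None) -> None:
    """Persist weights + full model configuration + schema version (.npz)."""
    arrays = {name: arr for name, arr, _, _ in model.named_params()}
    for lname, layer in model._all_layers():
        if isinstance(layer, BatchNorm1d):
            arrays[f"{lname}.running_mean"] = layer.running_mean
            arrays[f"{lname}.running_var"] = layer.running_var
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": asdict(model.cfg),
        "extra": extra or {},
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[SequenceModel, dict]:
    """Rebuild a model from a checkpoint; returns (model, extra metadata)."""
    with np.load(path) as data:
        try:
            meta = json.loads(bytes(data["__meta__"]).decode())
        except KeyError as exc:
            raise DataError(f"{path}: not a model checkpoint") from exc
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise DataError(
                f"{path}: checkpoint schema {meta.get('schema')!r} does not match "
                f"{CHECKPOINT_SCHEMA!r}"
            )
        cfg = ModelConfig(**meta["config"])
        model = build_model(cfg, seed=0)
        for name, arr, _, key in model.named_params():
            arr[...] = data[name]
        for lname, layer in model._all_layers():
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = data[f"{lname}.running_mean"].copy()
                layer.running_var = data[f"{lname}.running_var"].copy()
    return model, meta["extra"]
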