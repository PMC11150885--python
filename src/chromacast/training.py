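"""Masked Poisson-loss training with Adam, model selection on validation
Pearson, and dataset split utilities.

The loss is the Poisson negative log likelihood for a network that outputs
log rates x against observed counts y,

    loss = (1/n) Σ_i  exp(x_i) − y_i · x_i,

where the sum and n run over unmasked positions only: padded bases (and any
position excluded by the caller's mask) contribute nothing to loss or
gradient. Coverage targets are deliberately not depth-normalised, and no
mean-subtraction/ReLU normalisation is applied to them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from chromacast.errors import ConfigError, DataError
from chromacast.evaluation import pearson_r
from chromacast.genome import Container
from chromacast.nn import Adam, SequenceModel, save_checkpoint

logger = logging.getLogger(__name__)


def poisson_loss(x: np.ndarray, y: np.ndarray,
                 mask: np.ndarray | None = None) -> float:
    """Masked Poisson NLL of log-space predictions ``x`` against counts ``y``."""
    loss, _ = poisson_loss_grad(x, y, mask, need_grad=False)
    return loss


def poisson_loss_grad(
    x: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None,
    need_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Loss and its gradient w.r.t. ``x`` (zero at masked positions)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise DataError(f"prediction/target shape mismatch: {x.shape} vs {y.shape}")
    if mask is None:
        m = np.ones(x.shape, dtype=bool)
    else:
        m = np.asarray(mask, dtype=bool)
        if m.shape != x.shape:
            raise DataError(f"mask shape {m.shape} does not match {x.shape}")
    n = int(m.sum())
    if n == 0:
        raise DataError("all positions are masked; loss is undefined")
    ex = np.exp(np.where(m, x, 0.0))
    terms = np.where(m, ex - y * x, 0.0)
    loss = float(terms.sum() / n)
    grad = None
    if need_grad:
        grad = np.where(m, ex - y, 0.0) / n
    return loss, grad


@dataclass
class TrainConfig:
    """Optimisation hyperparameters and bookkeeping for one training run."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 10
    patience: int | None = None
    seed: int = 0
    max_batches_per_epoch: int | None = None
    checkpoint_dir: str | Path | None = None
    #: per-dataset selection: validation Pearson is computed per output and
    #: averaged ("mean") or taken on concatenated outputs ("pooled")
    selection: str = "mean"
    #: total optimiser steps for window-sampled training (:func:`train_sampled`)
    steps: int = 800
    #: how often (in steps) sampled training evaluates validation Pearson
    eval_every: int = 50
    #: stop sampled training early once validation Pearson reaches this value
    stop_at_pearson: float | None = None

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("batch_size and epochs must be ≥ 1")
        if self.selection not in ("mean", "pooled"):
            raise ConfigError(f"unknown selection mode {self.selection!r}")


@dataclass
class TrainState:
    """Outcome of a training run; ``best_val_pearson`` is non-decreasing."""

    epoch: int = 0
    best_val_pearson: float = -np.inf
    best_checkpoint: Path | None = None
    seed: int = 0
    history: list[dict] = field(default_factory=list)


def validation_pearson(model: SequenceModel, data: Mapping[str, np.ndarray],
                       batch_size: int = 16, selection: str = "mean") -> float:
    """Pearson r between predicted rates and targets over unmasked positions."""
    X, Y, mask = data["X"], data["Y"], data["mask"]
    rates = []
    for i in range(0, len(X), batch_size):
        rates.append(np.exp(model.forward(X[i: i + batch_size])))
    R = np.concatenate(rates, axis=0)
    if selection == "pooled":
        m3 = np.broadcast_to(mask[:, :, None], Y.shape)
        return pearson_r(R[m3], Y[m3])
    per_output = [
        pearson_r(R[:, :, k][mask], Y[:, :, k][mask]) for k in range(Y.shape[2])
    ]
    return float(np.mean(per_output))


def train(
    model: SequenceModel,
    train_data: Mapping[str, np.ndarray],
    val_data: Mapping[str, np.ndarray],
    cfg: TrainConfig,
) -> TrainState:
    """Optimise the masked Poisson loss with Adam; keep the checkpoint with the
    highest validation Pearson.

    ``train_data``/``val_data`` map ``X`` (N, L, 4), ``Y`` (N, L, n_outputs)
    and ``mask`` (N, L; True where a position counts). Deterministic given
    ``cfg.seed`` and single-threaded execution.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model, lr=cfg.learning_rate)
    state = TrainState(seed=cfg.seed)
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    X, Y, mask = train_data["X"], train_data["Y"], train_data["mask"]
    n = len(X)
    since_best = 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        batch_starts = range(0, n, cfg.batch_size)
        if cfg.max_batches_per_epoch is not None:
            batch_starts = list(batch_starts)[: cfg.max_batches_per_epoch]
        for b, start in enumerate(batch_starts):
            idx = order[start: start + cfg.batch_size]
            xb = X[idx]
            yb = Y[idx][:, :, None] if Y.ndim == 2 else Y[idx]
            mb = np.broadcast_to(mask[idx][:, :, None], yb.shape)
            log_rates = model.forward(xb, train=True, rng=rng)
            loss, grad = poisson_loss_grad(log_rates, yb, mb)
            if not np.isfinite(loss):
                raise DataError(
                    f"non-finite loss {loss} at epoch {epoch}, batch {b} "
                    f"(chunk indices {idx.tolist()})"
                )
            model.backward(grad)
            optimizer.step()
            losses.append(loss)
        val_r = validation_pearson(model, val_data, cfg.batch_size, cfg.selection)
        state.epoch = epoch
        record = {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_pearson": val_r}
        state.history.append(record)
        logger.info("epoch %d  train_loss %.5f  val_pearson %.4f",
                    epoch, record["train_loss"], val_r)
        if val_r > state.best_val_pearson:
            state.best_val_pearson = val_r
            since_best = 0
            if ckpt_dir:
                path = ckpt_dir / "best.npz"
                save_checkpoint(model, path, extra={"epoch": epoch, "val_pearson": val_r,
                                                    "seed": cfg.seed})
                state.best_checkpoint = path
        else:
            since_best += 1
            if cfg.patience is not None and since_best > cfg.patience:
                logger.info("early stop at epoch %d (patience %d)", epoch, cfg.patience)
                break
    return state


def train_sampled(
    model: SequenceModel,
    sequences: Mapping[str, Mapping[str, np.ndarray]],
    train_ids: Sequence[str],
    val_data: Mapping[str, np.ndarray],
    cfg: TrainConfig,
    rc_augment: bool = True,
) -> TrainState:
    """Window-resampling training: every batch draws fresh random windows.

    Instead of iterating a fixed chunk set, each batch samples ``batch_size``
    random ``subseq_len``-bp windows from the training sequences, optionally
    reverse-complementing half of them (targets reversed alongside, since
    coverage applies to both strands). Re-drawing window boundaries every step
    removes the incentive to memorise fixed tiles — the only features stable
    under shifting are genuine sequence determinants — which makes motif
    learning dramatically more sample-efficient on small genomes.

    ``sequences`` maps seq_id to ``{"X": (length, 4), "Y": (length,
    n_outputs)}`` full-sequence arrays (see
    :func:`sequence_arrays_from_container`). Validation uses the fixed tiles
    in ``val_data`` exactly as :func:`train`.
    """
    cfg.validate()
    L = model.cfg.subseq_len
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model, lr=cfg.learning_rate)
    state = TrainState(seed=cfg.seed)
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    ids = list(train_ids)
    for seq_id in ids:
        if len(sequences[seq_id]["X"]) < L:
            raise DataError(f"sequence {seq_id!r} is shorter than one window")
    n_out = model.cfg.n_outputs
    losses: list[float] = []
    for step in range(1, cfg.steps + 1):
        xb = np.empty((cfg.batch_size, L, 4))
        yb = np.empty((cfg.batch_size, L, n_out))
        for b in range(cfg.batch_size):
            seq_id = ids[rng.integers(len(ids))]
            seq = sequences[seq_id]
            start = int(rng.integers(0, len(seq["X"]) - L + 1))
            xw = seq["X"][start: start + L]
            yw = seq["Y"][start: start + L]
            if rc_augment and rng.random() < 0.5:
                xw = xw[::-1, ::-1]
                yw = yw[::-1]
            xb[b] = xw
            yb[b] = yw
        log_rates = model.forward(xb, train=True, rng=rng)
        loss, grad = poisson_loss_grad(log_rates, yb)
        if not np.isfinite(loss):
            raise DataError(f"non-finite loss {loss} at step {step}")
        model.backward(grad)
        optimizer.step()
        losses.append(loss)
        if step % cfg.eval_every == 0 or step == cfg.steps:
            val_r = validation_pearson(model, val_data, cfg.batch_size, cfg.selection)
            state.epoch = step
            record = {"step": step, "train_loss": float(np.mean(losses)),
                      "val_pearson": val_r}
            state.history.append(record)
            losses.clear()
            logger.info("step %d  train_loss %.5f  val_pearson %.4f",
                        step, record["train_loss"], val_r)
            if val_r > state.best_val_pearson:
                state.best_val_pearson = val_r
                if ckpt_dir:
                    path = ckpt_dir / "best.npz"
                    save_checkpoint(model, path,
                                    extra={"step": step, "val_pearson": val_r,
                                           "seed": cfg.seed})
                    state.best_checkpoint = path
            if cfg.stop_at_pearson is not None and val_r >= cfg.stop_at_pearson:
                logger.info("stopping at step %d: val Pearson %.4f reached target",
                            step, val_r)
                break
    return state


def sequence_arrays_from_container(
    container: Container, datasets: Sequence[str]
) -> dict[str, dict[str, np.ndarray]]:
    """Stitch plus-strand chunks back into full per-sequence X/Y arrays.

    Used to feed :func:`train_sampled`, which needs contiguous sequences to
    draw random windows from.
    """
    missing = [d for d in datasets if d not in container.tracks]
    if missing:
        raise DataError(f"container has no coverage for dataset(s) {missing}")
    out: dict[str, dict[str, np.ndarray]] = {}
    for seq_id, length in container.seq_lengths.items():
        X = np.zeros((length, 4))
        Y = np.zeros((length, len(datasets)))
        for i, chunk in enumerate(container.chunks):
            if chunk.seq_id != seq_id or chunk.strand != "+":
                continue
            n_real = chunk.end - chunk.start
            X[chunk.start: chunk.end] = chunk.matrix[:n_real]
            for k, d in enumerate(datasets):
                Y[chunk.start: chunk.end, k] = container.tracks[d][i][:n_real]
        out[seq_id] = {"X": X, "Y": Y}
    return out


# ---------------------------------------------------------------------------
# Split utilities


def intra_species_split(
    source: Container | Mapping[str, int], fraction: float, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Assign whole sequence IDs to training or validation.

    Each ID goes entirely to one side; after seeded shuffling, IDs are moved
    to validation while that brings the realised share of bases closer to
    ``fraction``. A single-sequence genome yields an empty validation set with
    a warning.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigError(f"fraction must be in (0, 1), got {fraction}")
    lengths = dict(source.seq_lengths) if isinstance(source, Container) else dict(source)
    if not lengths:
        raise DataError("no sequences to split")
    ids = sorted(lengths)
    if len(ids) == 1:
        warnings.warn(
            f"genome has a single sequence {ids[0]!r}; validation set is empty",
            stacklevel=2,
        )
        return ids, []
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    total = sum(lengths.values())
    val: list[str] = []
    share = 0.0
    for seq_id in ids:
        candidate = share + lengths[seq_id] / total
        if abs(candidate - fraction) < abs(share - fraction):
            val.append(seq_id)
            share = candidate
    val_set = set(val)
    train_ids = [s for s in ids if s not in val_set]
    return sorted(train_ids), sorted(val)


def loocv_plan(species_list: Sequence[str]) -> list[tuple[list[str], str]]:
    """Leave-one-out cross-validation folds: one fold per species, whose
    training set excludes exactly the held-out species."""
    species = list(species_list)
    if len(species) < 2:
        raise ConfigError("leave-one-out needs at least 2 species")
    if len(set(species)) != len(species):
        dupes = sorted({s for s in species if species.count(s) > 1})
        raise ConfigError(f"duplicate species names: {dupes}")
    return [([s for s in species if s != held_out], held_out) for held_out in species]


# ---------------------------------------------------------------------------
# Container → training arrays


def load_training_arrays(
    container: Container,
    datasets: Sequence[str],
    seq_ids: Sequence[str] | None = None,
    drop_gaps: bool = True,
    drop_blacklisted: bool = True,
) -> dict[str, np.ndarray]:
    """Assemble X/Y/mask arrays from a container for the given dataset kinds.

    Gap chunks and blacklisted chunks are dropped (the latter per the
    container's blacklist flags); the mask marks real (unpadded) bases.
    """
    missing = [d for d in datasets if d not in container.tracks]
    if missing:
        raise DataError(f"container has no coverage for dataset(s) {missing}")
    keep = []
    wanted = set(seq_ids) if seq_ids is not None else None
    for i, chunk in enumerate(container.chunks):
        if wanted is not None and chunk.seq_id not in wanted:
            continue
        if drop_gaps and chunk.is_gap:
            continue
        if drop_blacklisted and container.blacklist_flags[i]:
            continue
        keep.append(i)
    if not keep:
        raise DataError("no chunks left after filtering")
    keep = np.array(keep)
    X = np.stack([container.chunks[i].matrix for i in keep])
    mask = np.stack([container.chunks[i].pad_mask for i in keep])
    Y = np.stack([container.tracks[d][keep] for d in datasets], axis=2)
    return {"X": X, "Y": Y, "mask": mask,
            "chunk_indices": keep,
            "seq_ids": np.array([container.chunks[i].seq_id for i in keep])}
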