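"""Training: losses, learning-rate schedules, early stopping, transfer init.

The scorer is trained with AdamW (lr 1e-3) for up to 10 epochs with an
early-stopping patience of 2 on validation loss; the training archive is
split 90:10 into training and validation at the gene level. Two schedules
are available: ``multistep`` (lr 1e-3, halved at epoch 6 and every epoch
after) and ``cosine`` warm restarts (period 5, floor 1e-5).

Losses are averaged over non-pad positions. The focal loss multiplies the
cross-entropy term by ``(1 - P_true)^gamma`` so well-classified positions
are down-weighted; with ``gamma = 0`` it reduces exactly to cross-entropy.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .archive import read_archive, read_metadata
from .dataprep import SegmentedExample
from .modelarch import ModelConfig, SpliceScorer, build_scorer, load_checkpoint, save_checkpoint
from .nn.core import softmax
from .nn.optim import AdamW

logger = logging.getLogger(__name__)

__all__ = [
    "LossSpec",
    "TrainState",
    "loss",
    "loss_and_logit_grad",
    "schedule",
    "split_validation",
    "train_loop",
    "transfer_init",
]

EPS = 1e-10  # clamp inside log to avoid -inf at P=0
INITIAL_LR = 1e-3
ETA_MIN = 1e-5
COSINE_PERIOD = 5


@dataclass
class LossSpec:
    """``kind`` is ``cross_entropy`` or ``focal``; ``gamma`` the focusing exponent."""

    kind: str = "cross_entropy"
    gamma: float = 2.0

    def __post_init__(self):
        if self.kind not in {"cross_entropy", "focal"}:
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


@dataclass
class TrainState:
    epoch: int = 0
    lr: float = INITIAL_LR
    best_val_loss: float = np.inf
    best_epoch: int = 0
    patience_counter: int = 0
    patience_limit: int = 2
    seed: int = 10
    scheduler: str = "multistep"


def loss(probabilities: np.ndarray, labels: np.ndarray, spec: LossSpec | None = None) -> float:
    """Mean loss over non-pad positions.

    ``probabilities`` are simplex rows ``(..., 3)``; ``labels`` are one-hot
    rows or all-zero pad rows, which contribute nothing.
    """
    spec = spec or LossSpec()
    p = probabilities.reshape(-1, probabilities.shape[-1]).astype(np.float64)
    y = labels.reshape(-1, labels.shape[-1]).astype(np.float64)
    valid = y.sum(axis=1) > 0
    if not valid.any():
        return 0.0
    p_true = np.clip((p[valid] * y[valid]).sum(axis=1), EPS, 1.0)
    per_pos = -np.log(p_true)
    if spec.kind == "focal":
        per_pos = (1.0 - p_true) ** spec.gamma * per_pos
    return float(per_pos.mean())


def loss_and_logit_grad(
    logits: np.ndarray, labels: np.ndarray, spec: LossSpec
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the logits.

    Pad rows (all-zero labels) receive zero gradient. The gradient of the
    mean is returned, i.e. already divided by the number of valid positions.
    """
    p = softmax(logits, axis=-1)
    shape = p.shape
    pf = p.reshape(-1, 3).astype(np.float64)
    yf = labels.reshape(-1, 3).astype(np.float64)
    valid = yf.sum(axis=1) > 0
    n_valid = int(valid.sum())
    dlogits = np.zeros_like(pf)
    if n_valid == 0:
        return 0.0, dlogits.reshape(shape).astype(np.float32)
    pv, yv = pf[valid], yf[valid]
    p_true = np.clip((pv * yv).sum(axis=1), EPS, 1.0)
    if spec.kind == "cross_entropy":
        value = float(-np.log(p_true).mean())
        grad = (pv - yv) / n_valid
    else:
        g = spec.gamma
        mod = (1.0 - p_true) ** g
        value = float((mod * -np.log(p_true)).mean())
        # dL/dp_true, then through the softmax Jacobian
        dldp = g * (1.0 - p_true) ** np.maximum(g - 1.0, 0.0) * np.log(p_true) - mod / p_true
        gvec = yv * dldp[:, None]  # dL/dp has only the true-class component
        dot = (gvec * pv).sum(axis=1, keepdims=True)
        grad = pv * (gvec - dot) / n_valid
    dlogits[valid] = grad
    return value, dlogits.reshape(shape).astype(np.float32)


def schedule(epoch: int, kind: str = "multistep") -> float:
    """Learning rate for a 1-indexed epoch.

    ``multistep``: 1e-3 through epoch 5, then halved at epoch 6 and at each
    subsequent epoch. ``cosine``: smooth decay from 1e-3 to 1e-5 with warm
    restarts every 5 epochs.
    """
    if epoch < 1:
        raise ValueError(f"epoch must be >= 1, got {epoch}")
    if kind == "multistep":
        return INITIAL_LR * 0.5 ** max(0, epoch - 5)
    if kind == "cosine":
        t_cur = (epoch - 1) % COSINE_PERIOD
        return ETA_MIN + (INITIAL_LR - ETA_MIN) * (1 + np.cos(np.pi * t_cur / COSINE_PERIOD)) / 2
    raise ValueError(f"unknown scheduler {kind!r}; use 'multistep' or 'cosine'")


def split_validation(
    examples: list[SegmentedExample], fraction: float = 0.1, seed: int = 10
) -> tuple[list[SegmentedExample], list[SegmentedExample]]:
    """Seeded gene-level 90:10 split of a training set."""
    n = len(examples)
    if n < 2:
        raise ValueError(f"need at least 2 genes to split, got {n}")
    n_val = max(1, int(np.floor(n * fraction)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [ex for i, ex in enumerate(examples) if i not in val_idx]
    val = [ex for i, ex in enumerate(examples) if i in val_idx]
    return train, val


def _stack_segments(examples: list[SegmentedExample]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.concatenate([ex.x for ex in examples]),
        np.concatenate([ex.y for ex in examples]),
    )


def _mean_loss(scorer: SpliceScorer, x: np.ndarray, y: np.ndarray,
               spec: LossSpec, batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, x.shape[0], batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        half = scorer.cl // 2
        probs = scorer.forward(xb, training=False)
        value = loss(probs, yb, spec)
        valid = int((yb.sum(axis=-1) > 0).sum())
        total += value * valid
        n += valid
    return total / max(n, 1)


def train_loop(
    train_archive,
    config: ModelConfig,
    loss_spec: LossSpec | None = None,
    scheduler: str = "multistep",
    epochs: int = 10,
    patience: int = 2,
    batch_size: int = 8,
    seed: int = 10,
    val_fraction: float = 0.1,
    output_dir=None,
    scorer: SpliceScorer | None = None,
) -> tuple[SpliceScorer, list[dict]]:
    """Train a scorer from an archive path (or an example list).

    Stops early when validation loss fails to improve for ``patience``
    consecutive epochs; the returned scorer carries the best-validation
    parameters. Per-epoch losses are returned (and written as TSV when
    ``output_dir`` is given).
    """
    loss_spec = loss_spec or LossSpec()
    if isinstance(train_archive, (str, Path)):
        examples, meta = read_archive(train_archive)
        if int(meta["flank"]) != config.flank:
            raise ValueError(
                f"archive flank {int(meta['flank'])} does not match model flank {config.flank}"
            )
    else:
        examples = list(train_archive)
    train_ex, val_ex = split_validation(examples, val_fraction, seed)
    x_train, y_train = _stack_segments(train_ex)
    x_val, y_val = _stack_segments(val_ex)

    if scorer is None:
        scorer = build_scorer(config, seed=seed)
    opt = AdamW(scorer.parameters(), lr=INITIAL_LR)
    rng = np.random.default_rng(seed)
    state = TrainState(seed=seed, scheduler=scheduler, patience_limit=patience)
    best_state: dict | None = None
    logs: list[dict] = []

    for epoch in range(1, epochs + 1):
        state.epoch = epoch
        state.lr = opt.lr = schedule(epoch, scheduler)
        order = rng.permutation(x_train.shape[0])
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            logits = scorer.forward_logits(x_train[idx], training=True)
            value, dlogits = loss_and_logit_grad(logits, y_train[idx], loss_spec)
            if not np.isfinite(value):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}; aborting")
            opt.zero_grad()
            scorer.backward_from_logits(dlogits)
            opt.step()
            epoch_loss += value
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)
        val_loss = _mean_loss(scorer, x_val, y_val, loss_spec, batch_size)
        logs.append({"epoch": epoch, "lr": state.lr,
                     "train_loss": train_loss, "val_loss": val_loss})
        logger.info("epoch %d lr %.2e train %.4f val %.4f", epoch, state.lr, train_loss, val_loss)
        if val_loss < state.best_val_loss:
            state.best_val_loss = val_loss
            state.best_epoch = epoch
            state.patience_counter = 0
            best_state = copy.deepcopy(scorer.state_dict())
        else:
            state.patience_counter += 1
            if state.patience_counter >= state.patience_limit:
                logger.info("early stop at epoch %d (best epoch %d)", epoch, state.best_epoch)
                break

    if best_state is not None:
        scorer.load_state_dict(best_state)
    scorer.metadata.update({
        "seed": seed, "scheduler": scheduler, "loss": loss_spec.kind,
        "best_epoch": state.best_epoch, "best_val_loss": state.best_val_loss,
    })
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        with open(output_dir / "train_log.tsv", "w") as fh:
            fh.write("epoch\tlr\ttrain_loss\tval_loss\n")
            for row in logs:
                fh.write(f"{row['epoch']}\t{row['lr']:.3e}\t"
                         f"{row['train_loss']:.6f}\t{row['val_loss']:.6f}\n")
        save_checkpoint(scorer, output_dir / "model_best.npz")
    return scorer, logs


def transfer_init(
    pretrained_path,
    target_config: ModelConfig,
    policy: str = "unfreeze_all",
    unfreeze_k: int = 1,
) -> SpliceScorer:
    """Initialize from a pretrained checkpoint with a freezing policy.

    ``unfreeze_all`` leaves every parameter trainable; ``unfreeze_last_k``
    freezes everything except the last ``k`` parameterized layers (``k=1``
    unfreezes only the final output convolution). Raises on any
    architecture mismatch, naming the differing field.
    """
    scorer = load_checkpoint(pretrained_path, config=target_config)
    if policy == "unfreeze_all":
        for p in scorer.parameters():
            p.trainable = True
        return scorer
    if policy != "unfreeze_last_k":
        raise ValueError(f"unknown transfer policy {policy!r}")
    layers = scorer._layers()
    if not 1 <= unfreeze_k <= len(layers):
        raise ValueError(f"unfreeze_k must be in [1, {len(layers)}], got {unfreeze_k}")
    for _, layer in layers[:-unfreeze_k]:
        for _, p in layer.params():
            p.trainable = False
    for _, layer in layers[-unfreeze_k:]:
        for _, p in layer.params():
            p.trainable = True
    return scorer
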