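"""Training loops for teacher, baseline, upper-bound and distilled students.

An *iteration* is one minibatch gradient step.  Minibatches are drawn by
seeded shuffling with reshuffling each epoch; datasets smaller than the
batch size are sampled with replacement so every step sees a full batch.
All runs are single-threaded numpy and therefore exactly reproducible for a
fixed (config, seed).

The distillation loop keeps the teacher frozen: its parameters receive no
gradient, and per step the teacher consumes the original-modality inputs
while the student consumes the new-modality ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DualModalityDataset
from .losses import (
    AnnealingSchedule,
    DistillationConfig,
    annealed_alpha,
    combined_loss,
    combined_loss_grad,
    selective_alpha_mask,
)
from .models import NetworkSpec, build_network, load_checkpoint
from .nn import SGD, Network

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "images_to_float",
    "predict_logits",
    "accuracy",
    "train_supervised",
    "train_student_kd",
    "fork_student",
]


@dataclass
class TrainingConfig:
    iterations: int = 2000
    batch_size: int = 64
    learning_rate: float = 0.01
    momentum: float = 0.0
    seed: int = 0
    eval_every: int = 500

    def __post_init__(self):
        if self.iterations < 1 or self.batch_size < 1 or self.eval_every < 1:
            raise ValueError("iterations, batch_size and eval_every must be positive")
        if self.learning_rate < 0 or self.momentum < 0:
            raise ValueError("learning_rate and momentum must be nonnegative")


@dataclass
class TrainingHistory:
    """Per-checkpoint training records (strictly increasing iterations)."""

    records: list[dict] = field(default_factory=list)

    def append(self, **record) -> None:
        if self.records and record["iteration"] <= self.records[-1]["iteration"]:
            raise ValueError("history iterations must be strictly increasing")
        self.records.append(record)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_tidy(self) -> pd.DataFrame:
        """Long format: iteration, metric, value."""
        rows = []
        for rec in self.records:
            for key, value in rec.items():
                if key == "iteration" or value is None:
                    continue
                rows.append({"iteration": rec["iteration"], "metric": key, "value": value})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_tidy().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.records, indent=1))

    def final(self, metric: str):
        return self.records[-1][metric]


def images_to_float(images: np.ndarray) -> np.ndarray:
    """8-bit images -> float32 in [0, 1]; float inputs pass through."""
    x = np.asarray(images)
    if x.dtype == np.uint8:
        return x.astype(np.float32) / 255.0
    return x.astype(np.float32)


def predict_logits(network: Network, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Evaluation-mode forward pass in memory-bounded batches."""
    X = images_to_float(X)
    out = [network.forward(X[i:i + batch_size], training=False)
           for i in range(0, len(X), batch_size)]
    return np.concatenate(out) if out else np.empty((0,))


def accuracy(network: Network, X: np.ndarray, y: np.ndarray) -> float:
    logits = predict_logits(network, X)
    return float((logits.argmax(axis=1) == np.asarray(y)).mean())


def _batch_stream(n: int, batch_size: int, iterations: int, rng: np.random.Generator):
    """Yield seeded minibatch index arrays, one per iteration."""
    if n < batch_size:
        for _ in range(iterations):
            yield rng.integers(0, n, size=batch_size)
        return
    order = rng.permutation(n)
    pos = 0
    for _ in range(iterations):
        if pos + batch_size > n:
            order = rng.permutation(n)
            pos = 0
        yield order[pos:pos + batch_size]
        pos += batch_size


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes), np.float64)
    out[np.arange(len(y)), y] = 1.0
    return out


def _fit_loop(
    network: Network,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig,
    *,
    teacher: Network | None = None,
    X_teacher: np.ndarray | None = None,
    distill: DistillationConfig | None = None,
    schedule: AnnealingSchedule | None = None,
    eval_X: np.ndarray | None = None,
    eval_y: np.ndarray | None = None,
    start_iteration: int = 0,
    total_iterations: int | None = None,
    optimizer: SGD | None = None,
    history: TrainingHistory | None = None,
) -> tuple[TrainingHistory, SGD]:
    """Shared SGD loop for plain supervision and teacher-supervised training."""
    X = images_to_float(X)
    y = np.asarray(y, dtype=np.int64)
    if len(X) == 0:
        raise ValueError("training dataset is empty")
    n_classes = network.forward(X[:1], training=False).shape[1]
    if teacher is not None and X_teacher is None:
        raise ValueError("teacher supervision requires original-modality inputs")
    if X_teacher is not None:
        X_teacher = images_to_float(X_teacher)

    total = total_iterations if total_iterations is not None else (
        start_iteration + config.iterations
    )
    history = history if history is not None else TrainingHistory()
    optimizer = optimizer or SGD(network, config.learning_rate, config.momentum)
    optimizer.learning_rate = config.learning_rate
    optimizer.momentum = config.momentum
    rng = np.random.default_rng(config.seed)

    acc_terms = {"total": 0.0, "distillation": 0.0, "student": 0.0, "count": 0}
    for step, batch in enumerate(
        _batch_stream(len(X), config.batch_size, config.iterations, rng)
    ):
        i_global = start_iteration + step
        xb, yb = X[batch], y[batch]
        yb_1h = _one_hot(yb, n_classes)
        logits = network.forward(xb, training=True, rng=rng)

        if teacher is None:
            # plain supervised cross-entropy at T=1 (float64, matching the
            # numerics of the combined loss at alpha=0)
            z64 = logits.astype(np.float64)
            exp = np.exp(z64 - z64.max(axis=1, keepdims=True))
            p = exp / exp.sum(axis=1, keepdims=True)
            grad = (p - yb_1h) / len(yb)
            ce = -np.log(np.clip(p[np.arange(len(yb)), yb], 1e-30, None))
            acc_terms["total"] += float(ce.mean())
            acc_terms["student"] += float(ce.mean())
            alpha_eff = 0.0
        else:
            zt = teacher.forward(X_teacher[batch], training=False)
            if schedule is not None:
                alpha_eff = annealed_alpha(schedule, min(i_global, schedule.n_iterations - 1))
            else:
                alpha_eff = distill.alpha
            in_bootstrap = i_global < distill.bootstrap_fraction * total
            if distill.selective and not in_bootstrap:
                alpha_vec = selective_alpha_mask(zt, yb, alpha_eff)
            else:
                alpha_vec = np.full(len(yb), alpha_eff)
            bd = combined_loss(
                zt, logits, yb_1h, alpha_vec, distill.temperature,
                distill.student_loss_temperature_mode,
            )
            grad = combined_loss_grad(
                zt, logits, yb_1h, alpha_vec, distill.temperature,
                distill.student_loss_temperature_mode, distill.rescale_grad_t2,
            )
            acc_terms["total"] += bd.total
            acc_terms["distillation"] += bd.distillation_term
            acc_terms["student"] += bd.student_term
        acc_terms["count"] += 1

        network.backward(grad)
        optimizer.step()

        done = step + 1 == config.iterations
        if (i_global + 1) % config.eval_every == 0 or done:
            k = acc_terms["count"]
            history.append(
                iteration=i_global + 1,
                train_accuracy=accuracy(network, X, y),
                test_accuracy=(
                    accuracy(network, eval_X, eval_y) if eval_X is not None else None
                ),
                loss_total=acc_terms["total"] / k,
                loss_distillation=(
                    acc_terms["distillation"] / k if teacher is not None else None
                ),
                loss_student=acc_terms["student"] / k,
                alpha=float(alpha_eff),
            )
            acc_terms = {"total": 0.0, "distillation": 0.0, "student": 0.0, "count": 0}
    return history, optimizer


def train_supervised(
    network: Network | NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig,
    eval_data: tuple[np.ndarray, np.ndarray] | None = None,
    init_seed: int = 0,
) -> tuple[Network, TrainingHistory]:
    """Plain cross-entropy SGD training (teacher / baseline / upper bound)."""
    if isinstance(network, NetworkSpec):
        network = build_network(network, seed=init_seed)
    X = images_to_float(X)
    first_conv = next((l for l in network.layers if hasattr(l, "in_channels")), None)
    if first_conv is not None and X.shape[1] != first_conv.in_channels:
        raise ValueError(
            f"network expects {first_conv.in_channels}-channel input, "
            f"data has {X.shape[1]} channels"
        )
    eval_X, eval_y = eval_data if eval_data is not None else (None, None)
    history, _ = _fit_loop(
        network, X, y, config, eval_X=eval_X, eval_y=eval_y
    )
    return network, history


def train_student_kd(
    teacher: Network,
    student: Network | NetworkSpec,
    dataset: DualModalityDataset,
    config: TrainingConfig,
    distill: DistillationConfig,
    schedule: AnnealingSchedule | None = None,
    eval_dataset: DualModalityDataset | None = None,
    start_iteration: int = 0,
    total_iterations: int | None = None,
    optimizer: SGD | None = None,
    init_seed: int = 0,
) -> tuple[Network, TrainingHistory, SGD]:
    """Teacher-supervised training on a paired-modality dataset.

    The frozen teacher reads each sample's original modality, the student its
    new modality; the loss is the (optionally annealed or selective) convex
    combination of distillation and hard-label cross-entropies.
    """
    if isinstance(student, NetworkSpec):
        student = build_network(student, seed=init_seed)
    if len(dataset) == 0:
        raise ValueError("paired dataset is empty")
    eval_X = eval_y = None
    if eval_dataset is not None:
        eval_X, eval_y = eval_dataset.new, eval_dataset.labels
    history, optimizer = _fit_loop(
        student,
        dataset.new,
        dataset.labels,
        config,
        teacher=teacher,
        X_teacher=dataset.original,
        distill=distill,
        schedule=schedule,
        eval_X=eval_X,
        eval_y=eval_y,
        start_iteration=start_iteration,
        total_iterations=total_iterations,
        optimizer=optimizer,
    )
    return student, history, optimizer


def fork_student(checkpoint_path: str | Path) -> tuple[Network, Network, dict]:
    """Load a checkpoint into two parameter-identical, independent students.

    Both continue training from the same point; downstream RNG streams are
    the caller's to choose (and should differ if the continuations are meant
    to be compared as independent protocols).
    """
    net_a, spec, meta = load_checkpoint(checkpoint_path)
    net_b, _, _ = load_checkpoint(checkpoint_path)
    return net_a, net_b, meta
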