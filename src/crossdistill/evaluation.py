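"""Accuracy metrics and the experiment grid runner.

``evaluate`` scores a network on a labeled dataset: overall accuracy,
per-class accuracies, and tail accuracy (the unweighted mean over a stated
subset of the least-represented classes — digits 7, 8, 9 in the benchmark's
imbalance profile).

``run_grid`` reproduces the benchmark protocols end to end:

* ``fig3``  — balanced 2cMNIST accuracy-vs-train-set-size curves
* ``fig5``  — the imbalanced variant with tail-class accuracy
* ``fig6``  — alpha-annealing sweep on dual-modality CIFAR-10
* ``fig7``  — the annealing sweep on 2cMNIST at train size 1000
* ``fig8``  — selective-distillation fork protocol on CIFAR-10
* ``synthetic`` — the no-download fixture analog of fig3

Each cell is repeated ``n_repeats`` times with seeds derived
deterministically from (base seed, cell, repeat); per-run rows are kept next
to the aggregates so every mean/std is recomputable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    DualModalityDataset,
    ImbalanceProfile,
    generate_synthetic_dual_modality,
    load_cifar_pair,
    load_mnist_2c,
    sample_imbalanced_subset,
    sample_subset,
)
from .losses import AnnealingSchedule, DistillationConfig
from .models import build_network, cifar_net_spec, mnist_net_spec
from .nn import SGD, Network
from .training import (
    TrainingConfig,
    predict_logits,
    train_student_kd,
    train_supervised,
)

__all__ = [
    "EvaluationReport",
    "ExperimentGrid",
    "GridResult",
    "evaluate",
    "run_grid",
    "default_annealing_pairs",
    "EXPERIMENT_IDS",
]

EXPERIMENT_IDS = ("fig3", "fig5", "fig6", "fig7", "fig8", "synthetic")

PAPER_SIZES = (10, 50, 100, 250, 500, 750, 1000)
TAIL_CLASSES = (7, 8, 9)


@dataclass
class EvaluationReport:
    overall_accuracy: float
    per_class_accuracy: np.ndarray
    n_evaluated: int
    tail_classes: tuple[int, ...] | None = None
    tail_accuracy: float | None = None


def evaluate(model, dataset, tail_classes=None) -> EvaluationReport:
    """Argmax classification accuracy, overall / per class / tail.

    ``model`` is a :class:`~crossdistill.nn.Network` or a fitted estimator;
    ``dataset`` a :class:`DualModalityDataset` (scored on its new modality)
    or an ``(X, y)`` tuple.  Overall accuracy equals the label-frequency-
    weighted mean of per-class accuracies; tail accuracy is the unweighted
    mean over ``tail_classes``.
    """
    if isinstance(dataset, DualModalityDataset):
        X, y = dataset.new, dataset.labels
    else:
        X, y = dataset
    y = np.asarray(y, dtype=np.int64)
    if len(y) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    network = model.model_ if hasattr(model, "model_") else model
    if not isinstance(network, Network):
        raise TypeError("model must be a Network or a fitted estimator")
    pred = predict_logits(network, X).argmax(axis=1)
    n_classes = int(y.max()) + 1 if tail_classes is None else max(int(y.max()) + 1,
                                                                 max(tail_classes) + 1)
    per_class = np.full(n_classes, np.nan)
    for cls in range(n_classes):
        mask = y == cls
        if mask.any():
            per_class[cls] = float((pred[mask] == cls).mean())
    report = EvaluationReport(
        overall_accuracy=float((pred == y).mean()),
        per_class_accuracy=per_class,
        n_evaluated=len(y),
    )
    if tail_classes is not None:
        tail = tuple(int(c) for c in tail_classes)
        report.tail_classes = tail
        report.tail_accuracy = float(np.nanmean(per_class[list(tail)]))
    return report


def default_annealing_pairs() -> tuple[tuple[float, float], ...]:
    """All (alpha_start, alpha_end) pairs with start in {0.2,...,1.0}, end in
    {0.0,...,0.8} and end < start — the sweep behind the annealing figures."""
    starts = (0.2, 0.4, 0.6, 0.8, 1.0)
    ends = (0.0, 0.2, 0.4, 0.6, 0.8)
    return tuple((a0, an) for a0 in starts for an in ends if an < a0)


@dataclass
class ExperimentGrid:
    """Configuration of one benchmark experiment.

    Defaults follow the benchmark protocols (alpha=0.6, T=8 where fixed;
    2000 iterations / batch 64 / lr 0.01 for the digit experiments; 50,000
    iterations / momentum 0.5 for the CIFAR ones).  ``iterations`` and
    ``teacher_size`` may be overridden to run scaled-down variants.
    """

    experiment: str = "synthetic"
    sizes: tuple[int, ...] | None = None
    alpha_pairs: tuple[tuple[float, float], ...] | None = None
    n_repeats: int = 3
    base_seed: int = 0
    data_dir: str | Path | None = None
    alpha: float = 0.6
    temperature: float = 8.0
    # the canonical distillation recipe: hard-label term at T=1 and a
    # T^2-compensated distillation gradient, so both terms train at
    # comparable rates within the protocol's iteration budget
    student_loss_temperature_mode: str = "unit_temperature"
    rescale_grad_t2: bool = True
    iterations: int | None = None
    batch_size: int = 64
    learning_rate: float = 0.01
    momentum: float | None = None
    teacher_size: int | None = None
    eval_every: int = 500
    # synthetic fixture conditions
    synthetic_pool: int = 2000
    synthetic_test: int = 1000
    synthetic_image_size: int = 20

    def __post_init__(self):
        if self.experiment not in EXPERIMENT_IDS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; valid ids: {EXPERIMENT_IDS}"
            )
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class GridResult:
    """Per-run rows plus mean/std aggregates (recomputable from the rows)."""

    experiment: str
    runs: pd.DataFrame
    reference: pd.DataFrame  # teacher / upper-bound rows (trained once)

    @property
    def summary(self) -> pd.DataFrame:
        g = self.runs.groupby(["cell", "condition", "metric"])["value"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        out["std"] = out["std"].fillna(0.0)
        return out


def _seed_for(base_seed: int, *entropy) -> int:
    # crc32 keying: stable across processes (unlike builtin str hashing)
    key = "|".join(repr(e) for e in entropy).encode()
    ss = np.random.SeedSequence([int(base_seed), zlib.crc32(key)])
    return int(ss.generate_state(1)[0] % (2**31))


def _require_data(grid: ExperimentGrid, what: str, loader):
    if grid.data_dir is None:
        raise FileNotFoundError(
            f"experiment {grid.experiment!r} needs {what}; pass data_dir "
            f"pointing at the raw files"
        )
    return loader(grid.data_dir)


def _mnist_datasets(grid: ExperimentGrid):
    train = _require_data(
        grid, "MNIST IDX files (train/t10k images+labels)",
        lambda d: load_mnist_2c(d, "train"),
    )
    test = load_mnist_2c(grid.data_dir, "test")
    return train, test


def _cifar_datasets(grid: ExperimentGrid):
    train = _require_data(
        grid, "CIFAR-10 batch files (data_batch_*, test_batch)",
        lambda d: load_cifar_pair(d, "train"),
    )
    test = load_cifar_pair(grid.data_dir, "test")
    return train, test


def _synthetic_datasets(grid: ExperimentGrid):
    train = generate_synthetic_dual_modality(
        grid.synthetic_pool, image_size=grid.synthetic_image_size,
        seed=_seed_for(grid.base_seed, "synthetic-train"),
    )
    test = generate_synthetic_dual_modality(
        grid.synthetic_test, image_size=grid.synthetic_image_size,
        seed=_seed_for(grid.base_seed, "synthetic-test"),
    )
    return train, test


def _spec_for(grid: ExperimentGrid, channels: int):
    if grid.experiment in ("fig6", "fig8"):
        return cifar_net_spec(channels, 32)
    size = grid.synthetic_image_size if grid.experiment == "synthetic" else 28
    return mnist_net_spec(channels, size)


def _config(grid: ExperimentGrid, seed: int, iterations: int) -> TrainingConfig:
    momentum = grid.momentum
    if momentum is None:
        momentum = 0.5 if grid.experiment in ("fig6", "fig8") else 0.0
    return TrainingConfig(
        iterations=iterations, batch_size=grid.batch_size,
        learning_rate=grid.learning_rate, momentum=momentum,
        seed=seed, eval_every=grid.eval_every,
    )


def _default_iterations(grid: ExperimentGrid) -> int:
    if grid.iterations is not None:
        return grid.iterations
    if grid.experiment in ("fig6", "fig8"):
        return 50_000
    return 2000


def _train_reference(grid, train, test, iterations, teacher_size, imbalanced=False):
    """Teacher (original modality) and upper bound (new modality), trained
    once per experiment and shared across repeats."""
    seed_t = _seed_for(grid.base_seed, "teacher")
    seed_u = _seed_for(grid.base_seed, "upper_bound")
    if teacher_size is None or teacher_size >= len(train):
        pool = train
    elif imbalanced:
        pool = sample_imbalanced_subset(
            train, ImbalanceProfile.teacher_linear(train.n_classes),
            teacher_size, seed=_seed_for(grid.base_seed, "teacher-pool"),
        )
    else:
        pool = sample_subset(train, teacher_size,
                             seed=_seed_for(grid.base_seed, "teacher-pool"))
    teacher, _ = train_supervised(
        _spec_for(grid, 1), pool.original, pool.labels,
        _config(grid, seed_t, iterations), init_seed=seed_t,
    )
    upper, _ = train_supervised(
        _spec_for(grid, 3), pool.new, pool.labels,
        _config(grid, seed_u, iterations), init_seed=seed_u,
    )
    rows = []
    for name, net, X in (("teacher", teacher, test.original),
                         ("upper_bound", upper, test.new)):
        rep = evaluate(net, (X, test.labels), tail_classes=TAIL_CLASSES)
        rows.append({"condition": name, "metric": "test_accuracy",
                     "value": rep.overall_accuracy})
        rows.append({"condition": name, "metric": "tail_accuracy",
                     "value": rep.tail_accuracy})
    return teacher, pool, pd.DataFrame(rows)


def _size_curve(grid, train, test, pool, teacher, iterations, imbalanced):
    sizes = grid.sizes if grid.sizes is not None else (
        PAPER_SIZES if grid.experiment in ("fig3", "fig5") else (10, 50, 100)
    )
    distill = DistillationConfig(
        alpha=grid.alpha, temperature=grid.temperature,
        student_loss_temperature_mode=grid.student_loss_temperature_mode,
        rescale_grad_t2=grid.rescale_grad_t2,
    )
    rows = []
    for size in sizes:
        for repeat in range(grid.n_repeats):
            seed = _seed_for(grid.base_seed, "size", size, repeat)
            if imbalanced:
                subset = sample_imbalanced_subset(
                    pool, ImbalanceProfile.student_quadratic(pool.n_classes),
                    size, seed=seed,
                )
            else:
                subset = sample_subset(pool, size, seed=seed)
            for cond in ("student", "baseline"):
                run_seed = _seed_for(grid.base_seed, "size", size, repeat, cond)
                config = _config(grid, run_seed, iterations)
                if cond == "student":
                    net, _, _ = train_student_kd(
                        teacher, _spec_for(grid, 3), subset, config, distill,
                        init_seed=run_seed,
                    )
                else:
                    net, _ = train_supervised(
                        _spec_for(grid, 3), subset.new, subset.labels, config,
                        init_seed=run_seed,
                    )
                rep = evaluate(net, test, tail_classes=TAIL_CLASSES)
                for metric, value in (("test_accuracy", rep.overall_accuracy),
                                      ("tail_accuracy", rep.tail_accuracy)):
                    rows.append({"cell": size, "repeat": repeat, "condition": cond,
                                 "metric": metric, "value": value, "seed": run_seed})
    return pd.DataFrame(rows)


def _annealing_sweep(grid, train, test, pool_size, teacher, iterations):
    pairs = grid.alpha_pairs if grid.alpha_pairs is not None else default_annealing_pairs()
    rows = []
    for repeat in range(grid.n_repeats):
        pool_seed = _seed_for(grid.base_seed, "anneal-pool", repeat)
        subset = sample_subset(train, pool_size, seed=pool_seed)
        for pair in pairs:
            a0, an = pair
            cell = f"{a0:.1f}->{an:.1f}"
            run_seed = _seed_for(grid.base_seed, "anneal", cell, repeat)
            config = _config(grid, run_seed, iterations)
            schedule = AnnealingSchedule(a0, an, iterations)
            distill = DistillationConfig(
                alpha=a0, temperature=grid.temperature,
                student_loss_temperature_mode=grid.student_loss_temperature_mode,
                rescale_grad_t2=grid.rescale_grad_t2,
            )
            net, _, _ = train_student_kd(
                teacher, _spec_for(grid, 3), subset, config, distill,
                schedule=schedule, init_seed=run_seed,
            )
            rep = evaluate(net, test)
            rows.append({"cell": cell, "repeat": repeat, "condition": "student",
                         "metric": "test_accuracy", "value": rep.overall_accuracy,
                         "seed": run_seed})
        # baseline for comparison, one per repeat
        run_seed = _seed_for(grid.base_seed, "anneal-baseline", repeat)
        net, _ = train_supervised(
            _spec_for(grid, 3), subset.new, subset.labels,
            _config(grid, run_seed, iterations), init_seed=run_seed,
        )
        rep = evaluate(net, test)
        rows.append({"cell": "baseline", "repeat": repeat, "condition": "baseline",
                     "metric": "test_accuracy", "value": rep.overall_accuracy,
                     "seed": run_seed})
    return pd.DataFrame(rows)


def _fork_protocol(grid, train, test, teacher, iterations):
    """Default-vs-selective fork: distill for the bootstrap half, duplicate,
    continue one student per protocol for the second half."""
    half = iterations // 2
    distill = DistillationConfig(
        alpha=grid.alpha, temperature=grid.temperature,
        student_loss_temperature_mode=grid.student_loss_temperature_mode,
        rescale_grad_t2=grid.rescale_grad_t2,
    )
    rows = []
    for repeat in range(grid.n_repeats):
        pool_seed = _seed_for(grid.base_seed, "fork-pool", repeat)
        subset = sample_subset(train, min(5000, len(train)), seed=pool_seed)
        boot_seed = _seed_for(grid.base_seed, "fork-boot", repeat)
        config = _config(grid, boot_seed, half)
        student, _, opt = train_student_kd(
            teacher, _spec_for(grid, 3), subset, config, distill,
            init_seed=boot_seed, total_iterations=iterations,
        )
        base_state = student.get_state()
        base_velocity = [v.copy() for v in opt.velocity]
        momentum = grid.momentum if grid.momentum is not None else 0.5
        for cond, selective in (("default_kd", False), ("selective_kd", True)):
            cont = build_network(_spec_for(grid, 3), seed=boot_seed)
            cont.set_state(base_state)
            cont_opt = SGD(cont, grid.learning_rate, momentum)
            cont_opt.velocity = [v.copy() for v in base_velocity]
            cont_seed = _seed_for(grid.base_seed, "fork-cont", cond, repeat)
            cont_config = _config(grid, cont_seed, iterations - half)
            dc = DistillationConfig(
                alpha=grid.alpha, temperature=grid.temperature,
                selective=selective, bootstrap_fraction=0.5,
                student_loss_temperature_mode=grid.student_loss_temperature_mode,
                rescale_grad_t2=grid.rescale_grad_t2,
            )
            cont, hist, _ = train_student_kd(
                teacher, cont, subset, cont_config, dc,
                start_iteration=half, total_iterations=iterations,
                optimizer=cont_opt, eval_dataset=test,
            )
            rows.append({"cell": "final", "repeat": repeat, "condition": cond,
                         "metric": "train_accuracy",
                         "value": hist.final("train_accuracy"), "seed": cont_seed})
            rows.append({"cell": "final", "repeat": repeat, "condition": cond,
                         "metric": "test_accuracy",
                         "value": hist.final("test_accuracy"), "seed": cont_seed})
    return pd.DataFrame(rows)


def run_grid(grid: ExperimentGrid) -> GridResult:
    """Run one benchmark experiment; see the module docstring for ids."""
    iterations = _default_iterations(grid)
    if grid.experiment == "synthetic":
        train, test = _synthetic_datasets(grid)
        teacher_size = grid.teacher_size  # None -> full pool
        teacher, pool, ref = _train_reference(grid, train, test, iterations, teacher_size)
        runs = _size_curve(grid, train, test, pool, teacher, iterations, imbalanced=False)
    elif grid.experiment == "fig3":
        train, test = _mnist_datasets(grid)
        teacher, pool, ref = _train_reference(
            grid, train, test, iterations,
            grid.teacher_size if grid.teacher_size is not None else 5000,
        )
        runs = _size_curve(grid, train, test, pool, teacher, iterations, imbalanced=False)
    elif grid.experiment == "fig5":
        train, test = _mnist_datasets(grid)
        teacher, pool, ref = _train_reference(
            grid, train, test, iterations,
            grid.teacher_size if grid.teacher_size is not None else 5000,
            imbalanced=True,
        )
        runs = _size_curve(grid, train, test, train, teacher, iterations, imbalanced=True)
    elif grid.experiment in ("fig6", "fig7"):
        if grid.experiment == "fig6":
            train, test = _cifar_datasets(grid)
            pool_size = 5000
        else:
            train, test = _mnist_datasets(grid)
            pool_size = 1000
        teacher, _, ref = _train_reference(grid, train, test, iterations,
                                           grid.teacher_size)
        runs = _annealing_sweep(grid, train, test, pool_size, teacher, iterations)
    elif grid.experiment == "fig8":
        train, test = _cifar_datasets(grid)
        teacher, _, ref = _train_reference(grid, train, test, iterations,
                                           grid.teacher_size)
        runs = _fork_protocol(grid, train, test, teacher, iterations)
    return GridResult(experiment=grid.experiment, runs=runs, reference=ref)
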