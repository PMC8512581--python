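"""Temperature-softened distillation losses and the alpha-annealing schedule.

The training signal for a cross-modal student network is a convex combination
of two cross-entropies:

* the *distillation loss* ``L_D``, between the teacher's and the student's
  temperature-softened class distributions, and
* the *student loss* ``L_S``, between the student's distribution and the
  one-hot ground-truth label,

combined as ``L = alpha * L_D + (1 - alpha) * L_S``.  ``alpha`` may be fixed,
linearly annealed over training, or gated per example (selective
distillation: examples the teacher misclassifies contribute only ``L_S``).

All functions accept a single logit vector of shape ``(C,)`` or a batch of
shape ``(N, C)``; batched losses are reduced by the mean over examples.
Analytic gradients with respect to the student logits are provided for the
training loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistillationConfig",
    "AnnealingSchedule",
    "LossBreakdown",
    "softened_probabilities",
    "distillation_loss",
    "student_loss",
    "combined_loss",
    "combined_loss_grad",
    "selective_combined_loss",
    "selective_alpha_mask",
    "annealed_alpha",
]

_MODES = ("paper_literal", "unit_temperature")


@dataclass
class DistillationConfig:
    """Hyperparameters of the distillation objective.

    Parameters
    ----------
    alpha : float in [0, 1]
        Weight of the distillation term in the convex combination.
    temperature : float > 0
        Softmax temperature applied to both teacher and student logits in the
        distillation term.
    selective : bool
        If True, after the bootstrap phase the distillation term is applied
        only to examples the teacher classifies correctly.
    bootstrap_fraction : float in [0, 1]
        Fraction of training during which selectivity is disabled.
    student_loss_temperature_mode : {"paper_literal", "unit_temperature"}
        Whether the hard-label term also uses ``temperature``
        (``paper_literal``) or the conventional T=1 (``unit_temperature``).
    rescale_grad_t2 : bool
        Multiply the distillation gradient by T**2 so its magnitude stays
        comparable to the hard-label gradient across temperatures.  Off by
        default.
    """

    alpha: float = 0.6
    temperature: float = 8.0
    selective: bool = False
    bootstrap_fraction: float = 0.5
    student_loss_temperature_mode: str = "paper_literal"
    rescale_grad_t2: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if not 0.0 <= self.bootstrap_fraction <= 1.0:
            raise ValueError(
                f"bootstrap_fraction must lie in [0, 1], got {self.bootstrap_fraction}"
            )
        if self.student_loss_temperature_mode not in _MODES:
            raise ValueError(
                f"student_loss_temperature_mode must be one of {_MODES}, "
                f"got {self.student_loss_temperature_mode!r}"
            )


@dataclass(frozen=True)
class AnnealingSchedule:
    """Linear schedule for alpha over ``n_iterations`` training steps.

    alpha moves linearly from ``alpha_start`` at iteration 0 to ``alpha_end``
    at iteration ``n_iterations - 1``.
    """

    alpha_start: float
    alpha_end: float
    n_iterations: int

    def __post_init__(self) -> None:
        for name in ("alpha_start", "alpha_end"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")

    def __call__(self, i: int) -> float:
        return annealed_alpha(self, i)


@dataclass
class LossBreakdown:
    """Per-batch record of the combined objective and its components.

    Scalar attributes are batch means; the ``per_example_*`` arrays retain
    the unreduced values so that ``total`` is always the mean of
    ``alpha_i * L_D_i + (1 - alpha_i) * L_S_i``.
    """

    distillation_term: float
    student_term: float
    total: float
    alpha_used: np.ndarray
    per_example_distillation: np.ndarray = field(repr=False, default=None)
    per_example_student: np.ndarray = field(repr=False, default=None)
    per_example_total: np.ndarray = field(repr=False, default=None)


def _as_batch(z: np.ndarray, name: str) -> tuple[np.ndarray, bool]:
    z = np.asarray(z, dtype=np.float64)
    if np.isnan(z).any() or np.isinf(z).any():
        raise ValueError(f"{name} must be finite")
    if z.ndim == 1:
        return z[None, :], True
    if z.ndim == 2:
        return z, False
    raise ValueError(f"{name} must be 1- or 2-dimensional, got shape {z.shape}")


def _check_temperature(T: float) -> float:
    T = float(T)
    if not T > 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    return T


def softened_probabilities(z: np.ndarray, T: float = 1.0) -> np.ndarray:
    """Temperature-scaled softmax ``p_i = exp(z_i/T) / sum_j exp(z_j/T)``.

    Numerically stabilized by subtracting the maximum logit before
    exponentiation.  Higher T flattens the distribution, exposing the
    inter-class similarity structure ("dark knowledge") of the logits.
    """
    T = _check_temperature(T)
    zb, single = _as_batch(z, "logits")
    s = zb / T
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if single else p


def _log_softened(z: np.ndarray, T: float) -> np.ndarray:
    # log p with the same stabilization; z is already a 2-D batch
    s = z / T
    s = s - s.max(axis=1, keepdims=True)
    return s - np.log(np.exp(s).sum(axis=1, keepdims=True))


def distillation_loss(
    z_t: np.ndarray, z_s: np.ndarray, T: float = 1.0, *, reduce: bool = True
) -> float | np.ndarray:
    """Cross-entropy of the student's softened distribution under the teacher's.

    ``sum_i -p_i(z_t, T) * log p_i(z_s, T)``, averaged over a batch.  By the
    Gibbs inequality its minimum over ``z_s`` is the entropy of the teacher's
    softened distribution, attained when the two distributions coincide.
    """
    T = _check_temperature(T)
    zt, _ = _as_batch(z_t, "teacher logits")
    zs, single = _as_batch(z_s, "student logits")
    if zt.shape != zs.shape:
        raise ValueError(
            f"teacher and student logits must share a shape, got {zt.shape} vs {zs.shape}"
        )
    p_t = softened_probabilities(zt, T)
    per = -(p_t * _log_softened(zs, T)).sum(axis=1)
    if not reduce:
        return per[0] if single else per
    return float(per.mean())


def _check_one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 1:
        y = y[None, :]
    if y.shape[1] != n_classes:
        raise ValueError(f"one-hot labels have {y.shape[1]} classes, logits have {n_classes}")
    ok = np.all((y == 0) | (y == 1)) and np.all(y.sum(axis=1) == 1)
    if not ok:
        raise ValueError("labels must be valid one-hot vectors (exactly one entry equal to 1)")
    return y


def student_loss(
    z_s: np.ndarray,
    y: np.ndarray,
    T: float = 1.0,
    mode: str = "paper_literal",
    *,
    reduce: bool = True,
) -> float | np.ndarray:
    """Hard-label cross-entropy ``sum_i -y_i * log p_i(z_s, T_eff)``.

    ``T_eff = T`` in ``paper_literal`` mode; ``T_eff = 1`` in
    ``unit_temperature`` mode (the convention of the classical distillation
    literature for the ground-truth term).
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    T_eff = _check_temperature(T) if mode == "paper_literal" else 1.0
    zs, single = _as_batch(z_s, "student logits")
    yb = _check_one_hot(y, zs.shape[1])
    if yb.shape[0] != zs.shape[0]:
        raise ValueError("batch sizes of logits and labels differ")
    per = -(yb * _log_softened(zs, T_eff)).sum(axis=1)
    if not reduce:
        return per[0] if single else per
    return float(per.mean())


def _broadcast_alpha(alpha, n: int) -> np.ndarray:
    a = np.asarray(alpha, dtype=np.float64)
    if a.ndim == 0:
        a = np.full(n, float(a))
    if a.shape != (n,):
        raise ValueError(f"alpha must be a scalar or length-{n} vector")
    if (a < 0).any() or (a > 1).any():
        raise ValueError("alpha must lie in [0, 1]")
    return a


def combined_loss(
    z_t: np.ndarray,
    z_s: np.ndarray,
    y: np.ndarray,
    alpha: float | np.ndarray,
    T: float = 1.0,
    mode: str = "paper_literal",
) -> LossBreakdown:
    """Convex combination ``alpha * L_D + (1 - alpha) * L_S`` per example.

    ``alpha`` may be a scalar or a per-example vector (the selective variant
    passes a gated vector).  Batch reduction is the mean over examples.
    """
    zs, _ = _as_batch(z_s, "student logits")
    n = zs.shape[0]
    a = _broadcast_alpha(alpha, n)
    ld = np.atleast_1d(distillation_loss(z_t, z_s, T, reduce=False))
    ls = np.atleast_1d(student_loss(z_s, y, T, mode, reduce=False))
    per_total = a * ld + (1.0 - a) * ls
    return LossBreakdown(
        distillation_term=float(ld.mean()),
        student_term=float(ls.mean()),
        total=float(per_total.mean()),
        alpha_used=a,
        per_example_distillation=ld,
        per_example_student=ls,
        per_example_total=per_total,
    )


def combined_loss_grad(
    z_t: np.ndarray,
    z_s: np.ndarray,
    y: np.ndarray,
    alpha: float | np.ndarray,
    T: float = 1.0,
    mode: str = "paper_literal",
    rescale_grad_t2: bool = False,
) -> np.ndarray:
    """Gradient of the batch-mean combined loss with respect to ``z_s``.

    d L_D / d z_s = (p_s(T) - p_t(T)) / T and
    d L_S / d z_s = (p_s(T_eff) - y) / T_eff; the optional T**2 rescaling of
    the distillation term keeps its gradient magnitude temperature-invariant.
    """
    T = _check_temperature(T)
    zt, _ = _as_batch(z_t, "teacher logits")
    zs, single = _as_batch(z_s, "student logits")
    if zt.shape != zs.shape:
        raise ValueError("teacher and student logits must share a shape")
    n, c = zs.shape
    yb = _check_one_hot(y, c)
    a = _broadcast_alpha(alpha, n)[:, None]

    g_d = (softened_probabilities(zs, T) - softened_probabilities(zt, T)) / T
    if rescale_grad_t2:
        g_d = g_d * T * T
    T_eff = T if mode == "paper_literal" else 1.0
    g_s = (softened_probabilities(zs, T_eff) - yb) / T_eff

    g = (a * g_d + (1.0 - a) * g_s) / n
    return g[0] if single else g


def selective_alpha_mask(
    z_t: np.ndarray, labels: np.ndarray, alpha: float
) -> np.ndarray:
    """Per-example alpha: ``alpha`` where the teacher's argmax equals the
    label, 0 elsewhere.  Argmax ties are broken by the lowest class index."""
    zt, _ = _as_batch(z_t, "teacher logits")
    labels = np.asarray(labels, dtype=np.int64).reshape(-1)
    if labels.shape[0] != zt.shape[0]:
        raise ValueError("batch sizes of teacher logits and labels differ")
    correct = zt.argmax(axis=1) == labels
    return np.where(correct, float(alpha), 0.0)


def selective_combined_loss(
    z_t: np.ndarray,
    z_s: np.ndarray,
    y: np.ndarray,
    alpha: float,
    T: float = 1.0,
    mode: str = "paper_literal",
    in_bootstrap: bool = False,
) -> LossBreakdown:
    """Selective distillation objective.

    During the bootstrap phase this is exactly :func:`combined_loss`.
    Afterwards, examples the teacher misclassifies have alpha set to zero, so
    only the hard-label term trains the student on them.
    """
    if in_bootstrap:
        return combined_loss(z_t, z_s, y, alpha, T, mode)
    yb = _check_one_hot(np.asarray(y, dtype=np.float64), np.atleast_2d(z_t).shape[1])
    labels = yb.argmax(axis=1)
    a = selective_alpha_mask(z_t, labels, alpha)
    if np.asarray(z_s).ndim == 1:
        a = float(a[0])
    return combined_loss(z_t, z_s, y, a, T, mode)


def annealed_alpha(schedule: AnnealingSchedule, i: int) -> float:
    """alpha at iteration ``i``: linear from ``alpha_start`` (i=0) to
    ``alpha_end`` (i = n-1).  A single-iteration schedule returns
    ``alpha_start``."""
    n = schedule.n_iterations
    if not 0 <= i <= n - 1:
        raise IndexError(f"iteration index {i} outside [0, {n - 1}]")
    if n == 1:
        return float(schedule.alpha_start)
    return float(
        schedule.alpha_start
        + i * (schedule.alpha_end - schedule.alpha_start) / (n - 1)
    )
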