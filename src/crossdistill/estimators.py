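"""Scikit-learn style estimators wrapping the training engine.

``ConvNetClassifier`` trains one of the reference convolutional networks
with plain cross-entropy SGD — used for teachers, baselines and upper
bounds.  ``DistilledStudentClassifier`` trains a student on the new modality
under the supervision of a frozen, already-fitted teacher, using the
temperature-softened combined loss (optionally annealed or selective).

Both follow the scikit-learn contract: hyperparameters in ``__init__``,
``fit``/``predict``/``predict_proba``/``score``, ``get_params``/
``set_params``, and fitted attributes with a trailing underscore — so they
compose with ``sklearn.base.clone`` and model-selection utilities.  Inputs
are image batches of shape (N, C, H, W), uint8 in [0, 255] or float in
[0, 1].
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .data import DualModalityDataset
from .losses import AnnealingSchedule, DistillationConfig, softened_probabilities
from .models import NetworkSpec, build_network, cifar_net_spec, mnist_net_spec
from .training import TrainingConfig, _fit_loop, accuracy, predict_logits

__all__ = ["ConvNetClassifier", "DistilledStudentClassifier"]


def _resolve_spec(architecture, input_channels, input_size, n_classes, padding):
    if isinstance(architecture, NetworkSpec):
        return architecture
    if architecture == "mnist":
        return mnist_net_spec(input_channels, input_size, n_classes, padding)
    if architecture == "cifar":
        return cifar_net_spec(input_channels, input_size, n_classes, padding)
    raise ValueError(
        f"architecture must be 'mnist', 'cifar' or a NetworkSpec, got {architecture!r}"
    )


def _validate_images(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 4:
        raise ValueError(f"expected images of shape (N, C, H, W), got {X.shape}")
    return X


class ConvNetClassifier(ClassifierMixin, BaseEstimator):
    """Reference convolutional network trained with cross-entropy SGD.

    Parameters
    ----------
    architecture : {"mnist", "cifar"} or NetworkSpec
        The two-layer digit net or the three-block 32x32 net.
    input_channels : int, 1 or 3
        1 for the original (grayscale) modality, 3 for the new one.
    input_size : int
        Image side length (28 for the digit net, 32 for the CIFAR net).
    iterations, batch_size, learning_rate, momentum
        SGD settings; an iteration is one minibatch step.
    eval_every : int
        History checkpoint cadence in iterations.
    random_state : int
        Seeds both parameter initialization and the minibatch/dropout stream.

    Attributes
    ----------
    model_ : crossdistill.nn.Network
        The trained network.
    history_ : TrainingHistory
        Per-checkpoint accuracies and losses.
    classes_ : ndarray
        Class labels seen during fit.
    """

    def __init__(self, architecture="mnist", input_channels=1, input_size=28,
                 n_classes=10, padding="same", iterations=2000, batch_size=64,
                 learning_rate=0.01, momentum=0.0, eval_every=500, random_state=0):
        self.architecture = architecture
        self.input_channels = input_channels
        self.input_size = input_size
        self.n_classes = n_classes
        self.padding = padding
        self.iterations = iterations
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.eval_every = eval_every
        self.random_state = random_state

    def _seeds(self) -> tuple[int, int]:
        ss = np.random.SeedSequence(self.random_state)
        init, train = (int(s) % (2**31) for s in ss.generate_state(2))
        return init, train

    def _make_config(self, train_seed: int) -> TrainingConfig:
        return TrainingConfig(
            iterations=self.iterations,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            seed=train_seed,
            eval_every=self.eval_every,
        )

    def fit(self, X, y, eval_set=None):
        X = _validate_images(X)
        y = np.asarray(y, dtype=np.int64)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        spec = _resolve_spec(self.architecture, self.input_channels,
                             self.input_size, self.n_classes, self.padding)
        if X.shape[1] != spec.input_channels:
            raise ValueError(
                f"data has {X.shape[1]} channels, spec expects {spec.input_channels}"
            )
        init_seed, train_seed = self._seeds()
        self.spec_ = spec
        self.model_ = build_network(spec, seed=init_seed)
        eval_X = eval_y = None
        if eval_set is not None:
            eval_X, eval_y = _validate_images(eval_set[0]), np.asarray(eval_set[1])
        self.history_, _ = _fit_loop(
            self.model_, X, y, self._make_config(train_seed),
            eval_X=eval_X, eval_y=eval_y,
        )
        self.classes_ = np.arange(spec.n_classes)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        return predict_logits(self.model_, _validate_images(X))

    def predict_proba(self, X, temperature: float = 1.0) -> np.ndarray:
        return softened_probabilities(self.decision_function(X), temperature)

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X).argmax(axis=1)

    def score(self, X, y, sample_weight=None) -> float:
        self._check_fitted()
        return accuracy(self.model_, _validate_images(X), np.asarray(y))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")


class DistilledStudentClassifier(ConvNetClassifier):
    """Student network on the new modality supervised by a frozen teacher.

    ``fit`` consumes a paired-modality dataset — either a
    :class:`~crossdistill.data.DualModalityDataset` (then ``y=None``) or a
    ``(X_original, X_new)`` tuple with labels ``y``.  The teacher reads the
    original modality, the student the new one; the objective is
    ``alpha * L_D(T) + (1 - alpha) * L_S``.

    Additional parameters
    ---------------------
    teacher : fitted ConvNetClassifier or crossdistill.nn.Network
        Frozen original-modality network providing soft targets.
    alpha, temperature : float
        Mixing weight and softmax temperature (benchmark defaults 0.6, 8).
    alpha_schedule : None or (alpha_start, alpha_end)
        Linear annealing of alpha over the training iterations.
    selective : bool
        Gate the distillation term to teacher-correct examples after the
        bootstrap phase.
    bootstrap_fraction : float
        Fraction of training during which selectivity is disabled.
    student_loss_temperature_mode : {"paper_literal", "unit_temperature"}
        Temperature convention for the hard-label term.
    """

    def __init__(self, teacher=None, alpha=0.6, temperature=8.0,
                 alpha_schedule=None, selective=False, bootstrap_fraction=0.5,
                 student_loss_temperature_mode="paper_literal",
                 rescale_grad_t2=False,
                 architecture="mnist", input_channels=3, input_size=28,
                 n_classes=10, padding="same", iterations=2000, batch_size=64,
                 learning_rate=0.01, momentum=0.0, eval_every=500, random_state=0):
        super().__init__(
            architecture=architecture, input_channels=input_channels,
            input_size=input_size, n_classes=n_classes, padding=padding,
            iterations=iterations, batch_size=batch_size,
            learning_rate=learning_rate, momentum=momentum,
            eval_every=eval_every, random_state=random_state,
        )
        self.teacher = teacher
        self.alpha = alpha
        self.temperature = temperature
        self.alpha_schedule = alpha_schedule
        self.selective = selective
        self.bootstrap_fraction = bootstrap_fraction
        self.student_loss_temperature_mode = student_loss_temperature_mode
        self.rescale_grad_t2 = rescale_grad_t2

    def _teacher_network(self):
        if self.teacher is None:
            raise ValueError("a fitted teacher is required for distillation")
        if isinstance(self.teacher, ConvNetClassifier):
            self.teacher._check_fitted()
            return self.teacher.model_
        return self.teacher  # a bare Network

    def _distill_config(self) -> DistillationConfig:
        return DistillationConfig(
            alpha=self.alpha,
            temperature=self.temperature,
            selective=self.selective,
            bootstrap_fraction=self.bootstrap_fraction,
            student_loss_temperature_mode=self.student_loss_temperature_mode,
            rescale_grad_t2=self.rescale_grad_t2,
        )

    def fit(self, X, y=None, eval_set=None):
        if isinstance(X, DualModalityDataset):
            x_orig, x_new, y = X.original, X.new, X.labels
        else:
            x_orig, x_new = X
            if y is None:
                raise ValueError("labels are required when passing raw arrays")
        x_orig = _validate_images(x_orig)
        x_new = _validate_images(x_new)
        y = np.asarray(y, dtype=np.int64)
        if not len(x_orig) == len(x_new) == len(y):
            raise ValueError("paired modalities and labels must have equal length")

        teacher_net = self._teacher_network()
        spec = _resolve_spec(self.architecture, self.input_channels,
                             self.input_size, self.n_classes, self.padding)
        schedule = None
        if self.alpha_schedule is not None:
            a0, an = self.alpha_schedule
            schedule = AnnealingSchedule(a0, an, self.iterations)

        init_seed, train_seed = self._seeds()
        self.spec_ = spec
        self.model_ = build_network(spec, seed=init_seed)
        eval_X = eval_y = None
        if eval_set is not None:
            if isinstance(eval_set, DualModalityDataset):
                eval_X, eval_y = eval_set.new, eval_set.labels
            else:
                eval_X, eval_y = _validate_images(eval_set[0]), np.asarray(eval_set[1])
        self.history_, _ = _fit_loop(
            self.model_, x_new, y, self._make_config(train_seed),
            teacher=teacher_net, X_teacher=x_orig,
            distill=self._distill_config(), schedule=schedule,
            eval_X=eval_X, eval_y=eval_y,
        )
        self.classes_ = np.arange(spec.n_classes)
        self.n_features_in_ = int(np.prod(np.asarray(x_new).shape[1:]))
        return self
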