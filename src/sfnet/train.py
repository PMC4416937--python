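"""SFN trainers: per-epoch backpropagation and batch Levenberg-Marquardt.

Backpropagation presents one epoch at a time and takes a gradient step
of size ``mu`` after each presentation.  Levenberg-Marquardt presents
the whole training set, stacks the per-output residuals ``e = D - phi``
(epoch-major, output-minor) and their Jacobian ``J`` (rows = error
components, columns = flat weights), and updates

    q  <-  q - (J'J + mu I)^-1 J'e

dividing the damping ``mu`` by ``beta`` after an error decrease and, on
an increase, multiplying by ``beta`` and reverting the weights to the
last accepted state.  Small ``mu`` makes the step Gauss-Newton; large
``mu`` turns it into a short steepest-descent step since ``J'e`` is the
error gradient.

The stopping statistic for both trainers is the *mean per-epoch* error
``(1/K) sum_k E_k`` so the threshold ``emin`` is independent of the
training-set size.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .epochs import EpochSet
from .model import (
    SFNModel,
    epoch_error,
    forward,
    gradients,
    residual_jacobian_rows,
    target_vector,
)

__all__ = ["TrainConfig", "TrainingTrace", "train_bp", "train_lm", "mean_error"]


@dataclasses.dataclass
class TrainConfig:
    """Trainer hyperparameters.

    ``mu`` is the backprop learning rate; ``mu0``/``beta`` the initial
    Levenberg-Marquardt damping and its multiplier.  ``maxitr`` caps
    epoch presentations for backprop and batch iterations for LM.
    """

    method: str = "lm"
    mu: float = 1e-3
    mu0: float = 100.0
    beta: float = 2.0
    emin: float = 1e-3
    maxitr: int = 1000
    seed: int | None = None
    shuffle: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("bp", "lm"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.mu < 0 or min(self.mu0, self.beta) <= 0:
            raise ValueError("mu must be >= 0; mu0 and beta must be positive")
        if self.maxitr < 1:
            raise ValueError("maxitr must be >= 1")


@dataclasses.dataclass
class TrainingTrace:
    """Per-iteration convergence audit record."""

    mean_errors: list[float] = dataclasses.field(default_factory=list)
    mus: list[float] = dataclasses.field(default_factory=list)
    reverted: list[bool] = dataclasses.field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def _targets(es: EpochSet, O: int) -> list[np.ndarray]:
    C = es.n_classes or int(es.labels.max())
    if O == 1 and C != 2:
        raise ValueError("single-output model requires a 2-class epoch set")
    if O > 1 and O != C:
        raise ValueError(f"model has {O} outputs but epoch set has {C} classes")
    n = 2 if O == 1 else C
    return [target_vector(int(lab), n) for lab in es.labels]


def mean_error(model: SFNModel, es: EpochSet) -> float:
    """Mean per-epoch squared error ``(1/K) sum_k E_k``."""
    D = _targets(es, model.O)
    total = 0.0
    for X, d in zip(es.epochs, D):
        E, _ = epoch_error(forward(model, X).phi, d)
        total += E
    return total / es.n_epochs


def train_bp(
    model: SFNModel, es: EpochSet, cfg: TrainConfig
) -> tuple[SFNModel, TrainingTrace]:
    """Stochastic gradient training, one weight update per epoch presentation.

    Epochs are presented sequentially (optionally shuffled per pass with
    the seeded generator); the trace records one mean error per full
    pass, and training stops when that mean reaches ``emin`` or
    ``maxitr`` presentations are exhausted.
    """
    if cfg.method != "bp":
        raise ValueError("config method must be 'bp'")
    es.validate_training()
    D = _targets(es, model.O)
    model = model.copy()
    rng = np.random.default_rng(cfg.seed)
    trace = TrainingTrace()
    K = es.n_epochs
    presentations = 0
    while presentations < cfg.maxitr:
        order = rng.permutation(K) if cfg.shuffle else np.arange(K)
        pass_err = 0.0
        seen = 0
        for k in order:
            X, d = es.epochs[k], D[k]
            rec = forward(model, X)
            E, _ = epoch_error(rec.phi, d)
            if not np.isfinite(E):
                raise FloatingPointError("non-finite training error; aborting")
            dW, dV, db = gradients(model, X, d, rec)
            model.W -= cfg.mu * dW
            model.V -= cfg.mu * dV
            model.b -= cfg.mu * db
            pass_err += E
            seen += 1
            presentations += 1
            if presentations >= cfg.maxitr:
                break
        trace.mean_errors.append(pass_err / seen)
        trace.mus.append(cfg.mu)
        trace.reverted.append(False)
        trace.iterations += 1
        if trace.mean_errors[-1] <= cfg.emin:
            trace.converged = True
            break
    return model, trace


def _lm_batch(model: SFNModel, es: EpochSet, D: list[np.ndarray]):
    """Residual vector, Jacobian and mean error for the whole training set."""
    K, O = es.n_epochs, model.O
    e = np.empty(K * O)
    J = np.empty((K * O, model.n_weights))
    total = 0.0
    for k, (X, d) in enumerate(zip(es.epochs, D)):
        rec = forward(model, X)
        Ek, ek = epoch_error(rec.phi, d)
        total += Ek
        e[k * O:(k + 1) * O] = ek
        J[k * O:(k + 1) * O] = residual_jacobian_rows(model, X, rec)
    if not np.isfinite(total) or not np.all(np.isfinite(J)):
        raise FloatingPointError("non-finite residuals or Jacobian; aborting")
    return e, J, total / K


def train_lm(
    model: SFNModel, es: EpochSet, cfg: TrainConfig
) -> tuple[SFNModel, TrainingTrace]:
    """Batch Levenberg-Marquardt with adaptive damping and revert-on-increase.

    Each iteration evaluates the full batch, accepts the step (halving
    the damping) if the mean error decreased, otherwise reverts to the
    last accepted weights and multiplies the damping by ``beta``; the
    next step is then solved from the accepted state.  The accepted
    error sequence is therefore non-increasing.
    """
    if cfg.method != "lm":
        raise ValueError("config method must be 'lm'")
    es.validate_training()
    D = _targets(es, model.O)
    model = model.copy()
    trace = TrainingTrace()
    mu = cfg.mu0
    q = model.pack()
    e_acc = J_acc = None
    E_acc = np.inf
    n = model.n_weights
    for _ in range(cfg.maxitr):
        candidate = model.unpack(q)
        e, J, E = _lm_batch(candidate, es, D)
        if E < E_acc:  # first iteration always accepts (E_acc = inf)
            q_acc, e_acc, J_acc, E_acc = q.copy(), e, J, E
            mu = mu / cfg.beta
            reverted = False
        else:
            q = q_acc.copy()
            mu = mu * cfg.beta
            reverted = True
        trace.mean_errors.append(E_acc)
        trace.mus.append(mu)
        trace.reverted.append(reverted)
        trace.iterations += 1
        if E_acc <= cfg.emin:
            trace.converged = True
            break
        A = J_acc.T @ J_acc + mu * np.eye(n)
        g = J_acc.T @ e_acc  # = dE/dq at the accepted point
        try:
            step = np.linalg.solve(A, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(A, g, rcond=None)[0]
        q = q_acc - step
    return model.unpack(q_acc), trace
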