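"""Evaluation metrics and repeated-run summaries.

Besides plain accuracy, the module computes the Fisher separation of a
feature set — the ratio of between-class to within-class scatter,
``tr(S_B) / tr(S_W)`` — which is the criterion jointly trained spatial
filters are expected to improve over CSP, and a repeated-run protocol
that retrains a model from several seeds and reports quartiles of the
test accuracies (random initialization makes single accuracies noisy).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .epochs import EpochSet
from .model import classify, forward, init_model
from .train import TrainConfig, train_bp, train_lm

__all__ = ["RunSummary", "accuracy", "fisher_separation", "repeated_runs",
           "sfn_features", "sfn_predict"]


def accuracy(pred, truth) -> float:
    """Fraction of exact label matches."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("prediction/truth length mismatch or empty")
    return float(np.mean(pred == truth))


def fisher_separation(features: np.ndarray, labels) -> float:
    """Trace ratio ``tr(S_B)/tr(S_W)`` of between- to within-class scatter.

    ``S_B`` is the count-weighted scatter of class means about the grand
    mean; ``S_W`` the pooled within-class scatter.  Translation
    invariant; invariant under uniform feature scaling.  Zero
    within-class scatter yields ``inf`` with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if any((y == c).sum() < 2 for c in classes):
        raise ValueError("need at least two epochs per class")
    grand = X.mean(axis=0)
    sb = sw = 0.0
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        sb += len(Xc) * float(np.sum((mu - grand) ** 2))
        sw += float(np.sum((Xc - mu) ** 2))
    if sw == 0.0:
        warnings.warn("zero within-class scatter: separation is infinite",
                      stacklevel=2)
        return float("inf")
    return sb / sw


def sfn_features(model, es: EpochSet) -> np.ndarray:
    """Log-variance feature vectors (layer-1 output) for every epoch."""
    return np.array([forward(model, X).f for X in es.epochs])


def sfn_predict(model, es: EpochSet) -> np.ndarray:
    """Class decisions for every epoch of ``es``."""
    return np.array([classify(forward(model, X).phi) for X in es.epochs])


@dataclasses.dataclass
class RunSummary:
    """Accuracies of repeated independently initialized training runs."""

    accuracies: list[float]
    quartiles: tuple[float, float, float]
    n_runs: int
    n_failures: int
    config: TrainConfig
    M: int
    seeds: list[int]


def repeated_runs(
    es_train: EpochSet,
    es_test: EpochSet,
    cfg: TrainConfig,
    M: int,
    seeds,
) -> RunSummary:
    """Train one model per seed and summarize test accuracies.

    A run whose training aborts (degenerate filter, non-finite error) is
    recorded as a failure, not fatal.  Quartiles use linear
    interpolation so summaries are bit-reproducible.
    """
    seeds = [int(s) for s in seeds]
    if not seeds:
        raise ValueError("need at least one seed")
    C = es_train.n_classes or int(es_train.labels.max())
    O = 1 if C == 2 else C
    trainer = train_bp if cfg.method == "bp" else train_lm
    accs: list[float] = []
    failures = 0
    for s in seeds:
        run_cfg = dataclasses.replace(cfg, seed=s)
        model0 = init_model(es_train.n_channels, M, O, seed=s)
        try:
            model, _ = trainer(model0, es_train, run_cfg)
            accs.append(accuracy(sfn_predict(model, es_test), es_test.labels))
        except (ValueError, FloatingPointError) as exc:
            warnings.warn(f"run with seed {s} aborted: {exc}", stacklevel=2)
            failures += 1
    if not accs:
        raise RuntimeError("every training run aborted")
    q = tuple(np.quantile(accs, [0.25, 0.5, 0.75], method="linear"))
    return RunSummary(
        accuracies=accs,
        quartiles=q,
        n_runs=len(seeds),
        n_failures=failures,
        config=cfg,
        M=M,
        seeds=seeds,
    )
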