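"""Synthetic epoch generator with class-specific covariance structure.

Each toy epoch is ``T`` i.i.d. draws from a zero-mean multivariate
Gaussian whose covariance is fixed per class; class labels are drawn
uniformly, so class counts are only approximately balanced.  This
emulates the situation spatial filtering exploits in motor imagery —
classes differing in the orientation and anisotropy of their spatial
covariance — while ignoring everything else about real EEG (spectral
content, non-stationarity, artifacts).

The two bundled presets use 2-channel epochs (``N=2, T=100, K=100``):

* ``two_class`` — two equally powered ellipses oriented at +-45 degrees
  (identical marginal channel variances, opposite channel correlation),
  so no single channel separates the classes but a rotated filter pair
  does.
* ``four_class`` — four ellipses differing in orientation and total
  power, separable in 2-D log-variance feature space.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .epochs import EpochSet

__all__ = ["ToySpec", "generate", "preset_two_class", "preset_four_class"]


def _rot(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


def _ellipse_cov(theta_deg: float, major: float, minor: float) -> np.ndarray:
    """SPD covariance with principal axes (major, minor) at angle theta."""
    R = _rot(theta_deg)
    return R @ np.diag([major, minor]) @ R.T


@dataclasses.dataclass
class ToySpec:
    """Generator parameters: one SPD covariance per class plus sizes."""

    covariances: list[np.ndarray]
    N: int = 2
    T: int = 100
    K: int = 100
    seed: int | None = None
    preset: str = "custom"

    def __post_init__(self) -> None:
        self.covariances = [np.asarray(S, dtype=float) for S in self.covariances]
        for c, S in enumerate(self.covariances, start=1):
            if S.shape != (self.N, self.N):
                raise ValueError(f"class {c} covariance is not {self.N}x{self.N}")
            if not np.allclose(S, S.T):
                raise ValueError(f"class {c} covariance is not symmetric")
            if np.linalg.eigvalsh(S)[0] <= 0:
                raise ValueError(f"class {c} covariance is not positive definite")

    @property
    def n_classes(self) -> int:
        return len(self.covariances)


def generate(spec: ToySpec) -> EpochSet:
    """Draw K epochs; labels uniform over classes, samples N(0, Sigma_label).

    The per-channel mean of every epoch is subtracted afterwards so the
    zero-mean invariant holds exactly, not just in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    labels = rng.integers(1, spec.n_classes + 1, size=spec.K)
    chols = [np.linalg.cholesky(S) for S in spec.covariances]
    epochs = []
    for lab in labels:
        X = chols[lab - 1] @ rng.standard_normal((spec.N, spec.T))
        X -= X.mean(axis=1, keepdims=True)
        epochs.append(X)
    return EpochSet(
        epochs=epochs,
        labels=labels,
        sample_rate=None,
        n_classes=spec.n_classes,
    )


def preset_two_class(seed: int | None = None) -> ToySpec:
    """Two classes: same per-channel variance, opposite +-45 deg orientation."""
    covs = [
        _ellipse_cov(45.0, 2.0, 0.2),
        _ellipse_cov(-45.0, 2.0, 0.2),
    ]
    return ToySpec(covariances=covs, N=2, T=100, K=100, seed=seed,
                   preset="two_class")


def preset_four_class(seed: int | None = None) -> ToySpec:
    """Four classes differing in principal-axis orientation and power."""
    covs = [
        _ellipse_cov(0.0, 4.0, 0.4),    # horizontal
        _ellipse_cov(90.0, 4.0, 0.4),   # vertical
        _ellipse_cov(45.0, 1.0, 0.1),   # oblique, low power
        _ellipse_cov(135.0, 10.0, 1.0), # oblique, high power
    ]
    return ToySpec(covariances=covs, N=2, T=100, K=100, seed=seed,
                   preset="four_class")
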