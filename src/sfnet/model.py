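"""The spatial filter network (SFN) model.

Two layers trained jointly.  Layer 1 projects an ``N x T`` zero-mean
epoch through ``M`` unit-norm spatial filters (the columns of ``W``
divided by their norms) and extracts log-variance band-power features::

    y_m(t) = (w_m / ||w_m||)' x(t)
    f_m    = log( (1/T) sum_t y_m(t)^2 )

Layer 2 is a linear classifier squashed by tanh::

    z = V' f + b,   Phi = tanh(z)  in (-1, 1)^O

Binary problems use a single output (``O = 1``) thresholded at 0;
multiclass uses one output per class with argmax.  Because each column
of ``W`` only enters through ``w_m / ||w_m||``, the network searches the
unit hypersphere: every quantity here is invariant to positive rescaling
of a filter column, and the error gradient is orthogonal to each
``w_m``.

This module provides the forward pass, the squared-error loss against
``+-1`` target vectors, analytic gradients for backpropagation, and the
per-output residual Jacobian rows used by Levenberg-Marquardt.  The
gradients are the package's most heavily tested code: they are checked
against central finite differences.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "SFNModel",
    "ForwardRecord",
    "init_model",
    "forward",
    "classify",
    "target_vector",
    "epoch_error",
    "gradients",
    "residual_jacobian_rows",
    "save_model",
    "load_model",
]

INIT_SIGMA = 0.1  # std of the Normal(0, sigma^2) weight initialization


@dataclasses.dataclass
class SFNModel:
    """Trainable state: spatial filters W (N x M), classifier V (M x O), bias b (O)."""

    W: np.ndarray
    V: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.V.shape[0] != self.M or self.b.shape[0] != self.O:
            raise ValueError(
                f"inconsistent shapes: W {self.W.shape}, V {self.V.shape}, "
                f"b {self.b.shape}"
            )

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def M(self) -> int:
        return self.W.shape[1]

    @property
    def O(self) -> int:
        return self.V.shape[1]

    @property
    def n_weights(self) -> int:
        return self.N * self.M + self.O * (self.M + 1)

    # -- flat weight vector (frozen ordering: W row-major, V row-major, b) --
    def pack(self) -> np.ndarray:
        return np.concatenate([self.W.ravel(), self.V.ravel(), self.b])

    def unpack(self, q: np.ndarray) -> "SFNModel":
        q = np.asarray(q, dtype=float)
        if q.shape != (self.n_weights,):
            raise ValueError(f"expected {self.n_weights} weights, got {q.shape}")
        nw = self.N * self.M
        nv = self.M * self.O
        return SFNModel(
            W=q[:nw].reshape(self.N, self.M).copy(),
            V=q[nw:nw + nv].reshape(self.M, self.O).copy(),
            b=q[nw + nv:].copy(),
        )

    def copy(self) -> "SFNModel":
        return SFNModel(W=self.W.copy(), V=self.V.copy(), b=self.b.copy())


@dataclasses.dataclass
class ForwardRecord:
    """Intermediate quantities of one forward pass, kept for backprop."""

    y: np.ndarray      # M x T normalized spatially filtered signal
    f: np.ndarray      # M log-variance features
    z: np.ndarray      # O pre-activations
    phi: np.ndarray    # O outputs in (-1, 1)
    var: np.ndarray    # M per-filter signal powers (1/T convention)
    norms: np.ndarray  # M column norms of W


def init_model(N: int, M: int, O: int, seed=None) -> SFNModel:
    """Random model with all weights i.i.d. Normal(0, 0.1^2)."""
    if min(N, M, O) < 1:
        raise ValueError("N, M, O must all be >= 1")
    rng = np.random.default_rng(seed)
    return SFNModel(
        W=rng.normal(0.0, INIT_SIGMA, (N, M)),
        V=rng.normal(0.0, INIT_SIGMA, (M, O)),
        b=rng.normal(0.0, INIT_SIGMA, O),
    )


def forward(model: SFNModel, X: np.ndarray) -> ForwardRecord:
    """Forward pass on one zero-mean epoch ``X`` (N x T)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != model.N:
        raise ValueError(f"epoch has {X.shape[0]} channels, model expects {model.N}")
    T = X.shape[1]
    norms = np.linalg.norm(model.W, axis=0)
    if np.any(norms <= 1e-12):
        raise ValueError("zero-norm spatial filter column")
    y = (model.W / norms).T @ X  # M x T
    var = np.sum(y * y, axis=1) / T  # mu_y = 0 since X is zero mean
    if np.any(var <= 0):
        raise ValueError("zero-variance projection: collapsed spatial filter")
    f = np.log(var)
    z = model.V.T @ f + model.b
    phi = np.tanh(z)
    return ForwardRecord(y=y, f=f, z=z, phi=phi, var=var, norms=norms)


def classify(phi: np.ndarray) -> int:
    """Class decision from the output vector.

    One output: class 1 if ``phi > 0`` else class 2 (tanh threshold 0).
    Several outputs: argmax, ties to the lowest class index.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if phi.shape[0] == 1:
        return 1 if phi[0] > 0 else 2
    return int(np.argmax(phi)) + 1


def target_vector(label: int, n_classes: int) -> np.ndarray:
    """Target D: scalar +-1 for binary, one-versus-rest +-1 vector otherwise."""
    if not 1 <= label <= n_classes:
        raise ValueError(f"label {label} outside 1..{n_classes}")
    if n_classes == 2:
        return np.array([1.0 if label == 1 else -1.0])
    D = -np.ones(n_classes)
    D[label - 1] = 1.0
    return D


def epoch_error(phi: np.ndarray, D: np.ndarray) -> tuple[float, np.ndarray]:
    """Squared-error loss ``E = 1/2 sum_o (phi_o - D_o)^2`` and residuals ``e = D - phi``."""
    phi = np.asarray(phi, dtype=float)
    D = np.asarray(D, dtype=float)
    if phi.shape != D.shape:
        raise ValueError("output/target dimension mismatch")
    e = D - phi
    return 0.5 * float(e @ e), e


def _filter_direction_terms(model: SFNModel, X: np.ndarray, rec: ForwardRecord):
    """d f_m / d W[:, m] as columns of an N x M matrix.

    Chains (2/T) y_m(t)/var_m through
    d y_m(t)/d W_nm = (||w_m|| x_n(t) - W_nm y_m(t)) / ||w_m||^2.
    """
    T = X.shape[1]
    Xy = X @ rec.y.T  # N x M, column m = sum_t x(t) y_m(t)
    # sum_t y_m(t)^2 = T var_m
    dfdW = (2.0 / (T * rec.var)) * (
        Xy / rec.norms - model.W * (T * rec.var) / rec.norms**2
    )
    return dfdW  # N x M


def gradients(
    model: SFNModel, X: np.ndarray, D: np.ndarray, rec: ForwardRecord
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the epoch error w.r.t. W, V and b.

    The W-gradient sums the error of every output over all samples; by
    the unit-norm construction it is orthogonal to each filter column
    (rescaling a column is a flat direction).
    """
    delta = (rec.phi - np.asarray(D, dtype=float)) * (1.0 - rec.phi**2)  # O
    dV = np.outer(rec.f, delta)  # M x O
    db = delta.copy()
    g = model.V @ delta  # M, = sum_o delta_o V_mo
    dW = _filter_direction_terms(model, X, rec) * g  # N x M
    return dW, dV, db


def residual_jacobian_rows(
    model: SFNModel, X: np.ndarray, rec: ForwardRecord
) -> np.ndarray:
    """O rows of ``d e_o / d q`` for one epoch, in flat-weight order.

    ``e_o = D_o - phi_o`` so ``d e_o/d phi_o = -1``; the V/b blocks of
    row o are zero outside column o's weights.  Stacking the rows of all
    epochs (epoch-major, output-minor) gives the Levenberg-Marquardt
    Jacobian J with ``sum`` identity ``J' e = dE/dq``.
    """
    O, M, N = model.O, model.M, model.N
    s = -(1.0 - rec.phi**2)  # d e_o / d z_o
    dfdW = _filter_direction_terms(model, X, rec)  # N x M
    rows = np.zeros((O, model.n_weights))
    nw = N * M
    for o in range(O):
        # W block: s_o * V_mo * df_m/dW_nm
        rows[o, :nw] = (dfdW * (s[o] * model.V[:, o])).ravel()
        # V block (row-major M x O): only column o nonzero
        Vblock = np.zeros((M, O))
        Vblock[:, o] = s[o] * rec.f
        rows[o, nw:nw + M * O] = Vblock.ravel()
        rows[o, nw + M * O + o] = s[o]
    return rows


# -- plain-text model serialization -----------------------------------------

def save_model(model: SFNModel, path) -> None:
    """Deterministic delimited-text serialization (header then W, V, b)."""
    with open(path, "w") as fh:
        fh.write(f"# sfn model\nN={model.N}\nM={model.M}\nO={model.O}\n")
        for name, arr in (("W", model.W), ("V", model.V), ("b", model.b.reshape(1, -1))):
            fh.write(f"[{name}]\n")
            for row in np.atleast_2d(arr):
                fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def load_model(path) -> SFNModel:
    text = Path(path).read_text().splitlines()
    header = {}
    blocks: dict[str, list[list[float]]] = {}
    current = None
    for ln in text:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if ln.startswith("[") and ln.endswith("]"):
            current = ln[1:-1]
            blocks[current] = []
        elif current is None:
            k, v = ln.split("=")
            header[k] = int(v)
        else:
            blocks[current].append([float(x) for x in ln.split("\t")])
    return SFNModel(
        W=np.array(blocks["W"]),
        V=np.array(blocks["V"]),
        b=np.array(blocks["b"]).ravel(),
    )
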