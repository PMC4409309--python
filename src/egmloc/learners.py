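"""From-scratch learning machines: MLP, RBFNN, PNN, SVM, and KRR.

All five machines are implemented here rather than delegated to an ML
library, with the contracts the rest of the package relies on:

* MLP — one sigmoidal hidden layer, linear outputs, sum-of-squared-error
  loss minimized by conjugate gradients; seeded random initialization.
* RBFNN — a Gaussian unit on every training instance; output weights from
  the (regularized) least-squares solution via pseudoinverse.
* PNN — class-conditional Parzen density sums with Gaussian kernels; the
  class score is normalized by the class size so scores estimate
  densities (disable with ``class_size_norm=False``).
* SVM — soft-margin binary classifier solved by SMO-style coordinate
  ascent to a KKT tolerance of 1e-4; Gaussian or polynomial kernel;
  one-vs-rest for more than two classes.
* KRR — multi-output kernel ridge regression, dual coefficients from
  (K + lambda I) A = Y.

Hyperparameter grids follow the published search ranges (see
:func:`build_grid`); ``sigma_hat`` is the mean pairwise distance between
training instances, used to scale the KRR kernel-width grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "HyperGrid",
    "TrainedModel",
    "gaussian_kernel",
    "polynomial_kernel",
    "mlp_fit",
    "mlp_predict",
    "rbfnn_fit",
    "rbfnn_predict",
    "pnn_fit",
    "pnn_predict",
    "pnn_scores",
    "svm_fit",
    "svm_predict",
    "svm_decision",
    "svm_dual_objective",
    "multiclass_ovr",
    "krr_fit",
    "krr_predict",
    "sigma_hat",
    "build_grid",
    "one_hot",
    "fit_any",
    "predict_any",
    "LEARNER_KINDS",
]

LEARNER_KINDS = ("mlp", "rbfnn", "pnn", "svm-gk", "svm-pk", "krr")


# ---------------------------------------------------------------------------
# kernels and shared plumbing

def gaussian_kernel(X: np.ndarray, Z: np.ndarray, width: float) -> np.ndarray:
    """Gaussian kernel exp(-||x - z||^2 / (2 width^2))."""
    if width <= 0:
        raise ValueError("kernel width must be positive")
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(Z), "sqeuclidean")
    return np.exp(-d2 / (2.0 * width**2))


def polynomial_kernel(X: np.ndarray, Z: np.ndarray, degree: int) -> np.ndarray:
    """Polynomial kernel (1 + <x, z>)^degree."""
    if degree < 1 or degree != int(degree):
        raise ValueError("polynomial degree must be a positive integer")
    return (1.0 + np.atleast_2d(X) @ np.atleast_2d(Z).T) ** int(degree)


@dataclass
class TrainedModel:
    """Fitted learner: kind, opaque payload, and input/output contracts."""

    kind: str
    payload: dict
    n_features: int
    classes: np.ndarray | None = None
    out_dim: int | None = None
    feature_set: str | None = None
    converged: bool = True

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"input has {X.shape[1]} features, model was trained on {self.n_features}"
            )
        return X


def one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Targets as one-hot rows in the order of ``classes``."""
    y = np.asarray(y)
    T = np.zeros((y.size, classes.size))
    for j, c in enumerate(classes):
        T[y == c, j] = 1.0
    if not np.allclose(T.sum(axis=1), 1.0):
        raise ValueError("labels outside the declared class set")
    return T


def _classes_of(y: np.ndarray) -> np.ndarray:
    classes = np.unique(np.asarray(y))
    if classes.size < 1:
        raise ValueError("empty label vector")
    return classes


# ---------------------------------------------------------------------------
# MLP

def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def mlp_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    seed: int = 0,
    max_iter: int = 400,
) -> TrainedModel:
    """Train a one-hidden-layer MLP by conjugate-gradient SSE minimization.

    Hidden activations are sigmoidal, outputs linear; the loss is half the
    sum of squared errors against one-hot targets. Initial weights are
    drawn from the seeded generator. If the optimizer stops before
    convergence the best-so-far weights are kept and ``converged`` is
    False.
    """
    from scipy.optimize import minimize

    if n_hidden < 1:
        raise ValueError("the hidden layer needs at least one unit")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    classes = _classes_of(y)
    T = one_hot(y, classes)
    n, d = X.shape
    c = classes.size
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0.0, 1.0 / np.sqrt(d + 1), (d + 1, n_hidden))
    W2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden + 1), (n_hidden + 1, c))
    Xb = np.hstack([X, np.ones((n, 1))])
    n1 = W1.size

    def unpack(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return w[:n1].reshape(d + 1, n_hidden), w[n1:].reshape(n_hidden + 1, c)

    def loss_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        W1_, W2_ = unpack(w)
        H = _sigmoid(Xb @ W1_)
        Hb = np.hstack([H, np.ones((n, 1))])
        E = Hb @ W2_ - T
        loss = 0.5 * float(np.sum(E * E))
        gW2 = Hb.T @ E
        dH = (E @ W2_[:-1].T) * H * (1.0 - H)
        gW1 = Xb.T @ dH
        return loss, np.concatenate([gW1.ravel(), gW2.ravel()])

    w0 = np.concatenate([W1.ravel(), W2.ravel()])
    res = minimize(loss_grad, w0, jac=True, method="CG", options={"maxiter": max_iter})
    W1f, W2f = unpack(res.x)
    return TrainedModel(
        kind="mlp",
        payload={"W1": W1f, "W2": W2f},
        n_features=d,
        classes=classes,
        converged=bool(res.success),
    )


def _mlp_outputs(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = model._check_input(X)
    Xb = np.hstack([X, np.ones((X.shape[0], 1))])
    H = _sigmoid(Xb @ model.payload["W1"])
    Hb = np.hstack([H, np.ones((H.shape[0], 1))])
    return Hb @ model.payload["W2"]


def mlp_predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    return model.classes[np.argmax(_mlp_outputs(model, X), axis=1)]


# ---------------------------------------------------------------------------
# RBFNN

def rbfnn_fit(
    X: np.ndarray, y: np.ndarray, width: float, regularization: float = 0.0
) -> TrainedModel:
    """Exact/regularized RBF network: one Gaussian unit per training point.

    Output weights solve the (ridge-)least-squares system; with zero
    regularization the Moore–Penrose pseudoinverse is used, giving exact
    interpolation on distinct inputs.
    """
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    classes = _classes_of(y)
    T = one_hot(y, classes)
    Phi = gaussian_kernel(X, X, width)
    if regularization == 0.0:
        W = np.linalg.pinv(Phi) @ T
    else:
        A = Phi.T @ Phi + regularization * np.eye(X.shape[0])
        W = np.linalg.solve(A, Phi.T @ T)
    return TrainedModel(
        kind="rbfnn",
        payload={"centers": X.copy(), "W": W, "width": float(width)},
        n_features=X.shape[1],
        classes=classes,
    )


def _rbfnn_outputs(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = model._check_input(X)
    Phi = gaussian_kernel(X, model.payload["centers"], model.payload["width"])
    return Phi @ model.payload["W"]


def rbfnn_predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    return model.classes[np.argmax(_rbfnn_outputs(model, X), axis=1)]


# ---------------------------------------------------------------------------
# PNN

def pnn_fit(
    X: np.ndarray, y: np.ndarray, width: float, class_size_norm: bool = True
) -> TrainedModel:
    """Probabilistic neural network (class-conditional Parzen windows)."""
    if width <= 0:
        raise ValueError("kernel width must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = _classes_of(y)
    if classes.size < 2:
        raise ValueError("PNN needs at least two non-empty classes")
    return TrainedModel(
        kind="pnn",
        payload={
            "X": X.copy(),
            "y": y.copy(),
            "width": float(width),
            "class_size_norm": bool(class_size_norm),
        },
        n_features=X.shape[1],
        classes=classes,
    )


def pnn_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Per-class Parzen scores (density estimates up to a shared constant)."""
    X = model._check_input(X)
    K = gaussian_kernel(X, model.payload["X"], model.payload["width"])
    ytr = model.payload["y"]
    scores = np.empty((X.shape[0], model.classes.size))
    for j, c in enumerate(model.classes):
        mask = ytr == c
        s = K[:, mask].sum(axis=1)
        if model.payload["class_size_norm"]:
            s = s / mask.sum()
        scores[:, j] = s
    return scores


def pnn_predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    # log-domain computation: at small widths the raw kernel sums underflow
    # for queries far from every training point, which would collapse the
    # argmax; shifting by the per-query minimum distance leaves it invariant
    X = model._check_input(X)
    w = model.payload["width"]
    d2 = cdist(X, model.payload["X"], "sqeuclidean") / (2.0 * w**2)
    d2 = d2 - d2.min(axis=1, keepdims=True)
    K = np.exp(-d2)
    ytr = model.payload["y"]
    scores = np.empty((X.shape[0], model.classes.size))
    for j, c in enumerate(model.classes):
        mask = ytr == c
        s = K[:, mask].sum(axis=1)
        if model.payload["class_size_norm"]:
            s = s / mask.sum()
        scores[:, j] = s
    # argmax resolves ties to the lowest class index
    return model.classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# SVM (SMO)

def _svm_kernel(kind: str, X: np.ndarray, Z: np.ndarray, hyper: dict) -> np.ndarray:
    if kind == "gk":
        return gaussian_kernel(X, Z, hyper["width"])
    if kind == "pk":
        return polynomial_kernel(X, Z, hyper["degree"])
    raise ValueError(f"unknown SVM kernel {kind!r}")


def _smo(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float,
    max_epochs: int,
    seed: int,
) -> tuple[np.ndarray, float, bool]:
    """Platt-style sequential minimal optimization of the soft-margin dual."""
    n = y.size
    alpha = np.zeros(n)
    b = 0.0
    E = -y.astype(float)  # f(x) - y with alpha = 0, b = 0
    rng = np.random.default_rng(seed)
    eps = 1e-12

    def take_step(i1: int, i2: int) -> int:
        nonlocal b, E
        if i1 == i2:
            return 0
        a1o, a2o = alpha[i1], alpha[i2]
        y1, y2 = y[i1], y[i2]
        E1, E2 = E[i1], E[i2]
        s = y1 * y2
        if s < 0:
            L, H = max(0.0, a2o - a1o), min(C, C + a2o - a1o)
        else:
            L, H = max(0.0, a1o + a2o - C), min(C, a1o + a2o)
        if H - L < eps:
            return 0
        k11, k12, k22 = K[i1, i1], K[i1, i2], K[i2, i2]
        eta = k11 + k22 - 2.0 * k12
        if eta > eps:
            a2 = a2o + y2 * (E1 - E2) / eta
            a2 = min(max(a2, L), H)
        else:
            # objective at the two clip bounds (degenerate-curvature branch)
            f1 = y1 * (E1 - b) - a1o * k11 - s * a2o * k12
            f2 = y2 * (E2 - b) - s * a1o * k12 - a2o * k22
            L1 = a1o + s * (a2o - L)
            H1 = a1o + s * (a2o - H)
            psiL = L1 * f1 + L * f2 + 0.5 * L1 * L1 * k11 + 0.5 * L * L * k22 + s * L * L1 * k12
            psiH = H1 * f1 + H * f2 + 0.5 * H1 * H1 * k11 + 0.5 * H * H * k22 + s * H * H1 * k12
            if psiL < psiH - eps:
                a2 = L
            elif psiL > psiH + eps:
                a2 = H
            else:
                return 0
        if abs(a2 - a2o) < eps * (a2 + a2o + eps):
            return 0
        a1 = a1o + s * (a2o - a2)
        # bias making f(x1)=y1 (resp. f(x2)=y2) under f(x) = sum a y K + b
        b1 = b - (E1 + y1 * (a1 - a1o) * k11 + y2 * (a2 - a2o) * k12)
        b2 = b - (E2 + y1 * (a1 - a1o) * k12 + y2 * (a2 - a2o) * k22)
        if 0 < a1 < C:
            b_new = b1
        elif 0 < a2 < C:
            b_new = b2
        else:
            b_new = 0.5 * (b1 + b2)
        E += y1 * (a1 - a1o) * K[i1] + y2 * (a2 - a2o) * K[i2] + (b_new - b)
        alpha[i1], alpha[i2] = a1, a2
        b = b_new
        return 1

    def examine(i2: int) -> int:
        y2, a2, E2 = y[i2], alpha[i2], E[i2]
        r2 = E2 * y2
        if not ((r2 < -tol and a2 < C) or (r2 > tol and a2 > 0)):
            return 0
        nonbound = np.flatnonzero((alpha > eps) & (alpha < C - eps))
        if nonbound.size > 1:
            i1 = int(nonbound[np.argmax(np.abs(E[nonbound] - E2))])
            if take_step(i1, i2):
                return 1
        if nonbound.size:
            start = int(rng.integers(nonbound.size))
            for k in range(nonbound.size):
                if take_step(int(nonbound[(k + start) % nonbound.size]), i2):
                    return 1
        start = int(rng.integers(n))
        for k in range(n):
            if take_step((k + start) % n, i2):
                return 1
        return 0

    examine_all = True
    converged = False
    for _ in range(max_epochs):
        num_changed = 0
        idxs = (
            range(n)
            if examine_all
            else np.flatnonzero((alpha > eps) & (alpha < C - eps))
        )
        for i2 in idxs:
            num_changed += examine(int(i2))
        if examine_all:
            if num_changed == 0:
                converged = True
                break
            examine_all = False
        elif num_changed == 0:
            examine_all = True
    return alpha, b, converged


def svm_fit(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    kernel: str = "gk",
    width: float | None = None,
    degree: int | None = None,
    tol: float = 1e-4,
    max_epochs: int = 200,
    seed: int = 0,
) -> TrainedModel:
    """Soft-margin binary SVM via SMO.

    ``y`` may be ±1 or any two labels (the sorted first label maps to -1).
    ``kernel`` is ``"gk"`` (Gaussian, needs ``width``) or ``"pk"``
    (polynomial, needs ``degree``).
    """
    if C <= 0:
        raise ValueError("C must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    classes = _classes_of(y)
    if classes.size != 2:
        raise ValueError("binary SVM needs exactly two classes in the training data")
    ypm = np.where(np.asarray(y) == classes[0], -1.0, 1.0)
    hyper = {"width": width, "degree": degree}
    K = _svm_kernel(kernel, X, X, hyper)
    alpha, b, converged = _smo(K, ypm, float(C), tol, max_epochs, seed)
    sv = alpha > 1e-10
    return TrainedModel(
        kind=f"svm-{kernel}",
        payload={
            "X_sv": X[sv],
            "alpha_y": (alpha * ypm)[sv],
            "alpha": alpha,
            "y_pm": ypm,
            "b": b,
            "C": float(C),
            "kernel": kernel,
            "hyper": hyper,
        },
        n_features=X.shape[1],
        classes=classes,
        converged=converged,
    )


def svm_decision(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = model._check_input(X)
    p = model.payload
    if p["X_sv"].shape[0] == 0:
        return np.full(X.shape[0], p["b"])
    K = _svm_kernel(p["kernel"], X, p["X_sv"], p["hyper"])
    return K @ p["alpha_y"] + p["b"]


def svm_predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    f = svm_decision(model, X)
    return np.where(f < 0, model.classes[0], model.classes[1])


def svm_dual_objective(model: TrainedModel, X: np.ndarray) -> float:
    """Dual objective sum(alpha) - 1/2 a^T (yy^T * K) a on the training set."""
    p = model.payload
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = _svm_kernel(p["kernel"], X, X, p["hyper"])
    ay = p["alpha"] * p["y_pm"]
    return float(p["alpha"].sum() - 0.5 * ay @ K @ ay)


def multiclass_ovr(binary_factory, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """One-vs-rest multiclass wrapper over a binary learner factory.

    ``binary_factory(X, y_pm)`` must return a model whose decision values
    come from :func:`svm_decision`-compatible payloads, or any object with
    a ``decision(X)`` callable stored under ``payload["decision"]``.
    Prediction is the argmax of the per-class decision values; ties go to
    the lowest class index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    classes = _classes_of(y)
    if classes.size < 2:
        raise ValueError("one-vs-rest needs at least two classes")
    machines = []
    for c in classes:
        ypm = np.where(np.asarray(y) == c, 1.0, -1.0)
        machines.append(binary_factory(X, ypm))
    return TrainedModel(
        kind="ovr",
        payload={"machines": machines},
        n_features=X.shape[1],
        classes=classes,
    )


def ovr_predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = model._check_input(X)
    scores = np.column_stack(
        [svm_decision(m, X) for m in model.payload["machines"]]
    )
    return model.classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# KRR

def krr_fit(
    X: np.ndarray,
    Y: np.ndarray,
    regularization: float,
    width: float | None = None,
    kernel: str = "gk",
) -> TrainedModel:
    """Multi-output kernel ridge regression: (K + lambda I) A = Y.

    ``kernel`` is ``"gk"`` (Gaussian, the default) or ``"linear"`` (plain
    dot product, equivalent to intercept-free linear ridge regression).
    """
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y row counts differ")
    if kernel == "gk":
        K = gaussian_kernel(X, X, width)
    elif kernel == "linear":
        K = X @ X.T
    else:
        raise ValueError(f"unknown KRR kernel {kernel!r}")
    M = K + regularization * np.eye(X.shape[0])
    try:
        A = np.linalg.solve(M, Y)
    except np.linalg.LinAlgError:
        if regularization == 0.0:
            raise np.linalg.LinAlgError(
                "singular kernel system at zero regularization (duplicate inputs?)"
            )
        raise
    return TrainedModel(
        kind="krr",
        payload={
            "X": X.copy(),
            "A": A,
            "width": width,
            "kernel": kernel,
            "squeeze": squeeze,
        },
        n_features=X.shape[1],
        out_dim=Y.shape[1],
    )


def krr_predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = model._check_input(X)
    p = model.payload
    if p["kernel"] == "gk":
        K = gaussian_kernel(X, p["X"], p["width"])
    else:
        K = X @ p["X"].T
    out = K @ p["A"]
    return out[:, 0] if p["squeeze"] else out


# ---------------------------------------------------------------------------
# grids

def sigma_hat(X: np.ndarray) -> float:
    """Mean Euclidean distance over all unordered pairs of instances."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("sigma_hat needs at least two instances")
    return float(pdist(X).mean())


@dataclass(frozen=True)
class HyperGrid:
    """Named hyperparameter value lists for one learner kind.

    ``points()`` enumerates the Cartesian product in documented order
    (parameters in insertion order, last parameter fastest).
    """

    kind: str
    params: dict = field(default_factory=dict)

    def points(self) -> list[dict]:
        names = list(self.params)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.params[n] for n in names))
        ]


def build_grid(kind: str, sigma: float | None = None) -> HyperGrid:
    """The published hyperparameter search grid for one learner kind.

    The RBFNN grids are linearly spaced (the source states logarithmic
    spacing only for SVM and KRR); the KRR width grid is scaled by the
    mean pairwise training distance ``sigma``.
    """
    if kind == "mlp":
        return HyperGrid("mlp", {"n_hidden": list(range(1, 11))})
    if kind == "rbfnn":
        vals = list(np.linspace(1e-3, 1e2, 10))
        return HyperGrid("rbfnn", {"regularization": vals, "width": list(vals)})
    if kind == "pnn":
        return HyperGrid("pnn", {"width": list(np.linspace(0.1, 1.0, 10))})
    if kind == "svm-gk":
        return HyperGrid(
            "svm-gk",
            {
                "C": list(np.logspace(1, 3, 10)),
                "width": list(np.logspace(-2, 1, 20)),
            },
        )
    if kind == "svm-pk":
        return HyperGrid(
            "svm-pk",
            {"C": list(np.logspace(1, 3, 10)), "degree": list(range(1, 11))},
        )
    if kind == "krr":
        if sigma is None or sigma <= 0:
            raise ValueError("the KRR grid needs sigma = mean pairwise distance")
        return HyperGrid(
            "krr",
            {
                "regularization": list(np.logspace(-3, 1, 50)),
                "width": list(np.logspace(np.log10(0.1 * sigma), np.log10(100 * sigma), 50)),
            },
        )
    raise ValueError(f"unknown learner kind {kind!r}")


# ---------------------------------------------------------------------------
# uniform dispatch

def fit_any(
    kind: str, X: np.ndarray, y: np.ndarray, hyper: dict, seed: int = 0
) -> TrainedModel:
    """Fit any learner kind with a hyperparameter dict.

    Classifier kinds take label vectors; ``krr`` takes numeric targets
    (1- or multi-column). SVMs with more than two classes are wrapped
    one-vs-rest automatically.
    """
    if kind == "mlp":
        return mlp_fit(X, y, n_hidden=int(hyper["n_hidden"]), seed=seed)
    if kind == "rbfnn":
        return rbfnn_fit(X, y, width=hyper["width"], regularization=hyper["regularization"])
    if kind == "pnn":
        return pnn_fit(X, y, width=hyper["width"])
    if kind in ("svm-gk", "svm-pk"):
        kern = "gk" if kind == "svm-gk" else "pk"
        kw = dict(C=hyper["C"], kernel=kern, seed=seed)
        if kern == "gk":
            kw["width"] = hyper["width"]
        else:
            kw["degree"] = int(hyper["degree"])
        classes = np.unique(np.asarray(y))
        if classes.size == 2:
            return svm_fit(X, y, **kw)
        return multiclass_ovr(lambda Xt, ypm: svm_fit(Xt, ypm, **kw), X, y)
    if kind == "krr":
        return krr_fit(X, y, regularization=hyper["regularization"], width=hyper["width"])
    raise ValueError(f"unknown learner kind {kind!r}")


def predict_any(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    return {
        "mlp": mlp_predict,
        "rbfnn": rbfnn_predict,
        "pnn": pnn_predict,
        "svm-gk": svm_predict,
        "svm-pk": svm_predict,
        "ovr": ovr_predict,
        "krr": krr_predict,
    }[model.kind](model, X)
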