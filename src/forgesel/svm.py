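"""Binary SVM trained by solving the dual problem directly.

The soft-margin dual

    min_a  1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j) - sum_i a_i
    s.t.   sum_i a_i y_i = 0,  0 <= a_i <= C

is solved by sequential minimal optimization with maximal-violating-pair
working-set selection (the classic decomposition scheme). The box constraint
C is a soft-margin extension of the hard-margin dual (a_i >= 0), which is
recovered as C -> infinity. The decision function is

    f(x) = sgn( sum_i a*_i y_i K(x_i, x) + b* ),    sgn(0) := +1.

Four kernels: linear x.z, polynomial (x.z + 1)^d, RBF exp(-||x-z||^2 / 2s^2)
and sigmoid tanh(k (x.z) + theta).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

KERNEL_KINDS = ("linear", "polynomial", "rbf", "sigmoid")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice and its scalars: polynomial order d, rbf radius sigma,
    sigmoid scale k and shift theta."""

    kind: str = "linear"
    degree: int = 3
    sigma: float = 1.0
    k_scale: float = 1.0
    theta: float = 0.0

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kernel kind must be one of {KERNEL_KINDS}")
        if self.kind == "rbf" and not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")


def kernel_matrix(X, Z, spec: KernelSpec) -> np.ndarray:
    """Gram matrix K[i, j] = K(X[i], Z[j]) under ``spec``."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    if X.shape[1] != Z.shape[1]:
        raise ValueError("feature width mismatch between inputs")
    dots = X @ Z.T
    if spec.kind == "linear":
        return dots
    if spec.kind == "polynomial":
        return (dots + 1.0) ** spec.degree
    if spec.kind == "rbf":
        sq = (
            (X * X).sum(axis=1)[:, None]
            + (Z * Z).sum(axis=1)[None, :]
            - 2.0 * dots
        )
        np.maximum(sq, 0.0, out=sq)
        return np.exp(-sq / (2.0 * spec.sigma**2))
    return np.tanh(spec.k_scale * dots + spec.theta)


def kernel_eval(x, z, spec: KernelSpec) -> float:
    """K(x, z) for two single vectors."""
    x = np.asarray(x, dtype=np.float64).ravel()
    z = np.asarray(z, dtype=np.float64).ravel()
    if x.shape != z.shape:
        raise ValueError("x and z must have the same length")
    return float(kernel_matrix(x[None, :], z[None, :], spec)[0, 0])


class SVMConvergenceError(RuntimeError):
    """Raised when SMO fails to reach the KKT tolerance within the iteration cap."""

    def __init__(self, message, n_iter, violation):
        super().__init__(message)
        self.n_iter = n_iter
        self.violation = violation


def _smo(Q, y, C, tol, max_iter):
    """Maximal-violating-pair SMO on the dual with Q[i,j] = y_i y_j K_ij.

    Returns (alpha, b, n_iter). Gradient g = Q a - 1 is maintained
    incrementally; the stopping rule is the standard KKT gap
    max_{I_up} -y g  -  min_{I_low} -y g <= tol.
    """
    n = len(y)
    alpha = np.zeros(n)
    g = -np.ones(n)  # Q @ alpha - 1 at alpha = 0
    yg = None
    tau = 1e-12

    for it in range(max_iter):
        yg = -y * g
        up = ((alpha < C - 1e-12) & (y > 0)) | ((alpha > 1e-12) & (y < 0))
        low = ((alpha < C - 1e-12) & (y < 0)) | ((alpha > 1e-12) & (y > 0))
        if not up.any() or not low.any():
            break
        i = np.flatnonzero(up)[np.argmax(yg[up])]
        j = np.flatnonzero(low)[np.argmin(yg[low])]
        m, M = yg[i], yg[j]
        if m - M <= tol:
            return alpha, _bias(alpha, y, g, C, m, M), it

        # analytic solve for the pair (i, j) along the equality constraint
        eta = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        eta = max(eta, tau)
        delta = (m - M) / eta  # step in the y-scaled coordinate
        # bounds on the step so both alphas remain in [0, C]
        if y[i] > 0:
            hi_i = C - alpha[i]
        else:
            hi_i = alpha[i]
        if y[j] > 0:
            hi_j = alpha[j]
        else:
            hi_j = C - alpha[j]
        step = min(delta, hi_i, hi_j)
        if step <= 0:
            return alpha, _bias(alpha, y, g, C, m, M), it
        da_i = y[i] * step
        da_j = -y[j] * step
        alpha[i] += da_i
        alpha[j] += da_j
        g += Q[:, i] * da_i + Q[:, j] * da_j
    else:
        yg = -y * g
        up = ((alpha < C - 1e-12) & (y > 0)) | ((alpha > 1e-12) & (y < 0))
        low = ((alpha < C - 1e-12) & (y < 0)) | ((alpha > 1e-12) & (y > 0))
        gap = float(yg[up].max() - yg[low].min()) if up.any() and low.any() else 0.0
        raise SVMConvergenceError(
            f"SMO did not converge in {max_iter} iterations (KKT gap {gap:.3e})",
            n_iter=max_iter,
            violation=gap,
        )
    return alpha, _bias(alpha, y, g, C, 0.0, 0.0), it  # pragma: no cover


def _bias(alpha, y, g, C, m, M):
    free = (alpha > 1e-12) & (alpha < C - 1e-12)
    yg = -y * g
    if free.any():
        return float(yg[free].mean())
    return float((m + M) / 2.0)


class KernelSVC(ClassifierMixin, BaseEstimator):
    """Support-vector classifier solving the kernel dual by SMO.

    Parameters mirror :class:`KernelSpec` plus the box constraint ``C``
    (default 1.0; hard margin as C grows large) and the KKT stopping
    tolerance ``tol``.
    """

    def __init__(
        self,
        kernel: str = "linear",
        degree: int = 3,
        sigma: float = 1.0,
        k_scale: float = 1.0,
        theta: float = 0.0,
        C: float = 1.0,
        tol: float = 1e-4,
        max_iter: int = 200_000,
    ):
        self.kernel = kernel
        self.degree = degree
        self.sigma = sigma
        self.k_scale = k_scale
        self.theta = theta
        self.C = C
        self.tol = tol
        self.max_iter = max_iter

    def _spec(self) -> KernelSpec:
        return KernelSpec(
            kind=self.kernel,
            degree=self.degree,
            sigma=self.sigma,
            k_scale=self.k_scale,
            theta=self.theta,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("both classes must be present")
        # map to {-1, +1}; classes_ sorted so classes_[1] is the positive class
        ypm = np.where(y == self.classes_[1], 1.0, -1.0)
        if self.C <= 0:
            raise ValueError("C must be positive")
        spec = self._spec()
        K = kernel_matrix(X, X, spec)
        Q = (ypm[:, None] * ypm[None, :]) * K
        alpha, b, n_iter = _smo(Q, ypm, self.C, self.tol, self.max_iter)

        sv = alpha > 1e-12
        self.support_ = np.flatnonzero(sv)
        self.support_vectors_ = X[sv]
        self.alpha_ = alpha[sv]
        self.sv_y_ = ypm[sv]
        self.dual_coef_ = self.alpha_ * self.sv_y_
        self.intercept_ = b
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        # dual objective at the solution, for oracle comparisons
        self.dual_objective_ = float(0.5 * alpha @ (Q @ alpha) - alpha.sum())
        self.equality_residual_ = float(np.dot(alpha, ypm))
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature width mismatch with the trained model")
        K = kernel_matrix(X, self.support_vectors_, self._spec())
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return self.classes_[(d >= 0).astype(int)]  # sign(0) -> positive class

    def export_json(self, path) -> None:
        payload = {
            "kernel": self._spec().__dict__,
            "C": self.C,
            "intercept": self.intercept_,
            "dual_coef": self.dual_coef_.tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "classes": self.classes_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def train_svm(X, y, spec: KernelSpec | None = None, C: float = 1.0, tol: float = 1e-4) -> KernelSVC:
    """Fit a KernelSVC from a KernelSpec; thin wrapper over the estimator."""
    spec = spec or KernelSpec()
    model = KernelSVC(
        kernel=spec.kind,
        degree=spec.degree,
        sigma=spec.sigma,
        k_scale=spec.k_scale,
        theta=spec.theta,
        C=C,
        tol=tol,
    )
    return model.fit(X, y)


def predict(model: KernelSVC, X):
    """Predicted labels and raw decision values (for ROC ranking)."""
    d = model.decision_function(X)
    return model.classes_[(d >= 0).astype(int)], d
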