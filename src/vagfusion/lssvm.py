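"""Least-squares support vector machine classifier.

The LS-SVM replaces the standard SVM's inequality constraints with equality
constraints, so training reduces to one dense linear (KKT) system

    [ 0    1^T      ] [ b     ]   [ 0 ]
    [ 1  Omega + I/g] [ alpha ] = [ y ]

with ``Omega_ij = K(x_i, x_j)`` the kernel Gram matrix, ``g`` the
regularization parameter ``gamma`` and ``y`` the ±1 labels. The decision
function is ``g(x) = sum_i alpha_i K(x_i, x) + b``; the bias row of the KKT
system forces ``sum_i alpha_i = 0``.

Published defaults for the VAG task: polynomial kernel of degree 2 with
intercept 1, ``gamma = 5``. Features are standardized to zero mean / unit
variance with statistics estimated on the training set and stored in the
results object (kernel machines on mixed-unit features require it; each
leave-one-out or bootstrap retraining re-estimates it).

The module follows the model/results idiom: construct :class:`Lssvm` from
data, call :meth:`Lssvm.fit`, use the returned :class:`LssvmResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "KernelSpec",
    "kernel_eval",
    "kernel_matrix",
    "Lssvm",
    "LssvmResults",
    "train_lssvm",
    "loo_evaluate",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    kinds: ``linear``; ``polynomial`` ``(u.v + intercept)^degree``;
    ``rbf`` ``exp(-|u-v|^2 / (2 width^2))``; ``sigmoid``
    ``tanh(slope u.v + intercept)``.
    """

    kind: str = "polynomial"
    degree: int = 2
    intercept: float = 1.0
    width: float = 1.0
    slope: float = 1.0

    def __post_init__(self):
        if self.kind not in ("linear", "polynomial", "rbf", "sigmoid"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.kind == "rbf" and not self.width > 0:
            raise ValueError("rbf width must be positive")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "degree": self.degree,
            "intercept": self.intercept,
            "width": self.width,
            "slope": self.slope,
        }


def kernel_matrix(spec: KernelSpec, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Kernel Gram block ``K[i, j] = k(a_i, b_j)``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    if spec.kind == "linear":
        return a @ b.T
    if spec.kind == "polynomial":
        return (a @ b.T + spec.intercept) ** spec.degree
    if spec.kind == "rbf":
        sq = (
            np.sum(a**2, axis=1)[:, None]
            + np.sum(b**2, axis=1)[None, :]
            - 2.0 * (a @ b.T)
        )
        return np.exp(-np.maximum(sq, 0.0) / (2.0 * spec.width**2))
    return np.tanh(spec.slope * (a @ b.T) + spec.intercept)


def kernel_eval(spec: KernelSpec, u: np.ndarray, v: np.ndarray) -> float:
    """Scalar kernel evaluation ``k(u, v)`` (symmetric in its arguments)."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(kernel_matrix(spec, u[None, :], v[None, :])[0, 0])


class Lssvm:
    """LS-SVM model specification bound to training data.

    Parameters
    ----------
    X : (n, d) array
        Training feature matrix.
    y : (n,) array of ±1
        Class labels (+1 = abnormal/diseased by package convention).
    kernel : KernelSpec
        Default: polynomial, degree 2, intercept 1.
    gamma : float
        Regularization parameter (default 5).
    standardize : bool
        Standardize features using training statistics (default True).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        kernel: KernelSpec | None = None,
        gamma: float = 5.0,
        standardize: bool = True,
    ):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y have different numbers of samples")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("labels must be ±1")
        if np.unique(y).size < 2:
            raise ValueError("training data must contain both classes")
        if not gamma > 0:
            raise ValueError("gamma must be positive")
        self.X = X
        self.y = y
        self.kernel = kernel or KernelSpec()
        self.gamma = float(gamma)
        self.standardize = standardize

    def fit(self) -> "LssvmResults":
        """Solve the KKT system and return the fitted results."""
        n = self.X.shape[0]
        if self.standardize:
            mean = self.X.mean(axis=0)
            sd = self.X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mean = np.zeros(self.X.shape[1])
            sd = np.ones(self.X.shape[1])
        Z = (self.X - mean) / sd
        omega = kernel_matrix(self.kernel, Z, Z)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = omega + np.eye(n) / self.gamma
        rhs = np.concatenate([[0.0], self.y])
        try:
            sol = linalg.solve(A, rhs)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular KKT system (condition number {np.linalg.cond(A):.3e})"
            ) from exc
        residual = float(
            np.linalg.norm(A @ sol - rhs) / np.linalg.norm(rhs)
        )
        if not np.isfinite(residual) or residual > 1e-6:
            raise np.linalg.LinAlgError(
                f"ill-conditioned KKT system: relative residual {residual:.3e}, "
                f"condition number {np.linalg.cond(A):.3e}"
            )
        return LssvmResults(
            model=self,
            bias=float(sol[0]),
            alpha=sol[1:],
            feature_mean=mean,
            feature_sd=sd,
            kkt_residual=residual,
        )


@dataclass
class LssvmResults:
    """Fitted LS-SVM: dual coefficients, bias and training diagnostics."""

    model: Lssvm = field(repr=False)
    bias: float
    alpha: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    kkt_residual: float

    def _standardized(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"expected {self.model.X.shape[1]} features, got {X.shape[1]}"
            )
        return (X - self.feature_mean) / self.feature_sd

    def decision_value(self, X: np.ndarray) -> np.ndarray | float:
        """Decision function ``g(x) = sum_i alpha_i K(x_i, x) + b``."""
        single = np.asarray(X).ndim == 1
        Z = self._standardized(X)
        Ztr = (self.model.X - self.feature_mean) / self.feature_sd
        g = kernel_matrix(self.model.kernel, Z, Ztr) @ self.alpha + self.bias
        return float(g[0]) if single else g

    def predict(self, X: np.ndarray) -> np.ndarray | int:
        """Class prediction ``sign(g)``; the tie ``g == 0`` maps to +1."""
        g = self.decision_value(X)
        if np.isscalar(g):
            return 1 if g >= 0 else -1
        return np.where(np.asarray(g) >= 0, 1, -1)

    def summary(self) -> str:
        k = self.model.kernel
        lines = [
            "LS-SVM classification results",
            "=" * 45,
            f"n obs:            {self.model.X.shape[0]}",
            f"n features:       {self.model.X.shape[1]}",
            f"kernel:           {k.kind} (degree={k.degree}, intercept={k.intercept})",
            f"gamma:            {self.model.gamma}",
            f"bias b:           {self.bias: .6g}",
            f"sum(alpha):       {float(np.sum(self.alpha)): .3e}",
            f"KKT residual:     {self.kkt_residual:.3e}",
            "=" * 45,
        ]
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        """Serialize the fitted classifier (kernel, gamma, standardization,
        dual coefficients and training data) to JSON."""
        payload = {
            "kernel": self.model.kernel.to_dict(),
            "gamma": self.model.gamma,
            "standardize": self.model.standardize,
            "bias": self.bias,
            "alpha": self.alpha.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "kkt_residual": self.kkt_residual,
            "X": self.model.X.tolist(),
            "y": self.model.y.tolist(),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LssvmResults":
        """Rebuild a fitted classifier from :meth:`to_json` output."""
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (TypeError, json.JSONDecodeError):
                with open(source) as fh:
                    payload = json.load(fh)
        model = Lssvm(
            np.array(payload["X"]),
            np.array(payload["y"]),
            kernel=KernelSpec(**payload["kernel"]),
            gamma=payload["gamma"],
            standardize=payload["standardize"],
        )
        return cls(
            model=model,
            bias=payload["bias"],
            alpha=np.array(payload["alpha"]),
            feature_mean=np.array(payload["feature_mean"]),
            feature_sd=np.array(payload["feature_sd"]),
            kkt_residual=payload["kkt_residual"],
        )


def train_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: KernelSpec | None = None,
    gamma: float = 5.0,
    standardize: bool = True,
) -> LssvmResults:
    """Functional wrapper: ``Lssvm(X, y, ...).fit()``."""
    return Lssvm(X, y, kernel=kernel, gamma=gamma, standardize=standardize).fit()


def loo_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    kernel: KernelSpec | None = None,
    gamma: float = 5.0,
) -> tuple[float, np.ndarray]:
    """Leave-one-out validation.

    Trains ``n`` classifiers, each with one sample held out, and returns the
    overall held-out accuracy and the ``n`` held-out decision values.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 4:
        raise ValueError("leave-one-out needs at least 4 samples")
    for cls in (-1.0, 1.0):
        if np.sum(y == cls) < 2:
            raise ValueError(
                "leave-one-out needs at least 2 members of each class"
            )
    decisions = np.empty(n)
    correct = 0
    for i in range(n):
        mask = np.arange(n) != i
        res = train_lssvm(X[mask], y[mask], kernel=kernel, gamma=gamma)
        g = res.decision_value(X[i])
        decisions[i] = g
        pred = 1.0 if g >= 0 else -1.0
        correct += int(pred == y[i])
    return correct / n, decisions
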