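"""Bagging of component LS-SVMs and the dynamic weighted fusion (DWF) rule.

Bagging trains ``K`` component classifiers (CSVMs) on with-replacement
bootstrap resamples of the training set (each resample the size of the
original set) and averages their decision values.

DWF instead combines the component outputs ``g_k`` per signal with weights

    w_k = sum_j e_k^-1 e_j^-1 / sum_i sum_j e_i^-1 e_j^-1
        = e_k^-1 / sum_j e_j^-1,

inversely proportional to each component's error magnitude ``e_k`` on that
signal, so the weights are nonnegative and sum to one. The published
ensemble squared error is the closed form

    e2_DWF = 1 / (sum_i sum_j e_i^-1 e_j^-1) = 1 / (sum_j e_j^-1)^2,

which satisfies ``e_k^2 / e2_DWF >= 1`` for every component — the fused
error never exceeds the best component's. Two caveats, both documented in
the methods note and surfaced by this module's API:

* the weights above need error *magnitudes*: on signed errors the formula
  can produce negative weights or a vanishing denominator, so the default
  ``error_transform="absolute"`` uses ``|e_k|`` (a literal ``"signed"`` mode
  is kept for study);
* substituting the weights into the weighted double sum gives
  ``K^2 / (sum e^-1)^2``, i.e. ``K^2`` times the printed closed form. The
  closed form is what :func:`dwf_ensemble_error` returns; the substituted
  double sum is exposed separately as :func:`dwf_weighted_square_error`.

Error terms require the true class label (the published protocol evaluates
fusion weights with the test label available, "oracle" mode); the deployable
alternative ("estimated" mode) substitutes a per-model constant error
estimate such as the out-of-bag mean absolute error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lssvm import KernelSpec, LssvmResults, train_lssvm

__all__ = [
    "EnsembleConfig",
    "FusionResult",
    "bagging_train",
    "bagging_predict",
    "dwf_weights",
    "dwf_ensemble_error",
    "dwf_weighted_square_error",
    "dwf_predict",
    "DwfEnsemble",
    "DwfEnsembleResults",
]


@dataclass
class EnsembleConfig:
    """Ensemble hyperparameters (defaults = published values, K = 5)."""

    K: int = 5
    seed: int = 0
    dwf_mode: str = "oracle"  # {"oracle", "estimated"}
    error_transform: str = "absolute"  # {"absolute", "signed"}
    epsilon: float = 1e-12

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.dwf_mode not in ("oracle", "estimated"):
            raise ValueError(f"unknown dwf_mode {self.dwf_mode!r}")
        if self.error_transform not in ("absolute", "signed"):
            raise ValueError(f"unknown error_transform {self.error_transform!r}")


def bagging_train(
    X: np.ndarray,
    y: np.ndarray,
    K: int = 5,
    seed: int = 0,
    kernel: KernelSpec | None = None,
    gamma: float = 5.0,
) -> list[LssvmResults]:
    """Train ``K`` component LS-SVMs on bootstrap resamples of ``(X, y)``.

    Each resample draws ``n`` samples with replacement; single-class draws
    are rejected and redrawn (at most 100 attempts each, then an error).
    Deterministic given ``seed``. Each returned results object carries its
    ``bootstrap_indices`` and out-of-bag ``oob_indices``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 2 or np.unique(y).size < 2:
        raise ValueError("bagging needs >= 2 samples covering both classes")
    rng = np.random.default_rng(seed)
    models: list[LssvmResults] = []
    for k in range(K):
        for attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if np.unique(y[idx]).size == 2:
                break
        else:
            raise RuntimeError(
                f"could not draw a two-class bootstrap for component {k + 1} "
                "after 100 attempts"
            )
        res = train_lssvm(X[idx], y[idx], kernel=kernel, gamma=gamma)
        res.bootstrap_indices = idx
        res.oob_indices = np.setdiff1d(np.arange(n), idx)
        models.append(res)
    return models


def bagging_predict(models: list[LssvmResults], X: np.ndarray) -> np.ndarray | float:
    """Simple-average aggregation of component decision values."""
    if not models:
        raise ValueError("bagging_predict needs at least one model")
    gs = [m.decision_value(X) for m in models]
    if np.isscalar(gs[0]):
        return float(np.mean(gs))
    return np.mean(np.stack(gs), axis=0)


def _transformed_errors(errors: np.ndarray, config: EnsembleConfig) -> np.ndarray:
    e = np.asarray(errors, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("need at least one component error")
    if config.error_transform == "absolute":
        return np.abs(e)
    return e


def dwf_weights(errors: np.ndarray, config: EnsembleConfig | None = None) -> np.ndarray:
    """Fusion weights from per-component errors (normalized, sum to 1).

    Evaluated through the double-sum form
    ``w_k = sum_j e_k^-1 e_j^-1 / sum_i sum_j e_i^-1 e_j^-1``. Components
    whose error magnitude is within ``epsilon`` of zero receive all the
    weight (split equally among them), the natural limit of ``w ~ 1/e``.
    """
    config = config or EnsembleConfig()
    e = _transformed_errors(errors, config)
    small = np.abs(e) <= config.epsilon
    if np.any(small):
        return small.astype(float) / small.sum()
    inv = 1.0 / e
    outer = np.outer(inv, inv)
    denom = float(outer.sum())
    if denom == 0.0:
        raise ZeroDivisionError(
            "signed-error weights undefined: sum of inverse errors vanishes"
        )
    return outer.sum(axis=1) / denom


def dwf_ensemble_error(
    errors: np.ndarray, config: EnsembleConfig | None = None
) -> float:
    """Published closed-form ensemble squared error
    ``1 / (sum_i sum_j e_i^-1 e_j^-1)``.

    Near-zero component errors make the closed form collapse; the limit 0 is
    returned with a warning as the flag.
    """
    config = config or EnsembleConfig()
    e = _transformed_errors(errors, config)
    if np.any(np.abs(e) <= config.epsilon):
        warnings.warn(
            "near-zero component error: DWF ensemble error degenerates to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    inv = 1.0 / e
    return float(1.0 / np.outer(inv, inv).sum())


def dwf_weighted_square_error(errors: np.ndarray, weights: np.ndarray) -> float:
    """Weighted double-sum error ``sum_k sum_j w_k w_j e_k e_j``.

    This is the quantity the fusion weights actually minimize under the
    normalization constraint; substituting the closed-form weights yields
    ``K^2`` times :func:`dwf_ensemble_error` (the factor-``K^2`` discrepancy
    between the two printed expressions is deliberate to preserve — both are
    exposed).
    """
    e = np.asarray(errors, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if e.shape != w.shape:
        raise ValueError("errors and weights must have equal length")
    we = w * e
    return float(np.outer(we, we).sum())


@dataclass
class FusionResult:
    """Per-signal fusion diagnostics for ``n`` signals and ``K`` components.

    ``component_outputs`` (n, K), ``errors`` (n, K, transformed magnitudes
    in absolute mode), ``weights`` (n, K), ``fused_output`` (n,),
    ``ensemble_sq_error`` (n, closed form), ``degenerate`` (n, True where a
    component error was within epsilon of zero).
    """

    component_outputs: np.ndarray
    errors: np.ndarray
    weights: np.ndarray
    fused_output: np.ndarray
    ensemble_sq_error: np.ndarray
    degenerate: np.ndarray
    mode: str

    def predicted_class(self) -> np.ndarray:
        """±1 class prediction from the fused output (tie -> +1)."""
        return np.where(self.fused_output >= 0, 1, -1)

    def to_frame(self, ids=None, labels=None):
        """Fusion report table: id,label,g_1..g_K,e_1..e_K,w_1..w_K,g_dwf,e2_dwf."""
        import pandas as pd

        n, K = self.component_outputs.shape
        data = {}
        data["id"] = list(ids) if ids is not None else list(range(n))
        data["label"] = list(labels) if labels is not None else [""] * n
        for k in range(K):
            data[f"g_{k + 1}"] = self.component_outputs[:, k]
        for k in range(K):
            data[f"e_{k + 1}"] = self.errors[:, k]
        for k in range(K):
            data[f"w_{k + 1}"] = self.weights[:, k]
        data["g_dwf"] = self.fused_output
        data["e2_dwf"] = self.ensemble_sq_error
        return pd.DataFrame(data)


def dwf_predict(
    models: list[LssvmResults],
    X: np.ndarray,
    config: EnsembleConfig | None = None,
    labels: np.ndarray | None = None,
    error_estimates: np.ndarray | None = None,
) -> FusionResult:
    """Fuse component decisions with dynamic weights.

    In ``oracle`` mode (the published protocol) the per-signal component
    error is ``e_k = l - g_k`` with ``l`` the true ±1 label, which must be
    supplied; in ``estimated`` mode a constant per-model error estimate
    (e.g. out-of-bag mean absolute error) is used instead.
    """
    if not models:
        raise ValueError("dwf_predict needs at least one model")
    config = config or EnsembleConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    K = len(models)
    G = np.column_stack([m.decision_value(X) for m in models])
    if config.dwf_mode == "oracle":
        if labels is None:
            raise ValueError("oracle-mode fusion requires the true labels")
        labels = np.asarray(labels, dtype=float).ravel()
        if labels.size != n:
            raise ValueError("labels length does not match number of signals")
        E = labels[:, None] - G
    else:
        if error_estimates is None:
            raise ValueError(
                "estimated-mode fusion requires per-model error estimates"
            )
        est = np.asarray(error_estimates, dtype=float).ravel()
        if est.size != K:
            raise ValueError("need one error estimate per model")
        E = np.tile(est, (n, 1))
    weights = np.empty((n, K))
    e2 = np.empty(n)
    degenerate = np.zeros(n, dtype=bool)
    errors_out = np.empty((n, K))
    for i in range(n):
        e = _transformed_errors(E[i], config)
        errors_out[i] = e
        weights[i] = dwf_weights(e, config)
        if np.any(np.abs(e) <= config.epsilon):
            degenerate[i] = True
            e2[i] = 0.0
        else:
            e2[i] = dwf_ensemble_error(e, config)
    fused = np.sum(weights * G, axis=1)
    return FusionResult(
        component_outputs=G,
        errors=errors_out,
        weights=weights,
        fused_output=fused,
        ensemble_sq_error=e2,
        degenerate=degenerate,
        mode=config.dwf_mode,
    )


class DwfEnsemble:
    """Model object for the bagged LS-SVM ensemble with DWF fusion.

    Construct from a ±1-labeled feature matrix and call :meth:`fit` to train
    the ``K`` component classifiers on bootstrap resamples; the returned
    :class:`DwfEnsembleResults` exposes bagging and DWF predictions plus a
    summary table.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: EnsembleConfig | None = None,
        kernel: KernelSpec | None = None,
        gamma: float = 5.0,
    ):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        self.config = config or EnsembleConfig()
        self.kernel = kernel or KernelSpec()
        self.gamma = gamma

    def fit(self) -> "DwfEnsembleResults":
        models = bagging_train(
            self.X,
            self.y,
            K=self.config.K,
            seed=self.config.seed,
            kernel=self.kernel,
            gamma=self.gamma,
        )
        # Out-of-bag mean absolute error per component: the deployable
        # ("estimated") substitute for oracle per-signal errors.
        oob = np.empty(len(models))
        for k, m in enumerate(models):
            idx = m.oob_indices
            if idx.size == 0:
                idx = np.arange(self.X.shape[0])
            g = m.decision_value(self.X[idx])
            oob[k] = float(np.mean(np.abs(self.y[idx] - g)))
        return DwfEnsembleResults(model=self, components=models, oob_mae=oob)


@dataclass
class DwfEnsembleResults:
    """Fitted ensemble: component classifiers and fusion predictions."""

    model: DwfEnsemble = field(repr=False)
    components: list[LssvmResults]
    oob_mae: np.ndarray

    def bagging_decision(self, X: np.ndarray) -> np.ndarray | float:
        return bagging_predict(self.components, X)

    def fuse(self, X: np.ndarray, labels: np.ndarray | None = None) -> FusionResult:
        """DWF fusion on ``X`` (oracle mode needs ``labels``; estimated mode
        uses the stored out-of-bag error estimates)."""
        return dwf_predict(
            self.components,
            X,
            config=self.model.config,
            labels=labels,
            error_estimates=self.oob_mae,
        )

    def summary(self, X: np.ndarray | None = None, labels: np.ndarray | None = None):
        """Accuracy / ROC area / SE table over the component classifiers,
        their bagged average and the DWF fusion, evaluated on ``(X, labels)``
        (defaults to the training cohort, the published protocol)."""
        from .evaluation import accuracy, roc_auc

        X = self.model.X if X is None else np.atleast_2d(np.asarray(X, float))
        labels = self.model.y if labels is None else np.asarray(labels, float).ravel()
        import pandas as pd

        rows = []
        for k, m in enumerate(self.components, start=1):
            g = m.decision_value(X)
            roc = roc_auc(g, labels)
            rows.append(
                {
                    "classifier": f"CSVM{k}",
                    "accuracy_pct": 100.0 * accuracy(np.where(g >= 0, 1, -1), labels),
                    "az": roc.az,
                    "se": roc.se,
                }
            )
        g_bag = self.bagging_decision(X)
        roc = roc_auc(g_bag, labels)
        rows.append(
            {
                "classifier": "Bagging",
                "accuracy_pct": 100.0 * accuracy(np.where(g_bag >= 0, 1, -1), labels),
                "az": roc.az,
                "se": roc.se,
            }
        )
        fusion = self.fuse(X, labels=labels if self.model.config.dwf_mode == "oracle" else None)
        roc = roc_auc(fusion.fused_output, labels)
        rows.append(
            {
                "classifier": "DWF",
                "accuracy_pct": 100.0 * accuracy(fusion.predicted_class(), labels),
                "az": roc.az,
                "se": roc.se,
            }
        )
        return pd.DataFrame(rows, columns=["classifier", "accuracy_pct", "az", "se"])
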