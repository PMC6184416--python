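"""Single-hidden-layer perceptron regression of hospitalization expenditure.

The network is deliberately small and fixed to the configuration used in
provincial expenditure studies of this kind: one hidden layer of 5 tanh
units, squared-error loss with L2 weight penalty, optimized by L-BFGS
(gradients via backpropagation) for at most 1500 iterations, trained on a
90% split with 5-fold cross-validation inside the training set.  The fit is
delegated to scikit-learn's ``MLPRegressor``; this module owns the
standardization protocol (training-set statistics only — no leakage into
the test set), the weight extraction consumed by Garson sensitivity
analysis, and the evaluation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.neural_network import MLPRegressor

from .errors import ConfigError, FitError, UndefinedMetricError
from .preprocessing import ModelMatrix, SplitPlan

__all__ = [
    "NetworkSpec",
    "PerceptronWeights",
    "EvalMetrics",
    "FittedPerceptron",
    "fit",
    "evaluate",
    "learning_curves",
    "cross_validate",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Network configuration; defaults are the study configuration."""

    n_hidden: int = 5
    l2_alpha: float = 1e-4
    max_iter: int = 1500
    seed: int = 0
    activation: str = "tanh"  # fixed; exposed for introspection only
    optimizer: str = "lbfgs"

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ConfigError(f"n_hidden must be positive, got {self.n_hidden}")
        if self.l2_alpha < 0:
            raise ConfigError(f"l2_alpha must be nonnegative, got {self.l2_alpha}")
        if self.max_iter < 1:
            raise ConfigError(f"max_iter must be positive, got {self.max_iter}")
        if self.activation != "tanh" or self.optimizer != "lbfgs":
            raise ConfigError("activation is fixed to tanh and optimizer to lbfgs")


@dataclass(frozen=True)
class PerceptronWeights:
    """Connection weights of the fitted network: input->hidden matrix W
    (p x h), hidden biases, hidden->output vector v (h,), output bias."""

    W: np.ndarray
    b_h: np.ndarray
    v: np.ndarray
    b_o: float

    def __post_init__(self) -> None:
        p, h = self.W.shape
        if self.b_h.shape != (h,) or self.v.shape != (h,):
            raise ConfigError("inconsistent weight dimensions")


@dataclass(frozen=True)
class EvalMetrics:
    r2: float
    r2_adj: float
    mse: float
    mae: float
    n: int
    p: int

    def as_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "mse": self.mse,
            "mae": self.mae,
            "n": self.n,
            "p": self.p,
        }


@dataclass
class FittedPerceptron:
    """A trained network plus the train-only standardization it was fitted
    under."""

    estimator: MLPRegressor
    spec: NetworkSpec
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    feature_map: dict[str, str]
    columns: list[str]
    train_metrics: EvalMetrics
    test_metrics: EvalMetrics | None

    @property
    def weights(self) -> PerceptronWeights:
        return PerceptronWeights(
            W=self.estimator.coefs_[0].copy(),
            b_h=self.estimator.intercepts_[0].copy(),
            v=self.estimator.coefs_[1].ravel().copy(),
            b_o=float(self.estimator.intercepts_[1][0]),
        )

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scale_mean) / self.scale_sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(self.transform(X))


def evaluate(y_true, y_pred, p: int) -> EvalMetrics:
    """R^2, adjusted R^2 (= 1 - (1-R^2)(n-1)/(n-p-1)), MSE and MAE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ConfigError("evaluate needs equal-length vectors of length >= 2")
    if np.var(y_true) == 0:
        raise UndefinedMetricError("R^2 undefined: outcome has zero variance")
    n = y_true.size
    r2 = float(r2_score(y_true, y_pred))
    r2_adj = float(1 - (1 - r2) * (n - 1) / (n - p - 1)) if n - p - 1 > 0 else float("nan")
    return EvalMetrics(
        r2=r2,
        r2_adj=r2_adj,
        mse=float(mean_squared_error(y_true, y_pred)),
        mae=float(mean_absolute_error(y_true, y_pred)),
        n=n,
        p=p,
    )


def _scaler(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0  # constant columns pass through unscaled
    return mean, sd


def fit(
    matrix: ModelMatrix, spec: NetworkSpec, split: SplitPlan | None = None
) -> FittedPerceptron:
    """Train the perceptron on the training rows of ``matrix``.

    Standardization statistics come from the training rows only and are
    applied unchanged to the test rows.  A fixed spec seed fixes the weight
    initialization, so runs are reproducible on one platform.
    """
    if split is None:
        train_idx = np.arange(matrix.n)
        test_idx = np.array([], dtype=int)
    else:
        train_idx, test_idx = split.train_idx, split.test_idx
    if len(train_idx) <= matrix.p:
        import warnings

        warnings.warn(
            f"n_train={len(train_idx)} <= p={matrix.p}: model under-determined",
            stacklevel=2,
        )
    X_train, y_train = matrix.X[train_idx], matrix.y[train_idx]
    mean, sd = _scaler(X_train)

    est = MLPRegressor(
        hidden_layer_sizes=(spec.n_hidden,),
        activation="tanh",
        solver="lbfgs",
        alpha=spec.l2_alpha,
        max_iter=spec.max_iter,
        random_state=spec.seed,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit((X_train - mean) / sd, y_train)
    if not np.all(np.isfinite(est.coefs_[0])) or not np.isfinite(est.loss_):
        raise FitError(f"non-finite loss/weights (loss={est.loss_!r})")

    train_pred = est.predict((X_train - mean) / sd)
    train_metrics = evaluate(y_train, train_pred, matrix.p)
    test_metrics = None
    if len(test_idx):
        X_test = (matrix.X[test_idx] - mean) / sd
        test_metrics = evaluate(matrix.y[test_idx], est.predict(X_test), matrix.p)
    return FittedPerceptron(
        estimator=est,
        spec=spec,
        scale_mean=mean,
        scale_sd=sd,
        feature_map=dict(matrix.feature_map),
        columns=list(matrix.columns),
        train_metrics=train_metrics,
        test_metrics=test_metrics,
    )


def cross_validate(
    matrix: ModelMatrix, spec: NetworkSpec, split: SplitPlan
) -> pd.DataFrame:
    """5-fold cross-validation inside the training set: one row per fold
    with train/validation R^2 and MSE."""
    rows = []
    for k, fold in enumerate(split.cv_folds):
        fold_set = set(fold.tolist())
        tr = np.array([i for i in split.train_idx if i not in fold_set])
        mean, sd = _scaler(matrix.X[tr])
        est = MLPRegressor(
            hidden_layer_sizes=(spec.n_hidden,),
            activation="tanh",
            solver="lbfgs",
            alpha=spec.l2_alpha,
            max_iter=spec.max_iter,
            random_state=spec.seed + k,
        )
        import warnings

        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit((matrix.X[tr] - mean) / sd, matrix.y[tr])
        val_pred = est.predict((matrix.X[fold] - mean) / sd)
        tr_pred = est.predict((matrix.X[tr] - mean) / sd)
        rows.append(
            {
                "fold": k,
                "train_mse": float(np.mean((tr_pred - matrix.y[tr]) ** 2)),
                "val_mse": float(np.mean((val_pred - matrix.y[fold]) ** 2)),
                "train_r2": float(r2_score(matrix.y[tr], tr_pred)),
                "val_r2": float(r2_score(matrix.y[fold], val_pred)),
            }
        )
    return pd.DataFrame(rows)


def learning_curves(
    matrix: ModelMatrix,
    spec: NetworkSpec,
    split: SplitPlan,
    fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0),
) -> pd.DataFrame:
    """Training-size learning curve: refit on growing prefixes of the
    training set, score on the held-out test rows.

    The reported training error is the running minimum over fractions
    (a smoothed, monotone non-increasing curve), alongside the raw values.
    """
    rng = np.random.default_rng(split.seed)
    order = rng.permutation(split.train_idx)
    rows = []
    for frac in fractions:
        k = max(int(round(frac * len(order))), matrix.p + 2)
        sub = np.sort(order[:k])
        mean, sd = _scaler(matrix.X[sub])
        est = MLPRegressor(
            hidden_layer_sizes=(spec.n_hidden,),
            activation="tanh",
            solver="lbfgs",
            alpha=spec.l2_alpha,
            max_iter=spec.max_iter,
            random_state=spec.seed,
        )
        import warnings

        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit((matrix.X[sub] - mean) / sd, matrix.y[sub])
        train_mse = float(np.mean((est.predict((matrix.X[sub] - mean) / sd) - matrix.y[sub]) ** 2))
        test_mse = (
            float(
                np.mean(
                    (est.predict((matrix.X[split.test_idx] - mean) / sd) - matrix.y[split.test_idx])
                    ** 2
                )
            )
            if len(split.test_idx)
            else float("nan")
        )
        rows.append({"train_fraction": frac, "n_train": k, "train_mse": train_mse, "test_mse": test_mse})
    frame = pd.DataFrame(rows)
    frame["train_mse_smoothed"] = frame["train_mse"].cummin()
    return frame


def plot_learning_curves(curves: pd.DataFrame, path) -> None:
    """Save a simple train/test error plot (diagnostic, not publication
    styling)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curves["n_train"], curves["train_mse_smoothed"], marker="o", label="train")
    if curves["test_mse"].notna().any():
        ax.plot(curves["n_train"], curves["test_mse"], marker="s", label="test")
    ax.set_xlabel("training admissions")
    ax.set_ylabel("MSE (log-RMB scale)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
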