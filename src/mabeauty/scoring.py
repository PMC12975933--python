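"""Beauty-score regression head and evaluation metrics (PC, MAE, RMSE).

The score model is ridge regression with an intercept on a selected feature
subset, with predictions clipped to the 1-5 rating scale used by the public
facial-beauty datasets.  Ridge keeps rank-deficient designs well-posed and
matches the regressor inside the GA's wrapper evaluator, so selection
fitness and final evaluation are consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .errors import MABeautyError

SCORE_RANGE = (1.0, 5.0)


class UndefinedCorrelationError(MABeautyError):
    """Pearson correlation is undefined for constant input."""


def _check_paired(a, b, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < min_len:
        raise ValueError(f"need at least {min_len} samples, got {a.size}")
    return a, b


def pearson(a, b) -> float:
    """Sample Pearson correlation coefficient between paired vectors."""
    a, b = _check_paired(a, b, 2)
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom <= 0.0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float((da @ db) / denom)


def mae(a, b) -> float:
    """Mean absolute error between paired vectors."""
    a, b = _check_paired(a, b, 1)
    return float(np.mean(np.abs(a - b)))


def rmse(a, b) -> float:
    """Root mean square error between paired vectors."""
    a, b = _check_paired(a, b, 1)
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass(frozen=True)
class EvalReport:
    """PC/MAE/RMSE summary for one prediction set."""

    pc: float
    mae: float
    rmse: float
    n: int

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.pc <= 1.0 + 1e-12:
            raise ValueError(f"pc out of [-1, 1]: {self.pc}")
        if self.mae < 0 or self.rmse < 0:
            raise ValueError("errors must be non-negative")
        if self.rmse + 1e-12 < self.mae:  # power-mean inequality
            raise ValueError(f"rmse ({self.rmse}) < mae ({self.mae})")

    def to_dict(self) -> dict:
        return {"pc": self.pc, "mae": self.mae, "rmse": self.rmse, "n": self.n}


def evaluate_predictions(pred, truth, constant_pc: float = 0.0) -> EvalReport:
    """Build an EvalReport; a constant input maps PC to `constant_pc` with a warning."""
    pred, truth = _check_paired(pred, truth, 1)
    try:
        pc = pearson(pred, truth) if pred.size >= 2 else constant_pc
    except UndefinedCorrelationError:
        warnings.warn("constant predictions or labels; PC reported as "
                      f"{constant_pc}", stacklevel=2)
        pc = constant_pc
    return EvalReport(pc=pc, mae=mae(pred, truth), rmse=rmse(pred, truth),
                      n=int(pred.size))


class RidgeScoreModel:
    """Ridge regressor mapping a feature subset to a clipped 1-5 beauty score."""

    def __init__(self, subset: np.ndarray | None = None, alpha: float = 1.0,
                 clip: tuple[float, float] = SCORE_RANGE):
        self.subset = None if subset is None else np.asarray(subset, dtype=int)
        self.alpha = float(alpha)
        self.clip = clip
        self._ridge: Ridge | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    def _design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.subset is not None:
            X = X[:, self.subset]
        return X

    def fit(self, X, y) -> "RidgeScoreModel":
        X = self._design(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("feature table and scores are not aligned")
        if X.shape[0] < 2 * X.shape[1]:
            warnings.warn(
                f"only {X.shape[0]} samples for {X.shape[1]} features; "
                "ridge fit may be strongly regularized", stacklevel=2)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        self._ridge = Ridge(alpha=self.alpha)
        self._ridge.fit((X - self._mu) / self._sd, y)
        return self

    def predict(self, X, clipped: bool = True) -> np.ndarray:
        if self._ridge is None:
            raise RuntimeError("model is not fitted")
        X = self._design(X)
        pred = self._ridge.predict((X - self._mu) / self._sd)
        if clipped:
            pred = np.clip(pred, *self.clip)
        return pred


def fit_score_model(X, y, subset=None, alpha: float = 1.0) -> RidgeScoreModel:
    """Fit the default ridge score model on (optionally subset) features."""
    return RidgeScoreModel(subset=subset, alpha=alpha).fit(X, y)


def split_indices(n: int, seed: int,
                  fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)):
    """Deterministic train/validation/test index split (default 60/20/20)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]
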