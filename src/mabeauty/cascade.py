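"""Cascaded pose regression (CPR) landmark refiner.

A staged shape update S_v = S_{v-1} + alpha_v * R_v(X, S_{v-1}): starting
from the mean shape S_0, each stage's linear regressor R_v predicts a
144-dimensional shape increment from shape-indexed appearance features of
the image X, and the estimate advances by a decayed step alpha_v.  The decay
base defaults to 0.8; the default schedule is geometric (alpha_v = 0.8^v),
with a constant-0.8 mode available.

Stage features are pixel-difference pairs sampled at fixed random offsets
around the current landmark estimates (standard explicit-shape-regression
practice); offsets are drawn once per stage at training time from a seeded
generator, so prediction is fully deterministic.  Stage regressors are
ridge-regularized to stay well-posed in the small-sample regime this
architecture targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegeneracyError, NotFittedError
from .schema import N_POINTS, LandmarkSet


@dataclass
class CascadeStage:
    """One stage's sampling pattern and linear regressor."""

    anchor_idx: np.ndarray    # (P, 2) landmark index per pixel of each pair
    offsets: np.ndarray       # (P, 2, 2) integer (dx, dy) per pixel
    weights: np.ndarray       # (P, 2*N_POINTS)
    intercept: np.ndarray     # (2*N_POINTS,)


@dataclass
class CascadeModel:
    """Mean shape plus the ordered stage regressors and their step sizes."""

    mean_shape: np.ndarray                      # (N_POINTS, 2) raster coords
    stages: list[CascadeStage] = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        if self.mean_shape.shape != (N_POINTS, 2):
            raise ValueError(f"mean shape must be ({N_POINTS}, 2)")
        if not np.all(np.isfinite(self.mean_shape)):
            raise ValueError("mean shape must be finite")
        if len(self.stages) != len(self.alphas):
            raise ValueError("one step size per stage required")
        for s in self.stages:
            if not (np.all(np.isfinite(s.weights)) and np.all(np.isfinite(s.intercept))):
                raise ValueError("stage regressor weights must be finite")

    @property
    def n_stages(self) -> int:
        return len(self.stages)


def alpha_schedule(n_stages: int, decay_base: float = 0.8,
                   mode: str = "geometric") -> list[float]:
    """Per-stage step sizes: geometric 0.8^v (default) or constant 0.8."""
    if mode == "geometric":
        return [decay_base ** v for v in range(1, n_stages + 1)]
    if mode == "constant":
        return [decay_base] * n_stages
    raise ValueError(f"unknown decay mode {mode!r}")


def _sample_pixels(images: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Nearest-pixel lookup, clamped to bounds.

    images: (n, H, W); pts: (n, P, 2) in (x, y) raster coords -> (n, P).
    """
    n, H, W = images.shape
    x = np.clip(np.rint(pts[..., 0]).astype(int), 0, W - 1)
    y = np.clip(np.rint(pts[..., 1]).astype(int), 0, H - 1)
    return images[np.arange(n)[:, None], y, x]


def shape_indexed_features(images: np.ndarray, shapes: np.ndarray,
                           anchor_idx: np.ndarray, offsets: np.ndarray
                           ) -> np.ndarray:
    """Pixel-difference features indexed to the current shape estimate.

    For each of P pairs, the feature is I(a1 + o1) - I(a2 + o2) where a1, a2
    are current positions of the anchored landmarks and o1, o2 fixed integer
    offsets.  Accepts a single image/shape or a batch; returns (P,) or (n, P).
    """
    images = np.asarray(images, dtype=float)
    shapes = np.asarray(shapes, dtype=float)
    single = images.ndim == 2
    if single:
        images = images[None]
        shapes = shapes[None]
    if images.size == 0 or images.shape[1] == 0 or images.shape[2] == 0:
        raise ValueError("empty image input")
    p1 = shapes[:, anchor_idx[:, 0], :] + offsets[None, :, 0, :]
    p2 = shapes[:, anchor_idx[:, 1], :] + offsets[None, :, 1, :]
    feats = _sample_pixels(images, p1) - _sample_pixels(images, p2)
    return feats[0] if single else feats


def _fit_ridge(F: np.ndarray, T: np.ndarray, lam: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form multi-output ridge with intercept."""
    mF = F.mean(axis=0)
    mT = T.mean(axis=0)
    Fc = F - mF
    Tc = T - mT
    G = Fc.T @ Fc + lam * np.eye(F.shape[1])
    W = np.linalg.solve(G, Fc.T @ Tc)
    b = mT - mF @ W
    return W, b


def train_cascade(images, true_shapes, n_stages: int = 5,
                  decay_base: float = 0.8, decay_mode: str = "geometric",
                  n_features: int = 200, offset_radius: int = 6,
                  ridge_lambda: float = 1.0, seed: int = 0) -> CascadeModel:
    """Fit the staged regressors on (image, true shape) pairs.

    Each stage regresses the residual (true - current estimate) on
    shape-indexed pixel-difference features of the current estimates, then
    advances every training estimate by alpha_v times its prediction.
    """
    images = np.asarray(images, dtype=float)
    true_shapes = np.asarray(true_shapes, dtype=float)
    n = images.shape[0]
    if n < 10:
        raise ValueError("need at least 10 training faces")
    if true_shapes.shape != (n, N_POINTS, 2):
        raise ValueError(f"true shapes must be (n, {N_POINTS}, 2)")
    spread = true_shapes.std(axis=0).max()
    if spread <= 1e-9:
        raise DegeneracyError(
            "all training shapes identical (max coordinate SD "
            f"{spread:.2e}); the cascade would only memorize the mean shape"
        )

    rng = np.random.default_rng(seed)
    mean = true_shapes.mean(axis=0)
    current = np.repeat(mean[None], n, axis=0)
    alphas = alpha_schedule(n_stages, decay_base, decay_mode)
    stages: list[CascadeStage] = []
    for alpha in alphas:
        anchor_idx = rng.integers(0, N_POINTS, size=(n_features, 2))
        offsets = rng.integers(-offset_radius, offset_radius + 1,
                               size=(n_features, 2, 2))
        F = shape_indexed_features(images, current, anchor_idx, offsets)
        T = (true_shapes - current).reshape(n, -1)
        W, b = _fit_ridge(F, T, ridge_lambda)
        stages.append(CascadeStage(anchor_idx, offsets, W, b))
        current = current + alpha * (F @ W + b).reshape(n, N_POINTS, 2)
    return CascadeModel(mean_shape=mean, stages=stages, alphas=list(alphas))


def predict_landmarks(model: CascadeModel, image: np.ndarray) -> LandmarkSet:
    """Run the staged refinement from the mean shape on one image."""
    if model is None or not isinstance(model, CascadeModel):
        raise NotFittedError("predict_landmarks requires a trained CascadeModel")
    shapes = predict_shapes(model, np.asarray(image, dtype=float)[None])
    return LandmarkSet(shapes[0], frame="image")


def predict_shapes(model: CascadeModel, images: np.ndarray) -> np.ndarray:
    """Batched prediction; returns (n, N_POINTS, 2)."""
    images = np.asarray(images, dtype=float)
    n = images.shape[0]
    current = np.repeat(model.mean_shape[None], n, axis=0)
    for stage, alpha in zip(model.stages, model.alphas):
        F = shape_indexed_features(images, current, stage.anchor_idx, stage.offsets)
        current = current + alpha * (F @ stage.weights + stage.intercept
                                     ).reshape(n, N_POINTS, 2)
    return current


def mean_point_error(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean Euclidean point-to-point distance over faces and landmarks."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    return float(np.linalg.norm(pred - truth, axis=-1).mean())
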