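"""Regression model families: epsilon-SVR, CART regression, PLSR.

One fit/predict contract over the three families compared in the
calibration study:

* ``svr`` -- epsilon-insensitive support vector regression with a linear,
  polynomial (order 3) or RBF kernel; the box constraint is held at its
  conventional default C = 1 and the kernel scale is either a positive
  number or ``"auto"`` (median pairwise training distance).  Epsilon
  defaults to IQR(y)/13.49.
* ``dt`` -- a binary CART regression tree grown best-first by impurity
  (SSE) reduction with an explicit split budget ``max_splits``, so the
  budget caps the number of internal splits rather than the depth.
* ``plsr`` -- partial least squares regression with a stated number of
  latent components, or validation-selected up to 10.

All fits are deterministic given (spec, X, y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVR as _SkSVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ModelSpec",
    "FittedModel",
    "kernel_scale_auto",
    "fit",
    "predict",
    "select_plsr_components",
    "svr_epsilon",
]

MAX_SPLITS_GRID = (5, 10, 20, 50, 100)
MAX_PLSR_COMPONENTS = 10


@dataclass
class ModelSpec:
    """Model family plus its family-appropriate hyperparameters."""

    family: str  # "svr" | "dt" | "plsr"
    kernel: str = "rbf"  # svr: "linear" | "polynomial" | "rbf"
    box_constraint: float = 1.0  # svr C
    kernel_scale: float | str = "auto"  # svr; "auto" = median heuristic
    polynomial_order: int = 3  # svr polynomial kernel
    epsilon: float | str = "auto"  # svr; "auto" = IQR(y)/13.49
    max_splits: int = 10  # dt split budget
    n_components: int | str = "select"  # plsr; "select" = validation-chosen
    seed: int = 0  # seeds the kernel-scale subsampling only

    def __post_init__(self) -> None:
        if self.family not in ("svr", "dt", "plsr"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "svr":
            if self.kernel not in ("linear", "polynomial", "rbf"):
                raise ValueError(f"unknown SVR kernel {self.kernel!r}")
            if self.box_constraint <= 0:
                raise ValueError("box constraint C must be positive")
            if self.kernel_scale != "auto" and float(self.kernel_scale) <= 0:
                raise ValueError("kernel_scale must be positive or 'auto'")
        if self.family == "dt" and self.max_splits < 1:
            raise ValueError("max_splits must be >= 1")
        if self.family == "plsr" and self.n_components != "select":
            if int(self.n_components) < 1:
                raise ValueError("n_components must be >= 1 or 'select'")

    def label(self) -> str:
        if self.family == "svr":
            return f"svr-{self.kernel}"
        if self.family == "dt":
            return f"dt-{self.max_splits}"
        return f"plsr-{self.n_components}"

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "kernel": self.kernel,
            "box_constraint": self.box_constraint,
            "kernel_scale": self.kernel_scale,
            "polynomial_order": self.polynomial_order,
            "epsilon": self.epsilon,
            "max_splits": self.max_splits,
            "n_components": self.n_components,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class FittedModel:
    """A fitted estimator plus the wavelength metadata it was trained on."""

    spec: ModelSpec
    estimator: Any
    wavelengths_nm: np.ndarray
    constant_value: float | None = None  # degenerate constant-y fit
    details: dict = field(default_factory=dict)


def kernel_scale_auto(
    X_train: np.ndarray, max_rows: int = 1000, seed: int = 0
) -> float:
    """Median pairwise Euclidean distance among training rows.

    The reproducible stand-in for an 'auto' kernel-scale heuristic: the
    median heuristic on (at most ``max_rows`` seeded-subsampled) training
    rows.  Scales homogeneously with the data.
    """
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("kernel scale needs at least two rows")
    if X.shape[0] > max_rows:
        idx = np.random.default_rng(seed).choice(X.shape[0], max_rows, replace=False)
        X = X[np.sort(idx)]
    d = pdist(X)
    med = float(np.median(d))
    if med == 0:
        positive = d[d > 0]
        if positive.size == 0:
            raise ValueError("all training rows identical: kernel scale undefined")
        med = float(positive.min())
    return med


def svr_epsilon(y_train: np.ndarray) -> float:
    """Default epsilon for the insensitive loss: IQR(y)/13.49."""
    q75, q25 = np.percentile(y_train, [75, 25])
    return float((q75 - q25) / 13.49)


def _build_svr(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> _SkSVR:
    eps = svr_epsilon(y) if spec.epsilon == "auto" else float(spec.epsilon)
    if spec.kernel == "linear":
        return _SkSVR(kernel="linear", C=spec.box_constraint, epsilon=eps)
    scale = (
        kernel_scale_auto(X, seed=spec.seed)
        if spec.kernel_scale == "auto"
        else float(spec.kernel_scale)
    )
    gamma = 1.0 / scale**2  # k(x,y) = exp(-||x-y||^2 / scale^2)
    if spec.kernel == "rbf":
        return _SkSVR(kernel="rbf", C=spec.box_constraint, epsilon=eps, gamma=gamma)
    return _SkSVR(
        kernel="poly",
        degree=spec.polynomial_order,
        C=spec.box_constraint,
        epsilon=eps,
        gamma=gamma,
        coef0=1.0,
    )


def fit(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    wavelengths_nm: np.ndarray | None = None,
) -> FittedModel:
    """Fit one model family on a training matrix.

    A constant target yields a constant predictor for every family rather
    than an error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    if X.shape[0] < 3:
        raise ValueError("at least three training samples are required")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values in the training data")
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(X.shape[1], dtype=float)
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if wavelengths_nm.size != X.shape[1]:
        raise ValueError("one wavelength per column is required")

    if np.ptp(y) == 0:
        return FittedModel(spec, None, wavelengths_nm, constant_value=float(y[0]))

    if spec.family == "svr":
        est = _build_svr(spec, X, y)
        est.fit(X, y)
        return FittedModel(spec, est, wavelengths_nm)

    if spec.family == "dt":
        # max_leaf_nodes = max_splits + 1 grows the tree best-first by
        # impurity improvement, making the budget a true split count.
        est = DecisionTreeRegressor(
            max_leaf_nodes=spec.max_splits + 1, random_state=0
        )
        est.fit(X, y)
        return FittedModel(spec, est, wavelengths_nm)

    # plsr
    k = spec.n_components
    if k == "select":
        raise ValueError(
            "n_components='select' requires select_plsr_components with a "
            "validation set; pass an integer here"
        )
    k = int(k)
    rank_bound = min(X.shape[0] - 1, X.shape[1])
    if k > min(rank_bound, MAX_PLSR_COMPONENTS):
        raise ValueError(
            f"n_components={k} exceeds min(rank bound {rank_bound}, "
            f"{MAX_PLSR_COMPONENTS})"
        )
    est = PLSRegression(n_components=k, scale=False)
    with warnings.catch_warnings():
        # expected when k exceeds the informative rank; deflation just stops
        warnings.simplefilter("ignore", UserWarning)
        est.fit(X, y.reshape(-1, 1))
    return FittedModel(spec, est, wavelengths_nm)


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Predict the response for rows over the training wavelength set."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.wavelengths_nm.size:
        trained = model.wavelengths_nm
        raise ValueError(
            f"column mismatch: model trained on {trained.size} wavelengths "
            f"({trained[0]:g}-{trained[-1]:g} nm), got {X.shape[1]} columns"
        )
    if model.constant_value is not None:
        return np.full(X.shape[0], model.constant_value)
    out = model.estimator.predict(X)
    return np.asarray(out, dtype=float).ravel()


def select_plsr_components(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_k: int = MAX_PLSR_COMPONENTS,
) -> tuple[int, "FittedModel"]:
    """Choose the PLSR component count minimizing validation RMSE.

    Scans k = 1..max_k (capped at the training rank bound), refits at each
    k and scores on the validation rows.  Near-ties (validation RMSE within
    a 1e-9 relative band of the minimum) resolve to the smallest k, so a
    redundant extra component never wins on floating-point dust.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_val = np.asarray(y_val, dtype=float).ravel()
    rank_bound = min(X_train.shape[0] - 1, X_train.shape[1])
    ks = range(1, min(max_k, rank_bound) + 1)
    rmses, fits = {}, {}
    for k in ks:
        try:
            spec_k = ModelSpec(family="plsr", n_components=k)
            m = fit(spec_k, X_train, y_train)
            pred = predict(m, X_val)
            rmses[k] = float(np.sqrt(np.mean((y_val - pred) ** 2)))
            fits[k] = m
        except (ValueError, np.linalg.LinAlgError):
            continue
    if not rmses:
        raise ValueError("no PLSR component count could be fitted")
    best_rmse = min(rmses.values())
    tol = 1e-9 * max(best_rmse, 1e-300)
    chosen = min(k for k, r in rmses.items() if r <= best_rmse + tol)
    return chosen, fits[chosen]
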