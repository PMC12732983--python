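"""Spectral preprocessing operators.

Eight operators commonly used on diffuse-reflectance Vis/NIR spectra:
per-spectrum min-max normalization, SNV, MSC, three smoothing filters
(moving average and median with window 5, Gaussian with sigma 2), linear
detrending, and mean centering.  SNV, normalization, detrending and the
filters act row-wise and carry no state; MSC and mean centering are fitted
on the training partition only (reference spectrum / column means) so no
information leaks from validation or test rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessingSpec",
    "Preprocessor",
    "snv",
    "msc",
    "smooth",
    "detrend",
    "mean_center_fit",
    "mean_center_apply",
    "normalize",
    "PREPROCESSING_METHODS",
]

PREPROCESSING_METHODS = (
    "none",
    "normalization",
    "snv",
    "msc",
    "moving_average",
    "gaussian_filter",
    "median_filter",
    "detrend",
    "mean_centering",
)


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: subtract the spectrum mean, divide by its
    sample (n-1) standard deviation."""
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise ValueError("SNV needs at least two points")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a constant spectrum (zero variance)")
    return (x - np.mean(x)) / sd


def msc(spectrum: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Fits ``x = a + b * ref`` by ordinary least squares and returns
    ``(x - a) / b``, undoing the per-sample additive/multiplicative scatter.
    The reference is conventionally the mean training spectrum.
    """
    x = np.asarray(spectrum, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if x.shape != ref.shape:
        raise ValueError("spectrum and reference lengths differ")
    ref_c = ref - ref.mean()
    denom = np.dot(ref_c, ref_c)
    if denom == 0:
        raise ValueError("MSC reference is constant")
    b = np.dot(ref_c, x - x.mean()) / denom
    a = x.mean() - b * ref.mean()
    if b == 0:
        raise ValueError("MSC slope is zero: spectrum uncorrelated with reference")
    return (x - a) / b


def smooth(
    spectrum: np.ndarray,
    method: str = "moving_average",
    window: int = 5,
    sigma: float = 2.0,
) -> np.ndarray:
    """Smooth a spectrum with a moving-average, median or Gaussian filter.

    The moving-average and median filters use an odd ``window`` (default 5);
    the Gaussian filter uses ``sigma`` (default 2, in grid-point units)
    truncated at four sigma.  Edges are handled by reflect padding, so a
    constant spectrum passes through unchanged for all three methods.
    """
    x = np.asarray(spectrum, dtype=float)
    if method in ("moving_average", "median_filter", "median"):
        if window % 2 == 0 or window < 3:
            raise ValueError("window must be an odd integer >= 3")
        if x.size <= window:
            raise ValueError("spectrum must be longer than the window")
    if method == "moving_average":
        return ndimage.uniform_filter1d(x, size=window, mode="reflect")
    if method in ("median", "median_filter"):
        return ndimage.median_filter(x, size=window, mode="reflect")
    if method in ("gaussian", "gaussian_filter"):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        return ndimage.gaussian_filter1d(x, sigma=sigma, mode="reflect", truncate=4.0)
    raise ValueError(f"unknown smoothing method {method!r}")


def detrend(spectrum: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """Remove the least-squares line of absorbance on wavelength.

    The residuals are orthogonal to both the constant and the wavelength
    regressor, so any affine trend ``c + m*lambda`` is removed exactly.
    """
    x = np.asarray(spectrum, dtype=float)
    w = np.asarray(wavelengths, dtype=float)
    if x.size < 3:
        raise ValueError("detrend needs at least three points")
    if np.unique(w).size < 2:
        raise ValueError("detrend needs at least two distinct wavelengths")
    design = np.column_stack([np.ones_like(w), w])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def mean_center_fit(train_matrix: np.ndarray) -> np.ndarray:
    """Column means of the training rows (the fitted state)."""
    m = np.atleast_2d(np.asarray(train_matrix, dtype=float))
    return m.mean(axis=0)


def mean_center_apply(matrix: np.ndarray, column_means: np.ndarray) -> np.ndarray:
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    mu = np.asarray(column_means, dtype=float)
    if m.shape[1] != mu.size:
        raise ValueError(
            f"matrix has {m.shape[1]} columns, fitted means have {mu.size}"
        )
    return m - mu


def normalize(spectrum: np.ndarray, variant: str = "minmax") -> np.ndarray:
    """Per-spectrum normalization.

    ``minmax`` (default) rescales to [0, 1]; ``unit`` divides by the
    Euclidean norm.  Min-max is invariant to any increasing affine
    transform of the spectrum.
    """
    x = np.asarray(spectrum, dtype=float)
    if variant == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError("normalization undefined for a constant spectrum")
        return (x - lo) / (hi - lo)
    if variant == "unit":
        norm = np.linalg.norm(x)
        if norm == 0:
            raise ValueError("cannot normalize the zero spectrum")
        return x / norm
    raise ValueError(f"unknown normalization variant {variant!r}")


@dataclass
class PreprocessingSpec:
    """Named preprocessing method plus its tunable parameters."""

    method: str = "none"
    window: int = 5
    sigma: float = 2.0
    normalization_variant: str = "minmax"

    def __post_init__(self) -> None:
        if self.method not in PREPROCESSING_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {PREPROCESSING_METHODS}"
            )
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be an odd integer >= 3")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "window": self.window,
            "sigma": self.sigma,
            "normalization_variant": self.normalization_variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessingSpec":
        return cls(**{k: d[k] for k in d if k in ("method", "window", "sigma", "normalization_variant")})


@dataclass
class Preprocessor:
    """Fit/apply wrapper around one preprocessing method.

    ``fit`` records state from training rows only (the MSC reference
    spectrum or the mean-centering column means); stateless methods accept
    ``fit`` as a no-op.  ``transform`` may then be applied to any rows.
    """

    spec: PreprocessingSpec
    wavelengths_nm: np.ndarray | None = None
    reference_: np.ndarray | None = field(default=None, repr=False)
    column_means_: np.ndarray | None = field(default=None, repr=False)

    def fit(self, train_matrix: np.ndarray) -> "Preprocessor":
        m = np.atleast_2d(np.asarray(train_matrix, dtype=float))
        if self.spec.method == "msc":
            self.reference_ = m.mean(axis=0)
        elif self.spec.method == "mean_centering":
            self.column_means_ = mean_center_fit(m)
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        m = np.atleast_2d(np.asarray(matrix, dtype=float))
        method = self.spec.method
        if method == "none":
            return m.copy()
        if method == "normalization":
            return np.vstack([normalize(r, self.spec.normalization_variant) for r in m])
        if method == "snv":
            return np.vstack([snv(r) for r in m])
        if method == "msc":
            if self.reference_ is None:
                raise RuntimeError("MSC must be fitted on training rows first")
            return np.vstack([msc(r, self.reference_) for r in m])
        if method in ("moving_average", "median_filter", "gaussian_filter"):
            return np.vstack(
                [smooth(r, method, self.spec.window, self.spec.sigma) for r in m]
            )
        if method == "detrend":
            if self.wavelengths_nm is None:
                raise RuntimeError("detrend needs the wavelength grid")
            return np.vstack([detrend(r, self.wavelengths_nm) for r in m])
        if method == "mean_centering":
            if self.column_means_ is None:
                raise RuntimeError("mean centering must be fitted on training rows first")
            return mean_center_apply(m, self.column_means_)
        raise ValueError(f"unknown method {method!r}")

    def fit_transform(self, train_matrix: np.ndarray) -> np.ndarray:
        return self.fit(train_matrix).transform(train_matrix)
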