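"""PLS regression, cross-validation, evaluation metrics and univariate
peak calibration.

The PLS implementation is a mean-centered single-response NIPALS with no
variable autoscaling; its predictions are checked against an independent
reference implementation in the test suite.  The RMSE uses an ``m - 1``
denominator (not the conventional ``m``) for both cross-validation and
prediction errors — a deliberate fidelity choice, see the README.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import Spectrum

__all__ = [
    "PLSModel",
    "UnivariateModel",
    "EvaluationMetrics",
    "pls_fit",
    "pls_predict",
    "cross_validate",
    "select_n_factors",
    "rmse_eq1",
    "r_squared_eq2",
    "lod_eq3",
    "baseline_sd",
    "peak_height",
    "peak_area",
    "univariate_fit",
    "POTASSIUM_PEAKS_NM",
]

#: K I resonance doublet used for quantification.
POTASSIUM_PEAKS_NM = (766.57, 769.95)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse_eq1(actual: np.ndarray, predicted: np.ndarray) -> float:
    """sqrt( sum((actual - predicted)^2) / (m - 1) ).

    Note the ``m - 1`` denominator; this definition is applied uniformly to
    cross-validation (RMSECV) and prediction (RMSEP) errors.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.ndim != 1:
        raise ValueError("actual and predicted must be 1-D of equal length")
    m = actual.size
    if m < 2:
        raise ValueError("need at least 2 points (m - 1 denominator)")
    return float(np.sqrt(np.sum((actual - predicted) ** 2) / (m - 1)))


def r_squared_eq2(actual: np.ndarray, predicted: np.ndarray) -> float:
    """1 - SSE/SST; may be negative for models worse than the mean."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.ndim != 1:
        raise ValueError("actual and predicted must be 1-D of equal length")
    sst = float(np.sum((actual - actual.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("actual values have zero variance")
    sse = float(np.sum((actual - predicted) ** 2))
    return 1.0 - sse / sst


def lod_eq3(sd_blank: float, slope: float) -> float:
    """Limit of detection, 3.3 * SD_blank / |slope|."""
    if sd_blank < 0:
        raise ValueError("sd_blank must be >= 0")
    if slope == 0:
        raise ValueError("zero calibration slope")
    return 3.3 * sd_blank / abs(slope)


@dataclass(frozen=True)
class EvaluationMetrics:
    """Bundle of the evaluation quantities, all in concentration units
    except the dimensionless R^2."""

    rmsecv: float | None = None
    rmsep: float | None = None
    r_squared: float | None = None
    lod: float | None = None

    def __post_init__(self) -> None:
        for name in ("rmsecv", "rmsep"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.r_squared is not None and self.r_squared > 1:
            raise ValueError("r_squared cannot exceed 1")


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

def _nipals(xc: np.ndarray, yc: np.ndarray, a: int):
    """Centered single-y NIPALS. Returns (W, P, q) with orthogonal scores."""
    n, p = xc.shape
    w_mat = np.empty((p, a))
    p_mat = np.empty((p, a))
    q_vec = np.empty(a)
    x = xc.copy()
    y = yc.copy()
    scale = np.linalg.norm(x) * np.linalg.norm(y) + np.finfo(float).tiny
    for i in range(a):
        w = x.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-13 * scale:
            raise ValueError(
                f"PLS factor {i + 1}: no remaining covariance between X and y"
            )
        w /= nw
        t = x @ w
        tt = float(t @ t)
        if tt < 1e-26 * float(np.sum(x * x) + np.finfo(float).tiny):
            raise ValueError(f"PLS factor {i + 1}: degenerate score vector")
        pv = x.T @ t / tt
        q = float(y @ t) / tt
        x -= np.outer(t, pv)
        y = y - q * t
        w_mat[:, i] = w
        p_mat[:, i] = pv
        q_vec[i] = q
    return w_mat, p_mat, q_vec


def _pls_beta(w_mat: np.ndarray, p_mat: np.ndarray, q_vec: np.ndarray) -> np.ndarray:
    ptw = p_mat.T @ w_mat
    return w_mat @ np.linalg.solve(ptw, q_vec)


@dataclass
class PLSModel:
    """Fitted mean-centered PLS model; prediction is affine in X."""

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    weights: np.ndarray = field(repr=False, default=None)
    loadings: np.ndarray = field(repr=False, default=None)
    y_loadings: np.ndarray = field(repr=False, default=None)
    rmsecv_path: np.ndarray | None = field(repr=False, default=None)

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        if x_new.shape[1] != self.x_mean.size:
            raise ValueError(
                f"expected {self.x_mean.size} variables, got {x_new.shape[1]}"
            )
        return x_new @ self.coef + self.intercept


def pls_fit(x: np.ndarray, y: np.ndarray, n_factors: int) -> PLSModel:
    """Fit PLS with ``n_factors`` latent factors (deterministic, no
    randomness, mean-centering only)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of samples")
    if not 1 <= n_factors <= min(n - 1, p):
        raise ValueError(
            f"n_factors must be in [1, {min(n - 1, p)}], got {n_factors}"
        )
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    xc = x - x_mean
    if np.all(xc == 0.0):
        raise ValueError("degenerate X: all columns constant")
    w_mat, p_mat, q_vec = _nipals(xc, y - y_mean, n_factors)
    coef = _pls_beta(w_mat, p_mat, q_vec)
    return PLSModel(
        n_factors=n_factors,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef,
        weights=w_mat,
        loadings=p_mat,
        y_loadings=q_vec,
    )


def pls_predict(model: PLSModel, x_new: np.ndarray) -> np.ndarray:
    return model.predict(x_new)


def _fold_indices(
    n: int, scheme: str, k: int, seed: int | None
) -> list[np.ndarray]:
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    if scheme == "kfold":
        if not 2 <= k <= n:
            raise ValueError(f"k must be in [2, {n}]")
        perm = np.random.default_rng(seed).permutation(n)
        return [np.sort(f) for f in np.array_split(perm, k)]
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    scheme: str = "loo",
    k: int = 5,
    seed: int | None = 0,
    return_predictions: bool = False,
):
    """Out-of-fold PLS predictions assembled over all samples, scored with
    :func:`rmse_eq1`.  ``scheme`` is ``"loo"`` or ``"kfold"``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for cross-validation")
    folds = _fold_indices(n, scheme, k, seed)
    preds = np.empty(n)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        model = pls_fit(x[train], y[train], n_factors)
        preds[test_idx] = model.predict(x[test_idx])
    score = rmse_eq1(y, preds)
    if return_predictions:
        return score, preds
    return score


def select_n_factors(
    x: np.ndarray,
    y: np.ndarray,
    max_factors: int = 15,
    scheme: str = "loo",
    k: int = 5,
    seed: int | None = 0,
) -> tuple[int, np.ndarray]:
    """Pick the factor count minimizing RMSECV over ``1..max_factors``
    (ties go to the smaller count).  Returns (best_a, rmsecv_path)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    hi = min(max_factors, x.shape[0] - 2, x.shape[1])
    if hi < 1:
        raise ValueError("no feasible factor count")
    path = []
    for a in range(1, hi + 1):
        try:
            path.append(cross_validate(x, y, a, scheme=scheme, k=k, seed=seed))
        except ValueError:
            # covariance exhausted (e.g. noiseless data): stop the search
            break
    if not path:
        raise ValueError("no factor count could be cross-validated")
    path = np.asarray(path)
    return int(np.argmin(path)) + 1, path


# ---------------------------------------------------------------------------
# univariate peak calibration
# ---------------------------------------------------------------------------

def _window_slice(spectrum: Spectrum, lo: float, hi: float) -> np.ndarray:
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"window [{lo}, {hi}] nm contains no grid points")
    return idx


def peak_height(spectrum: Spectrum, center: float, half_width: float = 0.5) -> float:
    """Maximum intensity in ``[center - hw, center + hw]`` — robust to
    small peak shifts, unlike reading the nominal center point."""
    idx = _window_slice(spectrum, center - half_width, center + half_width)
    return float(spectrum.intensities[idx].max())


def _merge_windows(windows: list[tuple[float, float]]) -> list[tuple[float, float]]:
    windows = sorted(windows)
    merged = [windows[0]]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    return merged


def peak_area(
    spectrum: Spectrum,
    centers: Sequence[float],
    half_width: float = 0.5,
    baseline: str = "none",
) -> float:
    """Trapezoidal area over the peak windows; overlapping windows are
    merged.  ``baseline="linear_endpoints"`` subtracts the chord between
    each window's endpoints first."""
    if baseline not in ("none", "linear_endpoints"):
        raise ValueError(f"unknown baseline mode {baseline!r}")
    if not centers:
        raise ValueError("need at least one peak center")
    total = 0.0
    for lo, hi in _merge_windows([(c - half_width, c + half_width) for c in centers]):
        idx = _window_slice(spectrum, lo, hi)
        wl = spectrum.wavelengths[idx]
        it = spectrum.intensities[idx].copy()
        if baseline == "linear_endpoints" and idx.size > 1:
            chord = np.interp(wl, [wl[0], wl[-1]], [it[0], it[-1]])
            it -= chord
        total += float(np.trapezoid(it, wl))
    return total


def baseline_sd(
    spectrum: Spectrum,
    window: tuple[float, float],
    peak_windows: Sequence[tuple[float, float]] | None = None,
    peak_half_width: float = 0.5,
) -> float:
    """Sample standard deviation of intensities in a peak-free window.

    ``peak_windows`` defaults to the potassium doublet windows; a baseline
    window overlapping any of them is rejected.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must have lo < hi")
    if peak_windows is None:
        peak_windows = [
            (c - peak_half_width, c + peak_half_width) for c in POTASSIUM_PEAKS_NM
        ]
    for plo, phi in peak_windows:
        if lo <= phi and plo <= hi:
            raise ValueError(
                f"baseline window [{lo}, {hi}] overlaps peak window "
                f"[{plo}, {phi}]"
            )
    idx = _window_slice(spectrum, lo, hi)
    if idx.size < 2:
        raise ValueError("baseline window needs at least 2 grid points")
    return float(np.std(spectrum.intensities[idx], ddof=1))


@dataclass(frozen=True)
class UnivariateModel:
    """Ordinary least-squares line ``y = slope * x + intercept``.

    In the calibration-curve orientation, ``x`` is the concentration and
    ``y`` the peak feature, so ``slope`` is the quantity feeding the
    detection limit and concentrations are predicted by inverting the line.
    """

    slope: float
    intercept: float
    r_squared: float
    mode: str = "generic"

    def predict_feature(self, concentration: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(concentration, float) + self.intercept

    def predict_concentration(self, feature: np.ndarray) -> np.ndarray:
        if self.slope == 0:
            raise ValueError("zero slope: cannot invert calibration line")
        return (np.asarray(feature, float) - self.intercept) / self.slope


def univariate_fit(
    features: np.ndarray, y: np.ndarray, mode: str = "generic"
) -> UnivariateModel:
    """OLS of ``y`` on ``features`` with the usual R^2 on fitted values."""
    x = np.asarray(features, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate features: all values equal")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    if np.ptp(y) == 0:
        r2 = 1.0 if np.allclose(fitted, y) else 0.0
    else:
        r2 = r_squared_eq2(y, fitted)
    return UnivariateModel(
        slope=float(slope), intercept=float(intercept), r_squared=float(r2),
        mode=mode,
    )
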