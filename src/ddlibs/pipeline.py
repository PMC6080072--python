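"""End-to-end training, prediction and the method-comparison harness.

The full calibration chain is: normalize -> higher-density wavelet
transform -> bagged random-frog selection of the top coefficient(s) ->
PLS on the selected coefficients (one factor when a single coefficient is
kept).  ``compare_methods`` runs that chain next to univariate peak
calibration, raw-spectrum PLS, and the intermediate selector variants on a
shared validation set; ``compare_normalizations`` scores the five
normalization schemes under plain PLS.

Child seeds are fanned out from one master seed with a fixed counter
scheme, so adding one method never perturbs another's randomness.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import (
    POTASSIUM_PEAKS_NM,
    PLSModel,
    cross_validate,
    peak_area,
    peak_height,
    pls_fit,
    r_squared_eq2,
    rmse_eq1,
    select_n_factors,
    univariate_fit,
)
from .dataset import SpectraDataset
from .hdwt import load_filterbank, transform_dataset
from .preprocess import NormalizationMethod, NORMALIZATION_NAMES, normalize
from .selection import RFAParams, mrfa, rfa_run, select_top

__all__ = [
    "DDLIBSConfig",
    "DDLIBSModel",
    "MethodResult",
    "ComparisonReport",
    "METHOD_NAMES",
    "choose_scale",
    "ddlibs_train",
    "ddlibs_predict",
    "save_model",
    "load_model",
    "compare_methods",
    "compare_normalizations",
]

logger = logging.getLogger("ddlibs")

METHOD_NAMES = (
    "univariate_peak1",
    "univariate_peak2",
    "univariate_area",
    "pls_raw",
    "rfa_pls",
    "hdwt_rfa_pls",
    "ddlibs",
)

MODEL_FORMAT_VERSION = 1


def _child_seed(master: int, counter: int) -> int:
    """Fixed counter fan-out of the master seed."""
    return int(np.random.SeedSequence([master, counter]).generate_state(1)[0])


@dataclass(frozen=True)
class DDLIBSConfig:
    """Everything needed to train the full chain reproducibly."""

    normalization: NormalizationMethod = NormalizationMethod("mean")
    filter_name: str = "bi4"
    levels: int | None = 4  # None -> optimize by minimum RMSECV
    scale_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    boundary_mode: str = "zero"
    n_selected: int = 1  # coefficients kept after selection
    mrfa_runs: int = 50
    train_fraction: float = 0.7
    rfa_params: RFAParams = field(default_factory=lambda: RFAParams(n_iterations=200))
    selection_factors: int = 2  # PLS factors inside the frog search
    max_factors: int = 15  # cap for RMSECV-driven factor choice
    seed: int = 0


@dataclass
class DDLIBSModel:
    """A trained chain: transform geometry, selected coefficients, and the
    fitted PLS head."""

    normalization: NormalizationMethod
    filter_name: str
    levels: int
    boundary_mode: str
    selected_indices: np.ndarray
    pls: PLSModel
    wavelengths: np.ndarray
    training_metrics: dict = field(default_factory=dict)

    @property
    def n_factors(self) -> int:
        return self.pls.n_factors


def choose_scale(
    cal: SpectraDataset,
    fb,
    scales: tuple[int, ...],
    n_factors: int,
    boundary_mode: str = "zero",
) -> tuple[int, dict[int, float]]:
    """Decomposition depth minimizing leave-one-out RMSECV of PLS on the
    full coefficient set; ties go to the smaller scale."""
    if not scales:
        raise ValueError("empty candidate scale list")
    if cal.concentrations is None:
        raise ValueError("calibration set has no concentrations")
    scores: dict[int, float] = {}
    for j in sorted(scales):
        coeffs, _, _ = transform_dataset(cal.intensities, fb, j, boundary_mode)
        a = min(n_factors, cal.n_samples - 2, coeffs.shape[1])
        while a > 1:
            try:
                scores[j] = cross_validate(coeffs, cal.concentrations, a,
                                           scheme="loo")
                break
            except ValueError:
                a -= 1  # covariance exhausted in some fold: fewer factors
        else:
            scores[j] = cross_validate(coeffs, cal.concentrations, 1,
                                       scheme="loo")
        logger.info("scale %d: %d coefficients, RMSECV %.5g",
                    j, coeffs.shape[1], scores[j])
    best = min(scores, key=lambda j: (scores[j], j))
    return best, scores


def ddlibs_train(cal: SpectraDataset, config: DDLIBSConfig) -> DDLIBSModel:
    """Train the full chain on a calibration set with concentrations."""
    if cal.concentrations is None:
        raise ValueError("calibration set has no concentrations")
    fb = load_filterbank(config.filter_name)
    normed = normalize(cal, config.normalization)
    y = cal.concentrations

    if config.levels is None:
        levels, _ = choose_scale(
            normed, fb, config.scale_candidates,
            min(5, config.max_factors), config.boundary_mode,
        )
    else:
        levels = config.levels
    coeffs, index_map, _ = transform_dataset(
        normed.intensities, fb, levels, config.boundary_mode
    )
    logger.info("training: %d samples -> %d coefficients at scale %d",
                coeffs.shape[0], coeffs.shape[1], levels)

    result = mrfa(
        coeffs,
        y,
        config.selection_factors,
        n_runs=config.mrfa_runs,
        train_fraction=config.train_fraction,
        params=config.rfa_params,
        seed=_child_seed(config.seed, 0),
    )
    selected = select_top(result, config.n_selected)

    if config.n_selected == 1:
        n_factors = 1
    else:
        n_factors, _ = select_n_factors(
            coeffs[:, selected], y, max_factors=min(config.max_factors,
                                                   config.n_selected)
        )
    model_pls = pls_fit(coeffs[:, selected], y, n_factors)
    rmsecv = cross_validate(coeffs[:, selected], y, n_factors, scheme="loo")
    fitted = model_pls.predict(coeffs[:, selected])
    metrics = {
        "rmsecv": float(rmsecv),
        "r_squared_train": float(r_squared_eq2(y, fitted)),
        "selection_probability_max": float(result.probabilities.max()),
    }
    return DDLIBSModel(
        normalization=config.normalization,
        filter_name=config.filter_name,
        levels=levels,
        boundary_mode=config.boundary_mode,
        selected_indices=np.asarray(selected, dtype=int),
        pls=model_pls,
        wavelengths=cal.wavelengths.copy(),
        training_metrics=metrics,
    )


def _check_grid(model: DDLIBSModel, ds: SpectraDataset) -> None:
    if ds.wavelengths.size != model.wavelengths.size or not np.allclose(
        ds.wavelengths, model.wavelengths, atol=1e-9, rtol=0
    ):
        raise ValueError("dataset wavelength grid differs from training grid")


def ddlibs_predict(model: DDLIBSModel, ds: SpectraDataset) -> np.ndarray:
    """Predict concentrations: normalize -> transform -> selected
    coefficients -> PLS.  Pure function of model and data."""
    _check_grid(model, ds)
    fb = load_filterbank(model.filter_name)
    normed = normalize(ds, model.normalization)
    coeffs, _, _ = transform_dataset(
        normed.intensities, fb, model.levels, model.boundary_mode
    )
    return model.pls.predict(coeffs[:, model.selected_indices])


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: DDLIBSModel, path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "normalization": {
            "name": model.normalization.name,
            "reference_wavelength": model.normalization.reference_wavelength,
        },
        "filter_name": model.filter_name,
        "levels": model.levels,
        "boundary_mode": model.boundary_mode,
        "selected_indices": model.selected_indices.tolist(),
        "wavelengths": model.wavelengths.tolist(),
        "training_metrics": model.training_metrics,
        "pls": {
            "n_factors": model.pls.n_factors,
            "x_mean": model.pls.x_mean.tolist(),
            "y_mean": model.pls.y_mean,
            "coef": model.pls.coef.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> DDLIBSModel:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    pls = PLSModel(
        n_factors=payload["pls"]["n_factors"],
        x_mean=np.array(payload["pls"]["x_mean"]),
        y_mean=payload["pls"]["y_mean"],
        coef=np.array(payload["pls"]["coef"]),
    )
    return DDLIBSModel(
        normalization=NormalizationMethod(
            payload["normalization"]["name"],
            payload["normalization"]["reference_wavelength"],
        ),
        filter_name=payload["filter_name"],
        levels=payload["levels"],
        boundary_mode=payload["boundary_mode"],
        selected_indices=np.array(payload["selected_indices"], dtype=int),
        pls=pls,
        wavelengths=np.array(payload["wavelengths"]),
        training_metrics=payload["training_metrics"],
    )


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethodResult:
    method: str
    n_factors: int | None
    r_squared: float
    rmsep: float


@dataclass
class ComparisonReport:
    rows: list[MethodResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": r.method,
                    "n_factors": r.n_factors,
                    "r_squared": r.r_squared,
                    "rmsep": r.rmsep,
                }
                for r in self.rows
            ]
        )

    def __getitem__(self, method: str) -> MethodResult:
        for r in self.rows:
            if r.method == method:
                return r
        raise KeyError(method)


def _univariate_result(
    method: str,
    cal: SpectraDataset,
    val: SpectraDataset,
) -> MethodResult:
    def feature(ds: SpectraDataset) -> np.ndarray:
        if method == "univariate_peak1":
            return np.array(
                [peak_height(ds.spectrum(i), POTASSIUM_PEAKS_NM[0])
                 for i in range(ds.n_samples)]
            )
        if method == "univariate_peak2":
            return np.array(
                [peak_height(ds.spectrum(i), POTASSIUM_PEAKS_NM[1])
                 for i in range(ds.n_samples)]
            )
        return np.array(
            [peak_area(ds.spectrum(i), POTASSIUM_PEAKS_NM)
             for i in range(ds.n_samples)]
        )

    # calibration-curve orientation: feature regressed on concentration,
    # inverted for prediction
    uni = univariate_fit(cal.concentrations, feature(cal), mode=method)
    pred = uni.predict_concentration(feature(val))
    return MethodResult(
        method=method,
        n_factors=None,
        r_squared=r_squared_eq2(val.concentrations, pred),
        rmsep=rmse_eq1(val.concentrations, pred),
    )


def _frequency_subset(freq: np.ndarray) -> np.ndarray:
    """Above-mean-frequency retention rule for single-run frog selection."""
    keep = np.flatnonzero(freq > freq.mean())
    if keep.size == 0:
        keep = np.array([int(np.argmax(freq))])
    return keep


def _pls_result(
    method: str,
    x_cal: np.ndarray,
    y_cal: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    max_factors: int,
) -> MethodResult:
    a, _ = select_n_factors(x_cal, y_cal, max_factors=max_factors)
    model = pls_fit(x_cal, y_cal, a)
    pred = model.predict(x_val)
    return MethodResult(
        method=method,
        n_factors=a,
        r_squared=r_squared_eq2(y_val, pred),
        rmsep=rmse_eq1(y_val, pred),
    )


def compare_methods(
    cal: SpectraDataset,
    val: SpectraDataset,
    config: DDLIBSConfig = DDLIBSConfig(),
    methods: tuple[str, ...] = METHOD_NAMES,
) -> ComparisonReport:
    """Run the requested methods under a shared normalization and seed
    policy, scoring every one on the validation set."""
    if cal.concentrations is None or val.concentrations is None:
        raise ValueError("both sets need concentrations")
    if not np.allclose(cal.wavelengths, val.wavelengths, atol=1e-9, rtol=0):
        raise ValueError("calibration and validation grids differ")
    unknown = set(methods) - set(METHOD_NAMES)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}")

    cal_n = normalize(cal, config.normalization)
    val_n = normalize(val, config.normalization)
    y_cal, y_val = cal.concentrations, val.concentrations
    fb = load_filterbank(config.filter_name)
    levels = config.levels if config.levels is not None else 4

    rows: list[MethodResult] = []
    for method in methods:
        logger.info("comparison: running %s", method)
        if method.startswith("univariate"):
            rows.append(_univariate_result(method, cal_n, val_n))
        elif method == "pls_raw":
            rows.append(
                _pls_result(method, cal_n.intensities, y_cal,
                            val_n.intensities, y_val, config.max_factors)
            )
        elif method == "rfa_pls":
            freq = rfa_run(
                cal_n.intensities, y_cal, config.selection_factors,
                config.rfa_params, _child_seed(config.seed, 101),
            )
            keep = _frequency_subset(freq)
            rows.append(
                _pls_result(method, cal_n.intensities[:, keep], y_cal,
                            val_n.intensities[:, keep], y_val,
                            config.max_factors)
            )
        elif method == "hdwt_rfa_pls":
            xc, _, _ = transform_dataset(
                cal_n.intensities, fb, levels, config.boundary_mode
            )
            xv, _, _ = transform_dataset(
                val_n.intensities, fb, levels, config.boundary_mode
            )
            freq = rfa_run(
                xc, y_cal, config.selection_factors,
                config.rfa_params, _child_seed(config.seed, 102),
            )
            keep = _frequency_subset(freq)
            rows.append(
                _pls_result(method, xc[:, keep], y_cal, xv[:, keep], y_val,
                            config.max_factors)
            )
        else:  # ddlibs
            model = ddlibs_train(cal, replace(config, levels=levels))
            pred = ddlibs_predict(model, val)
            rows.append(
                MethodResult(
                    method=method,
                    n_factors=model.n_factors,
                    r_squared=r_squared_eq2(y_val, pred),
                    rmsep=rmse_eq1(y_val, pred),
                )
            )
    return ComparisonReport(rows=rows)


def compare_normalizations(
    cal: SpectraDataset,
    val: SpectraDataset,
    methods: tuple[NormalizationMethod, ...] | None = None,
    reference_wavelength: float | None = None,
    max_factors: int = 15,
) -> tuple[pd.DataFrame, str]:
    """Fit one plain PLS model per normalization scheme, score RMSEP on the
    validation set, and return (table, argmin method name)."""
    if methods is None:
        from .preprocess import CARBON_REFERENCE_NM

        ref = (
            reference_wavelength
            if reference_wavelength is not None
            else CARBON_REFERENCE_NM
        )
        methods = tuple(
            NormalizationMethod(n) if n != "reference_line"
            else NormalizationMethod(n, ref)
            for n in NORMALIZATION_NAMES
        )
    seen: list[NormalizationMethod] = []
    for m in methods:
        if m in seen:
            warnings.warn(f"duplicate normalization {m.name!r} ignored",
                          stacklevel=2)
        else:
            seen.append(m)

    records = []
    for m in seen:
        cal_n = normalize(cal, m)
        val_n = normalize(val, m)
        a, _ = select_n_factors(cal_n.intensities, cal.concentrations,
                                max_factors=max_factors)
        model = pls_fit(cal_n.intensities, cal.concentrations, a)
        pred = model.predict(val_n.intensities)
        records.append(
            {
                "normalization": m.name,
                "n_factors": a,
                "rmsep": rmse_eq1(val.concentrations, pred),
                "r_squared": r_squared_eq2(val.concentrations, pred),
            }
        )
    table = pd.DataFrame(records)
    best = table.loc[table["rmsep"].idxmin(), "normalization"]
    return table, str(best)
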