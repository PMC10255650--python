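"""Trait retrieval from plot spectra.

Two retrieval routes are implemented under one protocol:

* parametric: every (vegetation-index band assignment x function family)
  candidate is fitted by least squares and ranked by ten-fold
  cross-validated nRMSE on the training set;
* nonparametric: PLSR, random-forest, kernel-ridge and Gaussian-process
  regression over all sensor bands, hyperparameters picked by the same
  cross-validated nRMSE.

The data are split once into 2/3 training (bare-soil samples included) and
1/3 validation; the validation third never influences fitting or model
selection and is only used for the final report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF
from sklearn.compose import TransformedTargetRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.preprocessing import StandardScaler

from .indices import (BandAssignment, FAMILIES, compute_index_matrix,
                      enumerate_assignments)
from .metrics import EvalReport, evaluate, kfold_indices
from .sensors import SensorDef, band_column

log = logging.getLogger(__name__)

FUNCTION_FAMILIES = ("linear", "polynomial", "logarithmic", "exponential",
                     "power")
ML_METHODS = ("plsr", "rfr", "krr", "gpr")

#: traits whose retrieved values are physically non-negative
NONNEGATIVE_TRAITS = {"GY", "LAI", "LCC"}


@dataclass
class DataSplit:
    """Train/validation membership (positional indices), fixed per run."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    seed: int
    fraction: float

    @property
    def n(self) -> int:
        return len(self.train_idx) + len(self.val_idx)


def split_data(n: int, fraction: float = 2.0 / 3.0,
               seed: int = 0) -> DataSplit:
    """Random split into ceil(fraction*n) training / remainder validation."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if n < 9:
        raise ValueError("need at least 9 samples to split")
    n_train = int(np.ceil(fraction * n))
    order = np.random.default_rng(seed).permutation(n)
    return DataSplit(train_idx=np.sort(order[:n_train]),
                     val_idx=np.sort(order[n_train:]),
                     seed=seed, fraction=fraction)


# ---------------------------------------------------------------------------
# Parametric route

@dataclass
class FunctionFit:
    """Least-squares fit of one function family to (index, trait) pairs."""

    family: str
    coef: tuple[float, ...]
    ok: bool = True
    reason: str = ""
    n_dropped: int = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, np.nan)
        with np.errstate(all="ignore"):
            if self.family == "linear":
                a, b = self.coef
                out = a + b * x
            elif self.family == "polynomial":
                a, b, c = self.coef
                out = a + b * x + c * x ** 2
            elif self.family == "logarithmic":
                a, b = self.coef
                pos = x > 0
                out[pos] = a + b * np.log(x[pos])
            elif self.family == "exponential":
                a, b = self.coef
                out = a * np.exp(b * x)
            elif self.family == "power":
                a, b = self.coef
                pos = x > 0
                out[pos] = a * np.power(x[pos], b)
        return out

    @property
    def n_params(self) -> int:
        return len(self.coef)


def fit_parametric(x, y, family: str) -> FunctionFit:
    """Fit one function family by (possibly log-linearized) least squares.

    Power and exponential families are fitted in log space; points outside
    the family's domain (non-positive x and/or y) are dropped and counted.
    A singular or under-determined system yields a flagged non-model rather
    than an exception.
    """
    if family not in FUNCTION_FAMILIES:
        raise ValueError(f"unknown function family {family!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if family in ("logarithmic", "power"):
        keep &= x > 0
    if family in ("exponential", "power"):
        keep &= y > 0
    n_dropped = int(np.sum(np.isfinite(x) & np.isfinite(y)) - keep.sum())
    if n_dropped:
        log.debug("%s fit: dropped %d out-of-domain points", family, n_dropped)
    xv, yv = x[keep], y[keep]
    n_coef = 3 if family == "polynomial" else 2
    if xv.size < n_coef + 1:
        return FunctionFit(family, (), ok=False, n_dropped=n_dropped,
                           reason=f"only {xv.size} usable points")
    if np.ptp(xv) == 0:
        return FunctionFit(family, (), ok=False, n_dropped=n_dropped,
                           reason="constant predictor")
    try:
        if family == "linear":
            b, a = np.polyfit(xv, yv, 1)
            coef = (float(a), float(b))
        elif family == "polynomial":
            c, b, a = np.polyfit(xv, yv, 2)
            coef = (float(a), float(b), float(c))
        elif family == "logarithmic":
            b, a = np.polyfit(np.log(xv), yv, 1)
            coef = (float(a), float(b))
        elif family == "exponential":
            b, la = np.polyfit(xv, np.log(yv), 1)
            coef = (float(np.exp(la)), float(b))
        else:  # power
            b, la = np.polyfit(np.log(xv), np.log(yv), 1)
            coef = (float(np.exp(la)), float(b))
    except np.linalg.LinAlgError as exc:
        return FunctionFit(family, (), ok=False, n_dropped=n_dropped,
                           reason=f"singular system: {exc}")
    return FunctionFit(family, coef, n_dropped=n_dropped)


@dataclass
class ParametricFit:
    """A fitted (index, function) retrieval model with its reports."""

    trait: str
    assignment: BandAssignment
    function: FunctionFit
    cv: EvalReport
    validation: EvalReport | None = None

    @property
    def label(self) -> str:
        return f"{self.assignment.label()}/{self.function.family}"

    def index_values(self, samples: pd.DataFrame) -> np.ndarray:
        bands = {b: samples[band_column(b)].to_numpy()
                 for b in self.assignment.bands}
        return compute_index_matrix(self.assignment, bands)

    def predict(self, samples: pd.DataFrame) -> np.ndarray:
        return self.function.predict(self.index_values(samples))


def _cv_predict_parametric(x, y, folds, family):
    pred = np.full(y.shape, np.nan)
    for f in np.unique(folds):
        hold = folds == f
        fit = fit_parametric(x[~hold], y[~hold], family)
        if not fit.ok:
            return None
        pred[hold] = fit.predict(x[hold])
    return pred


def _safe_eval(y, pred, n_params=None) -> EvalReport | None:
    ok = np.isfinite(pred)
    if ok.sum() < max(3, int(0.9 * len(y))):
        return None  # too many undefined predictions to rank fairly
    try:
        return evaluate(y[ok], pred[ok], n_params)
    except ValueError:
        return None


def search_parametric(
    samples: pd.DataFrame,
    trait: str,
    sensor: SensorDef,
    split: DataSplit,
    families: Sequence[str] | None = None,
    functions: Sequence[str] = FUNCTION_FAMILIES,
    k: int = 10,
    seed: int = 0,
) -> list[ParametricFit]:
    """Exhaustive (band assignment x function) search ranked by CV nRMSE.

    ``samples`` must carry the sensor band columns, the target ``trait``
    column and an ``is_soil`` column.  Returns candidates ranked ascending
    by cross-validated nRMSE; the winner additionally carries a validation
    report on the held-out third.
    """
    assignments = enumerate_assignments(
        list(families) if families else list(FAMILIES), sensor)
    y_all = samples[trait].to_numpy(dtype=float)
    band_values = {b: samples[band_column(b)].to_numpy(dtype=float)
                   for b in sensor.band_centers}
    tr = split.train_idx
    y_tr = y_all[tr]
    folds = kfold_indices(len(tr), k=k, seed=seed,
                          strata=samples["is_soil"].to_numpy()[tr])
    results: list[ParametricFit] = []
    for assignment in assignments:
        x_all = compute_index_matrix(assignment, band_values)
        x_tr = x_all[tr]
        if not np.isfinite(x_tr).any():
            continue
        for func in functions:
            pred = _cv_predict_parametric(x_tr, y_tr, folds, func)
            if pred is None:
                continue
            cv = _safe_eval(y_tr, pred)
            if cv is None:
                continue
            fit = fit_parametric(x_tr, y_tr, func)
            if not fit.ok:
                continue
            results.append(ParametricFit(trait, assignment, fit, cv))
    if not results:
        raise RuntimeError(
            f"no parametric candidate could be fitted for {trait!r}"
        )
    results.sort(key=lambda m: m.cv.nrmse)
    best = results[0]
    y_val = y_all[split.val_idx]
    pred_val = best.predict(samples.iloc[split.val_idx])
    best.validation = _safe_eval(y_val, pred_val,
                                 n_params=best.function.n_params)
    return results


# ---------------------------------------------------------------------------
# Nonparametric route

DEFAULT_GRIDS: dict[str, dict[str, tuple]] = {
    "plsr": {"n_components": tuple(range(1, 11))},
    "rfr": {"n_estimators": (100, 500), "max_depth": (None, 10)},
    "krr": {"alpha": tuple(10.0 ** np.arange(-6, 1)),
            "gamma": tuple(10.0 ** np.arange(-3, 4))},
    "gpr": {"length_scale": tuple(10.0 ** np.arange(-2.0, 3.0)),
            "alpha": tuple(10.0 ** np.arange(-7, -1))},
}


def _make_estimator(method: str, params: Mapping, n_bands: int, seed: int):
    if method == "plsr":
        return PLSRegression(
            n_components=min(params["n_components"], n_bands))
    if method == "rfr":
        return RandomForestRegressor(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"], random_state=seed)
    if method == "krr":
        # kernel ridge has no intercept; centre/scale the target so the
        # heavy-regularization limit shrinks toward the training mean
        return TransformedTargetRegressor(
            regressor=KernelRidge(kernel="rbf", alpha=params["alpha"],
                                  gamma=params["gamma"]),
            transformer=StandardScaler())
    if method == "gpr":
        # fixed-kernel GPR: hyperparameters come from the CV grid, not the
        # marginal-likelihood optimizer, so selection mirrors the other methods
        return GaussianProcessRegressor(
            kernel=RBF(length_scale=params["length_scale"]),
            alpha=params["alpha"], normalize_y=True, optimizer=None)
    raise ValueError(f"unknown method {method!r}; choose from {ML_METHODS}")


@dataclass
class MLFit:
    """A fitted machine-learning retrieval model with its reports."""

    trait: str
    method: str
    params: dict
    estimator: object
    bands: tuple[float, ...]
    cv: EvalReport
    validation: EvalReport | None = None
    grid_cv: list[tuple[dict, float]] = field(default_factory=list)

    @property
    def label(self) -> str:
        return self.method.upper()

    def _x(self, samples: pd.DataFrame) -> np.ndarray:
        return samples[[band_column(b) for b in self.bands]].to_numpy(float)

    def predict(self, samples: pd.DataFrame,
                return_std: bool = False):
        X = self._x(samples)
        if return_std:
            if self.method != "gpr":
                raise ValueError("predictive SD is only available for GPR")
            return self.estimator.predict(X, return_std=True)
        pred = self.estimator.predict(X)
        return np.asarray(pred).ravel()

    @property
    def n_params(self) -> int:
        # AIC parameter-count proxy for ML models: tuned hyperparameters + 1
        return len(self.params) + 1


def fit_nonparametric(
    samples: pd.DataFrame,
    trait: str,
    sensor: SensorDef,
    split: DataSplit,
    method: str,
    grid: Mapping[str, Sequence] | None = None,
    k: int = 10,
    seed: int = 0,
) -> MLFit:
    """Grid-search one ML method by k-fold CV nRMSE, then refit and validate.

    Hyperparameters are chosen only from cross-validation on the training
    set; the selected model is refitted on the full training set and scored
    once on the held-out validation third.
    """
    method = method.lower()
    if method not in ML_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {ML_METHODS}")
    grid = dict(grid or DEFAULT_GRIDS[method])
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid must be non-empty")
    bands = sensor.band_centers
    cols = [band_column(b) for b in bands]
    X_all = samples[cols].to_numpy(float)
    y_all = samples[trait].to_numpy(float)
    tr, va = split.train_idx, split.val_idx
    folds = kfold_indices(len(tr), k=k, seed=seed,
                          strata=samples["is_soil"].to_numpy()[tr])
    X_tr, y_tr = X_all[tr], y_all[tr]

    keys = sorted(grid)
    best: tuple[float, dict] | None = None
    grid_cv = []
    for combo in product(*(grid[k_] for k_ in keys)):
        params = dict(zip(keys, combo))
        pred = np.empty_like(y_tr)
        try:
            for f in np.unique(folds):
                hold = folds == f
                est = _make_estimator(method, params, len(bands), seed)
                est.fit(X_tr[~hold], y_tr[~hold])
                pred[hold] = np.asarray(est.predict(X_tr[hold])).ravel()
            score = evaluate(y_tr, pred).nrmse
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.debug("grid point %s failed: %s", params, exc)
            continue
        grid_cv.append((params, score))
        if best is None or score < best[0]:
            best = (score, params)
    if best is None:
        raise RuntimeError(f"all {method} grid points failed for {trait!r}")

    params = best[1]
    # CV report at the winning grid point (pooled out-of-fold predictions)
    pred = np.empty_like(y_tr)
    for f in np.unique(folds):
        hold = folds == f
        est = _make_estimator(method, params, len(bands), seed)
        est.fit(X_tr[~hold], y_tr[~hold])
        pred[hold] = np.asarray(est.predict(X_tr[hold])).ravel()
    cv_report = evaluate(y_tr, pred)

    final = _make_estimator(method, params, len(bands), seed)
    final.fit(X_tr, y_tr)
    fit = MLFit(trait=trait, method=method, params=params, estimator=final,
                bands=bands, cv=cv_report, grid_cv=grid_cv)
    pred_val = fit.predict(samples.iloc[va])
    fit.validation = evaluate(y_all[va], pred_val, n_params=fit.n_params)
    return fit


def gpr_uncertainty_summary(fit: MLFit, samples: pd.DataFrame) -> float:
    """Mean relative predictive uncertainty, 100 * SD / prediction, in %.

    The summary describes vegetation retrievals: bare-soil samples (whose
    target and prediction sit at zero, making a relative measure
    meaningless) and samples with a zero predicted value are excluded, with
    counts logged.  This convention (mean coefficient of variation of the
    predictive distribution over vegetated plots) is this package's
    definition.
    """
    if fit.method != "gpr":
        raise ValueError("uncertainty summary requires a GPR fit")
    if "is_soil" in samples.columns:
        n_soil = int(samples["is_soil"].astype(bool).sum())
        if n_soil:
            log.info("uncertainty summary: excluded %d soil samples", n_soil)
        samples = samples[~samples["is_soil"].astype(bool)]
    pred, sd = fit.predict(samples, return_std=True)
    pred = np.asarray(pred).ravel()
    nonzero = pred != 0
    if (~nonzero).any():
        log.info("uncertainty summary: excluded %d zero predictions",
                 int((~nonzero).sum()))
    if not nonzero.any():
        raise ValueError("all predictions are zero; relative uncertainty "
                         "undefined")
    return float(np.mean(100.0 * sd[nonzero] / np.abs(pred[nonzero])))


def apply_model(fit: ParametricFit | MLFit,
                spectra: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted model to plot spectra; returns plot_id + retrieved value.

    Physically non-negative traits (GY, LAI, LCC) are clipped at zero with
    a log entry.  Soil samples (empty plot_id) are passed through unchanged.
    """
    needed = [band_column(b) for b in
              (fit.assignment.bands if isinstance(fit, ParametricFit)
               else fit.bands)]
    missing = [c for c in needed if c not in spectra.columns]
    if missing:
        raise ValueError(f"spectra table lacks band column(s) {missing}")
    pred = np.asarray(fit.predict(spectra), dtype=float).ravel()
    if fit.trait in NONNEGATIVE_TRAITS:
        neg = pred < 0
        if neg.any():
            log.info("clipped %d negative retrieved %s values to 0",
                     int(neg.sum()), fit.trait)
            pred = np.where(neg, 0.0, pred)
    out = spectra[["sample_id", "plot_id"]].copy()
    out[fit.trait] = pred
    return out


def build_dataset(spectra: pd.DataFrame, plots: pd.DataFrame,
                  trait: str) -> pd.DataFrame:
    """Join spectra with the target trait; soil samples get target 0."""
    merged = spectra.merge(
        plots[["plot_id", trait]], on="plot_id", how="left")
    soil = merged["is_soil"].astype(bool)
    merged.loc[soil, trait] = 0.0
    if merged[trait].isna().any():
        bad = merged.loc[merged[trait].isna(), "sample_id"].tolist()[:5]
        raise ValueError(f"samples without a target value, e.g. {bad}")
    return merged
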