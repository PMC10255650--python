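"""Goodness-of-fit metrics and k-fold machinery.

Conventions: R2 is the squared Pearson correlation between observed and
predicted (so it can exceed NSE for biased predictions); nRMSE normalizes
RMSE by the observed range and rRMSE by the observed mean, both in percent;
NSE = 1 - SSE/SST about the observed mean; AIC = n*ln(SSE/n) + 2k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EvalReport:
    n: int
    r2: float
    rmse: float
    nrmse: float        # percent of observed range
    rrmse: float        # percent of observed mean
    nse: float
    aic: float | None = None
    range_normalizer: float = float("nan")
    mean_normalizer: float = float("nan")

    def as_dict(self, prefix: str = "") -> dict[str, float]:
        d = {"n": self.n, "R2": self.r2, "RMSE": self.rmse,
             "nRMSE": self.nrmse, "rRMSE": self.rrmse, "NSE": self.nse}
        if self.aic is not None:
            d["AIC"] = self.aic
        return {prefix + k: v for k, v in d.items()}


def evaluate(observed, predicted, n_params: int | None = None) -> EvalReport:
    """Compute R2, RMSE, nRMSE, rRMSE, NSE and (optionally) AIC.

    ``n_params`` is the parameter count entering AIC; when omitted AIC is
    not reported.  Observed values must not be all equal (NSE undefined).
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} vs {p.shape}")
    if o.size < 2:
        raise ValueError("need at least 2 observations")
    # wildly diverging candidates (e.g. exploding exponentials) may overflow
    # to inf here; they simply rank last, so the overflow is benign
    with np.errstate(over="ignore"):
        sse = float(np.sum((o - p) ** 2))
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values are all equal; NSE undefined")
    rmse = float(np.sqrt(sse / o.size))
    rng = float(o.max() - o.min())
    mean = float(o.mean())
    with np.errstate(invalid="ignore", over="ignore"):
        r = np.corrcoef(o, p)[0, 1]
    r2 = float(r * r) if np.isfinite(r) else 0.0
    aic = None
    if n_params is not None:
        # SSE == 0 (perfect fit) would send ln to -inf; floor it
        aic = float(o.size * np.log(max(sse, 1e-300) / o.size) + 2 * n_params)
    return EvalReport(
        n=int(o.size),
        r2=r2,
        rmse=rmse,
        nrmse=100.0 * rmse / rng,
        rrmse=100.0 * rmse / mean if mean != 0 else float("inf"),
        nse=1.0 - sse / sst,
        aic=aic,
        range_normalizer=rng,
        mean_normalizer=mean,
    )


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100*sd/mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def kfold_indices(n: int, k: int = 10,
                  seed: int | np.random.Generator = 0,
                  strata=None) -> np.ndarray:
    """Fold assignment (length n, values 0..k-1); folds differ by <= 1.

    If ``strata`` is given (array of labels), each stratum is spread as
    evenly as possible across folds — used to keep bare-soil samples from
    concentrating in one fold.
    """
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    if strata is None:
        order = rng.permutation(n)
        assign[order] = np.arange(n) % k
    else:
        strata = np.asarray(strata)
        offset = 0
        for s in np.unique(strata):
            idx = np.flatnonzero(strata == s)
            order = rng.permutation(idx)
            assign[order] = (np.arange(idx.size) + offset) % k
            offset += idx.size
    return assign
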