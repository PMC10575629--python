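"""Follicle growth modelling: LOESS smoothing and the piecewise allometric model.

Follicle volume grows allometrically with nurse-cell DNA content, but the
scaling changes twice during oogenesis: at nurse-cell chromatin dispersion
(stage 6) and at the onset of vitellogenesis (stage 8).  The model is a
multiple linear regression with two condition indicators,

    log10 V = a0*x + a1*x*c1 + a2*x*c2 + b0 + b1*c1 + b2*c2,

where x is log2 normalized DNA content, c1 = [stage >= 6] and
c2 = [stage >= 8].  The indicators are independent (a stage-9 follicle has
c1 = c2 = 1), so b1/b2 and a1/a2 are incremental intercept and slope
shifts.  LOESS (span 0.75, degree 2, tricube weights) provides a
model-free smooth of the same data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("gscpipe")

COEF_NAMES = ("a0", "a1", "a2", "b0", "b1", "b2")

#: Fitted coefficients of the reference dataset (log10 volume units;
#: slopes in log10 volume per log2 DNA).
REFERENCE_COEFFICIENTS = {
    "b0": 3.47678, "a0": 0.23343, "b1": -0.13196,
    "b2": 1.45582, "a1": 0.05044, "a2": -0.13115,
}


def stage_conditions(stage) -> tuple[np.ndarray, np.ndarray]:
    """Condition indicators for stages 1-10.

    condition1 marks follicles at or after nurse-cell chromatin dispersion
    (stages 6-10); condition2 marks follicles at or after the onset of
    vitellogenesis (stages 8-10).
    """
    stage = np.asarray(stage)
    if np.any((stage < 1) | (stage > 10)):
        bad = stage[(stage < 1) | (stage > 10)]
        raise ValueError(f"stage outside 1-10: {np.unique(bad).tolist()}")
    return (stage >= 6).astype(float), (stage >= 8).astype(float)


@dataclass
class GrowthFit:
    """OLS fit of the two-condition piecewise allometric model."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    n: int
    residual_sd: float

    def coef_array(self) -> np.ndarray:
        return np.array([self.coefficients[k] for k in COEF_NAMES])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": [self.coefficients[k] for k in COEF_NAMES],
            "std_error": [self.standard_errors[k] for k in COEF_NAMES],
        }, index=list(COEF_NAMES))


def _design_matrix(stage, log2_dna) -> np.ndarray:
    x = np.asarray(log2_dna, dtype=float)
    c1, c2 = stage_conditions(stage)
    return np.column_stack([x, x * c1, x * c2, np.ones_like(x), c1, c2])


def fit_growth_model(records: pd.DataFrame) -> GrowthFit:
    """Fit the six-parameter model by ordinary least squares.

    ``records`` needs columns stage, log2_dna, log10_volume; stages above
    10 are excluded with a logged count (the condition definitions cover
    stages 1-10 only).
    """
    records = records.copy()
    over = records["stage"] > 10
    if over.any():
        logger.info("fit_growth_model: excluding %d records at stage > 10",
                    int(over.sum()))
        records = records.loc[~over]
    if len(records) < 7:
        raise ValueError(f"need at least 7 records, got {len(records)}")
    X = _design_matrix(records["stage"], records["log2_dna"])
    y = records["log10_volume"].to_numpy(dtype=float)
    for j, name in enumerate(COEF_NAMES):
        if name in ("b1", "b2") and not X[:, j].any():
            raise ValueError(f"no records in the condition for {name} "
                             "(empty design cell)")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: a condition group is "
                         "empty or collinear")
    res = sm.OLS(y, X).fit()
    return GrowthFit(
        coefficients=dict(zip(COEF_NAMES, res.params)),
        standard_errors=dict(zip(COEF_NAMES, res.bse)),
        n=int(res.nobs),
        residual_sd=float(np.sqrt(res.mse_resid)),
    )


def predict_log_volume(fit: "GrowthFit | dict[str, float]", stage,
                       log2_dna) -> np.ndarray | float:
    """Model prediction a0*x + a1*x*c1 + a2*x*c2 + b0 + b1*c1 + b2*c2."""
    coefs = fit.coefficients if isinstance(fit, GrowthFit) else fit
    beta = np.array([coefs[k] for k in COEF_NAMES])
    X = _design_matrix(np.atleast_1d(stage), np.atleast_1d(log2_dna))
    out = X @ beta
    return float(out[0]) if np.isscalar(stage) or np.ndim(stage) == 0 else out


def loess_smooth(x, y, query=None, span: float = 0.75,
                 degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    At each query point the nearest ``ceil(span * n)`` data points are
    fit by weighted least squares with a degree-``degree`` polynomial and
    tricube weights ``(1 - (d/dmax)^3)^3`` on distance scaled by the
    neighbourhood radius.  No robustness iterations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = len(x)
    if n < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} points")
    if query is None:
        query = x
    query = np.atleast_1d(np.asarray(query, dtype=float))
    q = max(degree + 1, math.ceil(span * n))
    fitted = np.empty(len(query))
    for i, x0 in enumerate(query):
        d = np.abs(x - x0)
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = float(np.mean(y[idx]))
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.maximum(w, 0.0)
        deg = degree
        sw = np.sqrt(w)
        while True:
            # centred Vandermonde for conditioning
            V = np.vander(x[idx] - x0, deg + 1, increasing=True)
            beta, _, rank, _ = np.linalg.lstsq(V * sw[:, None], y[idx] * sw,
                                               rcond=None)
            if rank == deg + 1 or deg == 0:
                break
            deg -= 1
            warnings.warn("loess_smooth: locally degenerate design; "
                          "falling back to a lower polynomial degree")
        fitted[i] = beta[0]
    return fitted
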