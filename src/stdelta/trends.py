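"""Second-order polynomial regressions among annual indices and covariates.

Each annual index of distribution or abundance (biomass, northing, easting,
effective area occupied) is regressed on an annual covariate with an
ordinary least-squares quadratic y ~ 1 + x + x^2 (x centred), testing the
coefficients at alpha = 0.05.  When the quadratic term is not significant a
linear-only submodel is also reported.  No multiple-testing correction is
applied; batch output carries the number of tests run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["TrendFit", "fit_trend", "trend_table"]

ALPHA = 0.05


@dataclass
class TrendFit:
    """OLS quadratic fit of an annual index on an annual covariate.

    Coefficients refer to the centred predictor; ``vertex`` (the stationary
    point -b1/(2 b2), back on the original x scale) is reported only when
    the quadratic coefficient is significant at alpha = 0.05.
    """

    response: str
    predictor: str
    n: int
    coef: np.ndarray          # (b0, b1, b2) on centred x
    se: np.ndarray
    pvalues: np.ndarray
    r2: float
    x_center: float
    vertex: float | None = None
    linear: dict | None = None   # linear-only submodel when b2 not significant

    @property
    def quadratic_significant(self) -> bool:
        return bool(self.pvalues[2] < ALPHA)


def fit_trend(x, y, response: str = "y", predictor: str = "x") -> TrendFit:
    """OLS of y on (1, x, x^2) with x centred; t-test p-values at alpha=0.05."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 paired annual values")
    if np.var(x) == 0:
        raise ValueError("predictor has zero variance")
    xc = x - x.mean()
    X = sm.add_constant(np.column_stack([xc, xc**2]))
    res = sm.OLS(y, X).fit()
    coef = np.asarray(res.params)
    pv = np.asarray(res.pvalues)
    vertex = None
    if pv[2] < ALPHA and coef[2] != 0:
        vertex = float(-coef[1] / (2.0 * coef[2]) + x.mean())
    linear = None
    if pv[2] >= ALPHA:
        lres = sm.OLS(y, sm.add_constant(xc)).fit()
        linear = {
            "coef": np.asarray(lres.params).tolist(),
            "pvalues": np.asarray(lres.pvalues).tolist(),
            "r2": float(lres.rsquared),
        }
    return TrendFit(
        response=response, predictor=predictor, n=len(x),
        coef=coef, se=np.asarray(res.bse), pvalues=pv,
        r2=float(res.rsquared), x_center=float(x.mean()),
        vertex=vertex, linear=linear,
    )


def trend_table(annual: pd.DataFrame, responses, predictors) -> pd.DataFrame:
    """All response-by-predictor quadratic regressions from a year-by-series table.

    ``annual`` has a 'year' column plus one column per series.  The output
    records one row per (response, predictor) pair and carries the total
    number of tests in ``df.attrs['n_tests']`` (no multiplicity correction
    is applied).
    """
    rows = []
    for resp in responses:
        for pred in predictors:
            tf = fit_trend(annual[pred], annual[resp], response=resp, predictor=pred)
            rows.append({
                "response": resp, "predictor": pred, "n": tf.n,
                "b0": tf.coef[0], "b1": tf.coef[1], "b2": tf.coef[2],
                "p_b1": tf.pvalues[1], "p_b2": tf.pvalues[2],
                "r2": tf.r2, "vertex": tf.vertex,
                "quadratic_significant": tf.quadratic_significant,
            })
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(rows)
    return out
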