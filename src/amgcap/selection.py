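"""Link and family selection for cost GLMs.

Two complementary routes, used jointly:

* an information-criteria grid over the 12 (link, family) menu pairs;
* a parametric pair of statistics — the Box-Cox transformation parameter
  lambda of the response regression (lambda near 0 -> log link, near 0.5
  -> square-root, near 1 -> identity) and the modified Park test, an OLS
  regression of log squared raw-scale residuals on the linear prediction
  of a gamma/log fit, whose slope estimates the variance-power exponent
  p in Var[Y] = phi * mu^p (0 gaussian, 1 poisson, 2 gamma, 3 inverse
  gaussian).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .glm import (
    FAMILIES,
    FAMILY_VARIANCE_POWER,
    LINKS,
    FittedGLM,
    ModelSpec,
    build_design,
    fit_glm,
    information_criteria,
    predict,
)

logger = logging.getLogger(__name__)

#: chi^2(1) 95% quantile / 2, the profile-likelihood CI cutoff
_PROFILE_CUT = stats.chi2.ppf(0.95, df=1) / 2.0


def selection_grid(records: pd.DataFrame, encoding=None) -> pd.DataFrame:
    """Fit all 12 (link, family) pairs; mark the AIC- and BIC-minimal rows.

    Individual fit failures are recorded per-row (``converged`` False,
    criteria NaN), never dropped; if every pair fails, raises.
    """
    X, y, encoding = build_design(records, encoding)
    rows = []
    for link in LINKS:
        for family in FAMILIES:
            row = {"link": link, "family": family, "converged": False,
                   "aic": np.nan, "bic": np.nan,
                   "aic_per_obs": np.nan, "bic_per_obs": np.nan}
            try:
                fitted = fit_glm(X, y, ModelSpec(family, link), encoding)
                row["converged"] = fitted.converged
                if fitted.converged:
                    row.update(information_criteria(fitted))
            except (ValueError, RuntimeError) as exc:
                logger.warning("fit %s/%s failed: %s", family, link, exc)
            rows.append(row)
    grid = pd.DataFrame(rows)
    if not grid["converged"].any():
        raise RuntimeError("all 12 family/link fits failed")
    grid["is_aic_min"] = grid["aic"] == grid["aic"].min()
    grid["is_bic_min"] = grid["bic"] == grid["bic"].min()
    return grid


@dataclass(frozen=True)
class BoxCoxResult:
    lam: float
    ci95: tuple[float, float]
    recommended_link: str

    def __post_init__(self):
        assert self.ci95[0] <= self.lam <= self.ci95[1]


def _boxcox_profile_llf(y: np.ndarray, Q: np.ndarray, log_y_sum: float):
    """Profile log-likelihood of lambda given an orthonormal design basis."""
    n = len(y)

    def llf(lam: float) -> float:
        if abs(lam) < 1e-12:
            z = np.log(y)
        else:
            z = (np.power(y, lam) - 1.0) / lam
        rss = float(z @ z - (Q.T @ z) @ (Q.T @ z))
        # an exactly-fitting transform would send the likelihood to +inf;
        # floor the RSS so degenerate inputs stay finite
        rss = max(rss, np.finfo(float).tiny)
        return -0.5 * n * np.log(rss / n) + (lam - 1.0) * log_y_sum

    return llf


def box_cox_lambda(
    y, X, grid_lo: float = -2.0, grid_hi: float = 2.0, grid_step: float = 1e-3
) -> BoxCoxResult:
    """Box-Cox lambda of the response regression on the full design.

    Maximises the profile log-likelihood of the transformed-response
    linear regression over a grid on [grid_lo, grid_hi] (step 1e-3),
    then refines locally; the 95% CI comes from the chi^2(1) profile
    cutoff. The recommended link is the nearest of lambda = 0 (log),
    0.5 (square root), 1 (identity).
    """
    yv = np.asarray(y, dtype=float)
    if np.any(yv <= 0):
        raise ValueError("Box-Cox requires a strictly positive response")
    Xv = np.asarray(X, dtype=float)
    Q, _ = np.linalg.qr(Xv)
    llf = _boxcox_profile_llf(yv, Q, float(np.sum(np.log(yv))))

    lams = np.arange(grid_lo, grid_hi + grid_step / 2, grid_step)
    vals = np.array([llf(l) for l in lams])
    i = int(np.argmax(vals))
    lo = lams[max(i - 1, 0)]
    hi = lams[min(i + 1, len(lams) - 1)]
    res = optimize.minimize_scalar(
        lambda l: -llf(l), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    lam_hat = float(res.x)
    ll_max = llf(lam_hat)

    def drop(l):
        return llf(l) - (ll_max - _PROFILE_CUT)

    def edge(direction: float) -> float:
        step = grid_step
        a = lam_hat
        b = lam_hat + direction * step
        while drop(b) > 0:
            a, b = b, b + direction * step
            step *= 2
            if direction * b > 2 * max(abs(grid_lo), abs(grid_hi)):
                return b  # CI runs off the search window
        return float(optimize.brentq(drop, min(a, b), max(a, b), xtol=1e-8))

    ci = (edge(-1.0), edge(+1.0))
    targets = {"log": 0.0, "power_half": 0.5, "identity": 1.0}
    link = min(targets, key=lambda k: abs(lam_hat - targets[k]))
    return BoxCoxResult(lam=lam_hat, ci95=ci, recommended_link=link)


@dataclass(frozen=True)
class ParkResult:
    slope: float
    ci95: tuple[float, float]
    recommended_family: str
    n_dropped: int  # zero-residual records excluded from the log regression

    @property
    def recommended_power(self) -> int:
        return FAMILY_VARIANCE_POWER[self.recommended_family]


def modified_park_test(
    records: pd.DataFrame,
    encoding=None,
    model: FittedGLM | None = None,
) -> ParkResult:
    """Modified Park test for the variance-power family.

    Fits a gamma/log GLM (the recommended working model for cost data —
    the link must be right for the test to be valid), forms raw-scale
    residuals r_i = y_i - mu_i, and regresses ln(r_i^2) on the linear
    prediction eta_i by OLS. The slope estimates the variance power;
    its HC1 heteroskedasticity-robust 95% CI is reported, and the
    recommended family is the menu family with the nearest integer
    exponent.
    """
    X, y, encoding = build_design(records, encoding)
    if model is None:
        model = fit_glm(X, y, ModelSpec("gamma", "log"), encoding)
    model.require_converged()
    pred = predict(model, X)
    resid = np.asarray(y, dtype=float) - pred["mu"].to_numpy()
    keep = resid != 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("Park test: dropped %d zero-residual record(s)", n_dropped)
    if not keep.any():
        raise ValueError("all residuals are zero: degenerate fit")
    log_r2 = np.log(resid[keep] ** 2)
    eta = pred["eta"].to_numpy()[keep]
    ols = sm.OLS(log_r2, sm.add_constant(eta)).fit(cov_type="HC1")
    slope = float(ols.params[1])
    lo, hi = ols.conf_int(alpha=0.05)[1]
    powers = {p: f for f, p in FAMILY_VARIANCE_POWER.items()}
    family = powers[min(powers, key=lambda p: abs(slope - p))]
    return ParkResult(
        slope=slope, ci95=(float(lo), float(hi)),
        recommended_family=family, n_dropped=n_dropped,
    )
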