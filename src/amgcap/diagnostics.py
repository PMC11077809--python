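"""Specification tests and goodness-of-fit for cost GLMs.

The battery applied to each candidate model:

* Pregibon link test — refit with the squared linear predictor added; a
  significant coefficient signals a misspecified link/mean.
* Modified Hosmer-Lemeshow — deciles of the linear predictor; F-test
  that mean raw-scale residuals are zero in every decile.
* Copas test — repeated half/half cross-validation; OLS of holdout
  observations on predictions, testing slope = 1 (slope < 1 indicates
  shrinkage/overfitting); holdout RMSE and MAE come with it.
* Auxiliary R^2, RMSE, MAE on the untransformed (euro) scale, so that
  models with different error assumptions are comparable.

All residuals here are raw-scale: y - mu.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glm import FittedGLM, ModelSpec, build_design, fit_glm, predict

logger = logging.getLogger(__name__)


def pregibon_test(model: FittedGLM, records: pd.DataFrame) -> float:
    """Two-sided p-value of the eta^2 term added to the refitted model.

    p > 0.05 is read as "no evidence of link misspecification". If eta^2
    is numerically collinear with the design (e.g. a saturated or
    single-pattern fit), the test is degenerate and returns p = 1.0 with
    a log note.
    """
    model.require_converged()
    X, y, enc = build_design(records, model.encoding)
    eta = predict(model, X)["eta"].to_numpy()
    X2 = X.copy()
    X2["eta_sq"] = eta**2
    rank = np.linalg.matrix_rank(np.asarray(X2, dtype=float))
    if rank < X2.shape[1]:
        logger.warning("Pregibon: eta^2 collinear with design; degenerate pass")
        return 1.0
    refit = fit_glm(X2, y, model.spec, enc)
    refit.require_converged()
    z = refit.coefficients["eta_sq"] / refit.bse["eta_sq"]
    from scipy import stats as sps

    return float(2 * sps.norm.sf(abs(z)))


def hosmer_lemeshow_modified(
    model: FittedGLM, records: pd.DataFrame, n_groups: int = 10
) -> tuple[float, float]:
    """Modified Hosmer-Lemeshow test: (F statistic, p-value).

    Records are sorted by the linear predictor (stable sort, so ties keep
    record order), split into `n_groups` equal-size groups, and raw-scale
    residuals are regressed on the group indicators without intercept;
    the joint F-test that all group means are zero is returned.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if len(records) < 10 * n_groups:
        raise ValueError(f"need at least {10 * n_groups} records for {n_groups} groups")
    model.require_converged()
    X, y, _ = build_design(records, model.encoding)
    pred = predict(model, X)
    resid = np.asarray(y, dtype=float) - pred["mu"].to_numpy()
    order = np.argsort(pred["eta"].to_numpy(), kind="stable")
    groups = np.empty(len(resid), dtype=int)
    # equal-size groups (first n % g groups take one extra record)
    groups[order] = np.minimum(
        n_groups - 1,
        (np.arange(len(resid)) * n_groups) // len(resid),
    )
    if np.allclose(resid, 0.0):
        return 0.0, 1.0
    dummies = pd.get_dummies(groups).to_numpy(dtype=float)
    # cost residual variance grows steeply across deciles: use a
    # heteroskedasticity-robust (HC1) joint Wald test of zero group means
    ols = sm.OLS(resid, dummies).fit(cov_type="HC1")
    ftest = ols.f_test(np.eye(dummies.shape[1]))
    return float(ftest.statistic), float(ftest.pvalue)


def _independent_columns(X: pd.DataFrame) -> list[str]:
    """A maximal linearly independent column subset, in original order.

    Pivoted QR keeps the best-conditioned columns; ``const`` always stays.
    """
    from scipy import linalg

    A = np.asarray(X, dtype=float)
    r = np.linalg.matrix_rank(A)
    if r == A.shape[1]:
        return list(X.columns)
    _, _, piv = linalg.qr(A, mode="economic", pivoting=True)
    chosen = set(piv[:r]) | {X.columns.get_loc("const")}
    cols = [c for i, c in enumerate(X.columns) if i in chosen]
    # the const union can push the subset over rank; re-check and trim
    while np.linalg.matrix_rank(np.asarray(X[cols], dtype=float)) < len(cols):
        cols.remove(next(c for c in reversed(cols) if c != "const"))
    return cols


@dataclass
class CopasResult:
    reps: list = field(default_factory=list)  # (slope, p) per repetition
    p_summary: float = np.nan  # mean of repetition p-values
    slope_mean: float = np.nan
    rmse_cv: float = np.nan  # holdout RMSE averaged over repetitions
    mae_cv: float = np.nan


def copas_test(
    records: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    repetitions: int = 10,
    seed: int = 0,
    encoding=None,
) -> CopasResult:
    """Copas cross-validation test over random half/half splits.

    Per repetition: fit `spec` on one half, predict the other, regress
    observed on predicted by OLS and test slope = 1 (two-sided). The
    summary p is the mean of the repetition p-values — a decision at
    alpha compares this mean against alpha, treating the repetitions as
    one pooled piece of evidence. Holdout RMSE/MAE are averaged across
    repetitions.

    Halves that lack at least two covariate patterns are redrawn (at
    most 10 times per repetition, logged).
    """
    n = len(records)
    if n < 100:
        raise ValueError("Copas test needs at least 100 records")
    full_X, _, encoding = build_design(records, encoding)
    rng = np.random.default_rng(seed)
    result = CopasResult()
    rmses, maes = [], []
    for rep in range(repetitions):
        for attempt in range(10):
            perm = rng.permutation(n)
            half_a = records.iloc[perm[: n // 2]]
            half_b = records.iloc[perm[n // 2:]]
            Xa, ya, _ = build_design(half_a, encoding)
            if np.unique(np.asarray(Xa), axis=0).shape[0] >= 2:
                break
            logger.info("Copas rep %d: degenerate half, redrawing", rep)
        else:
            raise RuntimeError("could not draw a non-degenerate half split")
        # Rare indicator levels can be absent or exactly collinear within
        # a training half; restrict the repetition to a full-rank column
        # subset chosen by pivoted QR (records carrying a dropped level
        # predict at the reference level).
        keep_cols = _independent_columns(Xa)
        if len(keep_cols) < Xa.shape[1]:
            logger.info(
                "Copas rep %d: %d sparse column(s) dropped",
                rep, Xa.shape[1] - len(keep_cols),
            )
        fit = fit_glm(Xa[keep_cols], ya, spec, encoding)
        fit.require_converged()
        Xb, yb, _ = build_design(half_b, encoding)
        mu_b = predict(fit, Xb[keep_cols])["mu"].to_numpy()
        yb = np.asarray(yb, dtype=float)
        err = yb - mu_b
        rmses.append(float(np.sqrt(np.mean(err**2))))
        maes.append(float(np.mean(np.abs(err))))
        if np.allclose(yb, mu_b):
            result.reps.append((1.0, 1.0))
            continue
        # HC1 errors: holdout costs are strongly heteroskedastic in mu
        ols = sm.OLS(yb, sm.add_constant(mu_b)).fit(cov_type="HC1")
        slope = float(ols.params[1])
        tval = (slope - 1.0) / float(ols.bse[1])
        from scipy import stats as sps

        p = float(2 * sps.t.sf(abs(tval), df=ols.df_resid))
        result.reps.append((slope, p))
    result.p_summary = float(np.mean([p for _, p in result.reps]))
    result.slope_mean = float(np.mean([s for s, _ in result.reps]))
    result.rmse_cv = float(np.mean(rmses))
    result.mae_cv = float(np.mean(maes))
    return result


def fit_metrics(observed, predicted) -> dict:
    """Auxiliary R^2, RMSE and MAE on the untransformed scale.

    r2_aux is the squared correlation from the OLS of observed on
    predicted (0 when predictions are constant, with a log note).
    """
    y = np.asarray(observed, dtype=float)
    mu = np.asarray(predicted, dtype=float)
    if len(y) != len(mu) or len(y) < 2:
        raise ValueError("observed/predicted must have equal length >= 2")
    err = y - mu
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.allclose(mu, mu[0]) or np.allclose(y, y[0]):
        if np.allclose(mu, mu[0]):
            logger.info("fit_metrics: constant predictions, r2_aux = 0")
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y, mu)[0, 1] ** 2)
    return {"r2_aux": r2, "rmse": rmse, "mae": mae}


def diagnostics_report(
    model: FittedGLM,
    records: pd.DataFrame,
    repetitions: int = 10,
    seed: int = 0,
    hl_groups: int = 10,
) -> dict:
    """Run the full battery and return a JSON-serialisable report."""
    X, y, _ = build_design(records, model.encoding)
    mu = predict(model, X)["mu"].to_numpy()
    metrics = fit_metrics(y, mu)
    hl_stat, hl_p = hosmer_lemeshow_modified(model, records, hl_groups)
    copas = copas_test(records, model.spec, repetitions, seed, model.encoding)
    return {
        "pregibon_p": pregibon_test(model, records),
        "hl_stat": hl_stat,
        "hl_p": hl_p,
        "hl_groups": hl_groups,
        "copas_reps": [{"slope": s, "p": p} for s, p in copas.reps],
        "copas_p_summary": copas.p_summary,
        "copas_slope_mean": copas.slope_mean,
        "rmse_cv": copas.rmse_cv,
        "mae_cv": copas.mae_cv,
        **metrics,
    }
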