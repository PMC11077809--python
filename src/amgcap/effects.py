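"""Per-AMG cost surface: average marginal effects, predicted means, weights.

The relative weight of an AMG is its average predicted cost divided by
the healthy base group's — the morbidity "price" a capitation formula
attaches to each group. Predicted group means are averages of individual
predictions within the group (groups differ in age/sex composition, so
these ratios deliberately differ from exp(coefficient differences)).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .glm import FittedGLM, build_design, predict

logger = logging.getLogger(__name__)


def _switch(X: pd.DataFrame, prefix: str, target: str | None) -> pd.DataFrame:
    """Return a copy with every `prefix` indicator off and `target` on.

    `target=None` switches the whole mutually exclusive set to its
    reference level.
    """
    out = X.copy()
    for col in out.columns:
        if col.startswith(prefix):
            out[col] = 0.0
    if target is not None:
        out[target] = 1.0
    return out


def _counterfactual_pair(X: pd.DataFrame, variable: str):
    """Designs with `variable` forced to 1 and to 0 for every record.

    For indicators in a mutually exclusive set (``amg_*``, ``age_*``),
    forcing on switches the sibling indicators off and forcing off
    returns the record to the set's reference level.
    """
    if variable == "sex":
        return _switch(X, "sex", "sex"), _switch(X, "sex", None)
    for prefix in ("amg_", "age_"):
        if variable.startswith(prefix):
            if variable not in X.columns:
                raise ValueError(f"unknown design column: {variable!r}")
            return _switch(X, prefix, variable), _switch(X, prefix, None)
    raise ValueError(f"{variable!r} is not a binary indicator in the design")


def average_marginal_effect(
    model: FittedGLM, X: pd.DataFrame, variable: str
) -> float:
    """Average change in predicted cost when `variable` flips 0 -> 1.

    Averaged over all records, holding each record's other covariates
    fixed; for AMG and age-band indicators the 0 state is the reference
    level (healthy / age band 0).
    """
    X1, X0 = _counterfactual_pair(X, variable)
    mu1 = predict(model, X1)["mu"].to_numpy()
    mu0 = predict(model, X0)["mu"].to_numpy()
    return float(np.mean(mu1 - mu0))


def group_predicted_means(
    model: FittedGLM,
    records: pd.DataFrame,
    grouping: str = "amg_code",
) -> pd.Series:
    """Mean of per-record predictions within each group.

    This is an average over each group's own members — not a prediction
    at group-mean covariates — so group composition (age, sex) flows
    into the means and hence into relative weights.
    """
    model.require_converged()
    X, _, _ = build_design(records, model.encoding)
    mu = predict(model, X)["mu"].to_numpy()
    out = (
        pd.Series(mu, index=records.index, name="predicted_mean")
        .groupby(records[grouping])
        .mean()
        .sort_index()
    )
    return out


def relative_weights(group_means: pd.Series, base_code=1) -> pd.Series:
    """Weight of each group: predicted mean over the base group's mean."""
    if base_code not in group_means.index:
        raise ValueError(f"base group {base_code!r} missing from group means")
    base = group_means[base_code]
    if not base > 0:
        raise ValueError("base group predicted mean must be positive")
    return (group_means / base).rename("relative_weight")


def weight_table(model: FittedGLM, records: pd.DataFrame) -> pd.DataFrame:
    """Per-AMG table: coefficient, AME (EUR), predicted mean (EUR), weight.

    The base group row carries weight exactly 1. Rounding for reporting
    (3 decimals for coefficients and weights, 2 for euro amounts) is
    left to the renderer; values here are full precision.
    """
    model.require_converged()
    X, _, _ = build_design(records, model.encoding)
    means = group_predicted_means(model, records)
    weights = relative_weights(means)
    rows = []
    for code in means.index:
        col = f"amg_{code}"
        coef = float(model.coefficients.get(col, 0.0))
        ame = (
            average_marginal_effect(model, X, col) if col in X.columns else np.nan
        )
        rows.append(
            {
                "amg_code": code,
                "coefficient": coef,
                "ame_eur": ame,
                "predicted_mean_eur": float(means[code]),
                "relative_weight": float(weights[code]),
            }
        )
    return pd.DataFrame(rows).set_index("amg_code")


def age_band_effects(model: FittedGLM, records: pd.DataFrame) -> pd.DataFrame:
    """Per-age-band coefficient and AME, companion to :func:`weight_table`."""
    model.require_converged()
    X, _, _ = build_design(records, model.encoding)
    rows = []
    for band in model.encoding.age_bands if model.encoding else ():
        if band == 0:
            continue
        col = f"age_{band}"
        if col not in X.columns:
            continue
        rows.append(
            {
                "age_band": band,
                "coefficient": float(model.coefficients[col]),
                "ame_eur": average_marginal_effect(model, X, col),
            }
        )
    return pd.DataFrame(rows).set_index("age_band")
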