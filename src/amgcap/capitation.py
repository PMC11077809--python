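"""Needs-based capitation arithmetic across health areas.

From per-person observed costs and model predictions this module builds:

* the area cost summary — observed and predicted average cost per user,
  their difference, and cross-sectional indices with the system mean
  set to 100;
* need indices (predicted index / 100) and adjusted ("equivalent")
  populations, covered population x need index;
* a three-way allocation of a fixed budget: by raw population, by
  adjusted population, and by historical share, with the difference
  between the needs-based and historical columns.

Predictions are multiplicatively calibrated so the predicted system
mean equals the observed one before indices are formed (a log-link GLM
does not guarantee that the predictions sum to observed cost); the
calibration factor is logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TOTAL_LABEL = "Total"


def area_cost_summary(
    records: pd.DataFrame,
    predictions: np.ndarray | pd.Series,
    calibrate: bool = True,
) -> pd.DataFrame:
    """Observed vs predicted average cost per area, with indices.

    Parameters
    ----------
    records
        Person-level table with ``area_id`` and ``cost_eur``.
    predictions
        Per-record predicted cost, aligned positionally with `records`.
    calibrate
        Rescale predictions so the predicted system mean equals the
        observed system mean (factor logged). With calibration the Total
        difference is exactly 0.
    """
    if len(predictions) != len(records):
        raise ValueError("every record needs a prediction")
    df = pd.DataFrame(
        {
            "area_id": records["area_id"].to_numpy(),
            "observed": records["cost_eur"].to_numpy(dtype=float),
            "predicted": np.asarray(predictions, dtype=float),
        }
    )
    if calibrate:
        factor = df["observed"].mean() / df["predicted"].mean()
        logger.info("prediction calibration factor: %.6f", factor)
        df["predicted"] *= factor

    grouped = df.groupby("area_id").agg(
        observed_mean=("observed", "mean"),
        predicted_mean=("predicted", "mean"),
        n=("observed", "size"),
    )
    system_obs = df["observed"].mean()
    system_pred = df["predicted"].mean()
    total = pd.DataFrame(
        {
            "observed_mean": [system_obs],
            "predicted_mean": [system_pred],
            "n": [len(df)],
        },
        index=pd.Index([TOTAL_LABEL], name="area_id"),
    )
    out = pd.concat([grouped, total])
    out["difference"] = out["observed_mean"] - out["predicted_mean"]
    out["observed_index"] = 100.0 * out["observed_mean"] / system_obs
    out["predicted_index"] = 100.0 * out["predicted_mean"] / system_pred
    return out


def summary_from_area_means(
    observed_mean: pd.Series,
    predicted_mean: pd.Series,
    weights: pd.Series,
) -> pd.DataFrame:
    """Area summary built from published per-area means and user counts,
    for when person-level data are unavailable but aggregates are."""
    df = pd.DataFrame(
        {"observed_mean": observed_mean, "predicted_mean": predicted_mean}
    )
    w = weights / weights.sum()
    system_obs = float((df["observed_mean"] * w).sum())
    system_pred = float((df["predicted_mean"] * w).sum())
    total = pd.DataFrame(
        {"observed_mean": [system_obs], "predicted_mean": [system_pred]},
        index=pd.Index([TOTAL_LABEL], name="area_id"),
    )
    out = pd.concat([df, total])
    out["difference"] = out["observed_mean"] - out["predicted_mean"]
    out["observed_index"] = 100.0 * out["observed_mean"] / system_obs
    out["predicted_index"] = 100.0 * out["predicted_mean"] / system_pred
    return out


def need_index(area_summary: pd.DataFrame) -> pd.Series:
    """Per-area need index: predicted cross-sectional index on unit scale."""
    pred = area_summary["predicted_index"]
    if (pred <= 0).any():
        raise ValueError("predicted indices must be positive")
    out = (pred / 100.0).rename("need_index")
    return out.drop(TOTAL_LABEL, errors="ignore")


def adjusted_population(covered: pd.Series, need: pd.Series) -> pd.Series:
    """Equivalent population: covered population x need index.

    Full precision is retained; round only for reporting.
    """
    if (np.asarray(covered) < 0).any():
        raise ValueError("covered population must be >= 0")
    if (np.asarray(need) <= 0).any():
        raise ValueError("need index must be > 0")
    return (covered * need).rename("adjusted_population")


def allocate_budget(
    budget_eur_m: float,
    areas: pd.DataFrame,
) -> pd.DataFrame:
    """Three-way budget allocation across areas.

    Parameters
    ----------
    budget_eur_m
        Fixed budget in millions of euros.
    areas
        Indexed by area, with columns ``covered_population``,
        ``need_index`` and ``historical_share`` (fractions summing to 1
        within 1e-6).

    Returns
    -------
    DataFrame with the adjusted population and the three allocations
    (``alloc_population``, ``alloc_adjusted``, ``alloc_historical``,
    each in EUR millions, each summing exactly to the budget before
    rounding) plus ``difference`` = adjusted - historical.
    """
    if not budget_eur_m > 0:
        raise ValueError("budget must be positive")
    required = {"covered_population", "need_index", "historical_share"}
    missing = required - set(areas.columns)
    if missing:
        raise ValueError(f"area table missing column(s): {sorted(missing)}")
    if (areas["covered_population"] <= 0).any():
        raise ValueError("covered populations must be positive")
    share_sum = float(areas["historical_share"].sum())
    if abs(share_sum - 1.0) > 1e-6:
        raise ValueError(f"historical shares must sum to 1 (got {share_sum:.8f})")

    out = areas.copy()
    out["adjusted_population"] = adjusted_population(
        out["covered_population"], out["need_index"]
    )
    out["alloc_population"] = (
        budget_eur_m * out["covered_population"] / out["covered_population"].sum()
    )
    out["alloc_adjusted"] = (
        budget_eur_m * out["adjusted_population"] / out["adjusted_population"].sum()
    )
    out["alloc_historical"] = budget_eur_m * out["historical_share"] / share_sum
    out["difference"] = out["alloc_adjusted"] - out["alloc_historical"]
    return out


def render_allocation(finance: pd.DataFrame) -> pd.DataFrame:
    """Reporting view: populations to whole persons, allocations to whole
    EUR millions, differences to 2 decimals, need indices to 5."""
    view = finance.copy()
    view["covered_population"] = view["covered_population"].round().astype(int)
    view["adjusted_population"] = view["adjusted_population"].round().astype(int)
    view["need_index"] = view["need_index"].round(5)
    for col in ("alloc_population", "alloc_adjusted", "alloc_historical"):
        view[col] = view[col].round().astype(int)
    view["difference"] = view["difference"].round(2)
    return view.drop(columns=["historical_share"], errors="ignore")
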