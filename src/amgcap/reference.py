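"""Reference figures from the 2017 Murcian Health Service study population.

The person-level analytic file behind these figures (1,251,108 cost-incurring
users of a Spanish regional health service, stratified into 31 Adjusted
Morbidity Groups) is not public. What is public are its summary statistics:
per-AMG composition (size, mean/SD age, % female, mean/SD cost), the fitted
log-scale cost coefficients of a gamma/log GLM on sex, 5-year age band and
AMG, and the area-level financing inputs for the nine health areas.

These summaries serve two roles here:

* defaults for the synthetic-population generator (:mod:`amgcap.simulate`),
  so simulated data share the real system's composition and cost gradients;
* exogenous inputs to the capitation arithmetic (covered populations,
  area-level observed/predicted average costs, historical budget shares),
  which is pure accounting on published aggregates.
"""

from __future__ import annotations

import pandas as pd

from .catalog import AGE_BANDS, AMG_CODES

# ---------------------------------------------------------------------------
# Per-AMG composition of the analytic population
# columns: mean age (yr), mean cost (EUR/yr), % female, SD age, SD cost, n
# ---------------------------------------------------------------------------
_GROUP_STATS = {
    1: (29.75, 217.95, 38.81, 17.84, 1649.53, 59406),
    101: (23.96, 242.02, 40.97, 17.35, 1416.63, 63069),
    102: (22.30, 338.14, 42.62, 17.83, 945.04, 40396),
    103: (18.82, 490.77, 45.93, 17.94, 1914.75, 28366),
    104: (14.74, 713.83, 49.23, 17.31, 1829.18, 17678),
    105: (9.61, 1510.94, 51.35, 15.44, 3692.16, 9398),
    201: (31.31, 1323.92, 100.00, 6.29, 1617.92, 5448),
    202: (31.87, 2265.04, 100.00, 6.09, 1979.63, 8504),
    203: (32.03, 2824.10, 100.00, 6.11, 2054.58, 6473),
    204: (32.23, 3526.77, 100.00, 6.25, 2726.36, 5424),
    205: (33.16, 4910.26, 100.00, 6.42, 5406.10, 2019),
    311: (27.50, 251.55, 47.24, 15.66, 1207.10, 51168),
    312: (31.48, 337.31, 41.26, 18.79, 1550.15, 85983),
    313: (31.05, 541.05, 42.45, 19.40, 4046.06, 60803),
    314: (30.10, 828.60, 44.60, 21.07, 2901.36, 46292),
    315: (28.19, 1962.88, 44.89, 23.25, 6029.96, 19558),
    321: (32.89, 402.78, 52.95, 17.48, 1304.25, 133841),
    322: (40.78, 731.48, 51.49, 19.57, 2420.03, 148624),
    323: (47.53, 1221.10, 50.68, 20.36, 3213.40, 77502),
    324: (53.49, 2016.29, 48.55, 20.75, 3880.43, 44931),
    325: (61.34, 4645.00, 40.59, 19.86, 8752.23, 16830),
    331: (49.91, 1173.00, 68.30, 18.92, 3010.10, 135466),
    332: (64.75, 2659.36, 65.35, 15.77, 4917.98, 96693),
    333: (70.87, 4494.43, 59.80, 14.09, 6789.83, 31732),
    334: (75.04, 7046.22, 53.81, 13.00, 10394.44, 23185),
    335: (78.62, 13135.77, 50.34, 10.92, 15821.16, 11186),
    401: (56.92, 5275.08, 52.42, 17.11, 8030.34, 6984),
    402: (66.53, 9960.65, 48.43, 14.83, 12529.17, 6287),
    403: (70.65, 14769.87, 42.88, 13.81, 17427.73, 3757),
    404: (73.89, 18873.63, 37.26, 12.35, 22535.54, 2845),
    405: (76.69, 24280.64, 32.62, 10.83, 23529.62, 1260),
}

#: total analytic (cost-incurring) population
ANALYTIC_POPULATION = 1_251_108


def group_stats() -> pd.DataFrame:
    """Per-AMG composition of the study population, indexed by AMG code."""
    df = pd.DataFrame.from_dict(
        _GROUP_STATS,
        orient="index",
        columns=["age_mean", "cost_mean", "pct_female", "age_sd", "cost_sd", "n"],
    )
    df.index.name = "amg_code"
    return df.loc[list(AMG_CODES)]


# ---------------------------------------------------------------------------
# Fitted gamma/log GLM coefficients (log-euro scale), the generator's
# default truth. Reference levels: age band 0, AMG 1, sex = male (0);
# sex indicator is 1 for female.
# ---------------------------------------------------------------------------
DEFAULT_INTERCEPT = 5.731
DEFAULT_SEX_COEF = -0.126

DEFAULT_AGE_COEFS = {
    0: 0.0,
    5: -0.509,
    10: -0.475,
    15: -0.428,
    20: -0.429,
    25: -0.389,
    30: -0.303,
    35: -0.276,
    40: -0.249,
    45: -0.230,
    50: -0.186,
    55: -0.206,
    60: -0.198,
    65: -0.161,
    70: -0.137,
    75: -0.155,
    80: -0.228,
    85: -0.311,
}

DEFAULT_AMG_COEFS = {
    1: 0.0,
    101: 0.095,
    102: 0.416,
    103: 0.761,
    104: 1.085,
    105: 1.762,
    201: 1.911,
    202: 2.445,
    203: 2.665,
    204: 2.886,
    205: 3.213,
    311: 0.198,
    312: 0.445,
    313: 0.908,
    314: 1.308,
    315: 2.122,
    321: 0.653,
    322: 1.201,
    323: 1.683,
    324: 2.169,
    325: 2.976,
    331: 1.659,
    332: 2.443,
    333: 2.961,
    334: 3.406,
    335: 4.026,
    401: 3.131,
    402: 3.739,
    403: 4.126,
    404: 4.360,
    405: 4.611,
}

#: published per-AMG predicted mean cost (EUR) under the fitted model,
#: averaged over each group's own age/sex composition (base group 215.57)
PUBLISHED_PREDICTED_MEANS = {
    1: 215.57,
    101: 239.45,
    102: 336.07,
    103: 488.33,
    104: 710.44,
    105: 1499.98,
    201: 1325.84,
    202: 2273.03,
    203: 2835.37,
    204: 3543.37,
    205: 4951.63,
    311: 252.75,
    312: 337.69,
    313: 542.61,
    314: 826.14,
    315: 1951.76,
    321: 404.73,
    322: 732.52,
    323: 1225.20,
    324: 2035.35,
    325: 4665.86,
    331: 1168.28,
    332: 2671.43,
    333: 4512.83,
    334: 7029.94,
    335: 12991.52,
    401: 5346.30,
    402: 10022.15,
    403: 14816.30,
    404: 18797.00,
    405: 24150.32,
}

assert set(DEFAULT_AMG_COEFS) == set(AMG_CODES)
assert set(DEFAULT_AGE_COEFS) == set(AGE_BANDS)


def default_coefficients() -> pd.Series:
    """The default truth as a named coefficient vector on the log scale.

    Names follow the design-matrix convention of :mod:`amgcap.glm`:
    ``const``, ``sex``, ``age_<band>`` (bands 5..85), ``amg_<code>``.
    """
    coefs = {"const": DEFAULT_INTERCEPT, "sex": DEFAULT_SEX_COEF}
    for band, value in DEFAULT_AGE_COEFS.items():
        if band != 0:
            coefs[f"age_{band}"] = value
    for code, value in DEFAULT_AMG_COEFS.items():
        if code != 1:
            coefs[f"amg_{code}"] = value
    return pd.Series(coefs, dtype=float)


# ---------------------------------------------------------------------------
# Area-level financing inputs for the nine health areas
# ---------------------------------------------------------------------------
AREA_IDS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX")

#: observed and model-predicted average cost per analytic user (EUR)
AREA_MEAN_COSTS = pd.DataFrame(
    {
        "observed_mean": [
            1445.20, 1538.25, 1406.21, 1610.49, 1425.95,
            1369.53, 1473.27, 1553.30, 1678.93,
        ],
        "predicted_mean": [
            1455.45, 1505.97, 1385.48, 1499.33, 1336.79,
            1496.10, 1527.42, 1454.58, 1511.97,
        ],
    },
    index=pd.Index(AREA_IDS, name="area_id"),
)

#: system-wide average cost per analytic user (EUR)
SYSTEM_MEAN_COST = 1473.07

#: covered population per area (health-card holders, including non-users)
AREA_COVERED_POPULATION = pd.Series(
    [269_627, 288_536, 180_577, 69_947, 60_828, 272_042, 204_969, 109_851, 54_874],
    index=pd.Index(AREA_IDS, name="area_id"),
    name="covered_population",
)

#: published per-area need indices (predicted cross-sectional index / 100)
AREA_NEED_INDEX = pd.Series(
    [0.98804, 1.02234, 0.94054, 1.01783, 0.90749, 1.01564, 1.03690, 0.98745, 1.02641],
    index=pd.Index(AREA_IDS, name="area_id"),
    name="need_index",
)

#: regional budget to allocate, millions of EUR
DEFAULT_BUDGET_EUR_M = 1842.0

#: historical budget shares (fraction of the budget each area has received
#: under the status quo). These come from the accounting system, not from
#: the model; shown here normalised to sum exactly to 1.
_HIST_EUR_M = pd.Series(
    [317.27, 364.56, 209.63, 102.06, 74.24, 294.01, 259.93, 139.08, 81.24],
    index=pd.Index(AREA_IDS, name="area_id"),
)
AREA_HISTORICAL_SHARE = (_HIST_EUR_M / _HIST_EUR_M.sum()).rename("historical_share")


def reference_area_table() -> pd.DataFrame:
    """Area-level financing input table: covered population, need index,
    historical share — the exogenous inputs to the budget allocation."""
    return pd.concat(
        [AREA_COVERED_POPULATION, AREA_NEED_INDEX, AREA_HISTORICAL_SHARE], axis=1
    )
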