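"""Synthetic person-level populations for capitation analysis.

Generates populations with the statistical structure the cost model
assumes: 31 AMG strata with configurable shares, per-stratum age
(truncated normal on [0, 105]) and sex (Bernoulli female share),
and strictly positive annual costs drawn from a gamma distribution
whose conditional mean is log-linear in sex, 5-year age band and AMG.
Areas re-weight the AMG mixture multiplicatively (sicker / healthier
case mixes) and may distort realised costs by a multiplier, creating
the over- and under-funding patterns a needs-based allocation is meant
to expose.

Defaults reproduce the composition and cost gradients of the 2017
Murcian study population (see :mod:`amgcap.reference`): Table-style
per-AMG shares, age moments and female shares, the published gamma/log
coefficients as the true beta, and a common gamma shape nu = 0.5
(cost CV of sqrt(2) within a stratum, matching strongly right-skewed
individual costs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .catalog import AMG_CODES, age_band, amg_entry
from .glm import DesignEncoding, build_design

MAX_AGE = 105


@dataclass(frozen=True)
class AreaConfig:
    """One health area's generative settings.

    ``tilt`` multiplies the global AMG shares per code (then renormalises),
    shifting the case mix; ``cost_multiplier`` scales realised costs away
    from need (1.0 = spending matches need); ``weight`` is the area's share
    of generated persons; ``coverage_inflation`` maps analytic users to
    covered population (covered = users x inflation, accounting for insured
    persons who incurred no cost).
    """

    area_id: str
    weight: float = 1.0
    tilt: dict = field(default_factory=dict)
    cost_multiplier: float = 1.0
    coverage_inflation: float = 1.208


def complexity_tilt(strength: float) -> dict:
    """A tilt multiplying each code's share by strength^complexity.

    strength > 1 yields a sicker-than-average area, < 1 a healthier one;
    the healthy group (complexity None) keeps multiplier 1.
    """
    return {
        c: float(strength) ** (amg_entry(c).complexity or 0) for c in AMG_CODES
    }


def _default_areas() -> tuple[AreaConfig, ...]:
    # nine areas sized like the reference covered populations, with mild
    # case-mix tilts and cost distortions qualitatively matching the
    # observed over/under-funding pattern (obs/predicted cost ratios)
    weights = reference.AREA_COVERED_POPULATION / reference.AREA_COVERED_POPULATION.sum()
    ratios = (
        reference.AREA_MEAN_COSTS["observed_mean"]
        / reference.AREA_MEAN_COSTS["predicted_mean"]
    )
    need = reference.AREA_NEED_INDEX
    # map the published need indices to tilt strengths: sicker areas have
    # need index > 1; strength ~ 1 + 2.5*(need - 1) spreads indices similarly
    return tuple(
        AreaConfig(
            area_id=a,
            weight=float(weights[a]),
            tilt=complexity_tilt(1.0 + 2.5 * (float(need[a]) - 1.0)),
            cost_multiplier=float(ratios[a]),
        )
        for a in reference.AREA_IDS
    )


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the reference population."""

    n_persons: int = 50_000
    seed: int = 0
    amg_shares: dict = None  # code -> probability, sums to 1
    age_means: dict = None  # code -> mean age (years)
    age_sds: dict = None  # code -> SD age (years)
    female_shares: dict = None  # code -> P(female)
    true_coefficients: pd.Series = None  # log-scale, glm naming convention
    gamma_shape: float = 0.5  # nu; Var[cost] = mu^2 / nu
    areas: tuple = None  # tuple of AreaConfig

    def __post_init__(self):
        stats_df = reference.group_stats()
        if self.amg_shares is None:
            n = stats_df["n"]
            self.amg_shares = (n / n.sum()).to_dict()
        if self.age_means is None:
            self.age_means = stats_df["age_mean"].to_dict()
        if self.age_sds is None:
            self.age_sds = stats_df["age_sd"].to_dict()
        if self.female_shares is None:
            self.female_shares = (stats_df["pct_female"] / 100.0).to_dict()
        if self.true_coefficients is None:
            self.true_coefficients = reference.default_coefficients()
        if self.areas is None:
            self.areas = _default_areas()
        self.validate()

    def validate(self):
        if self.n_persons < 0:
            raise ValueError("n_persons must be >= 0")
        shares = np.array([self.amg_shares[c] for c in self.codes], dtype=float)
        if np.any(shares < 0):
            raise ValueError("amg_shares must be non-negative")
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"amg_shares must sum to 1 (got {shares.sum():.12f})"
            )
        if not self.gamma_shape > 0:
            raise ValueError("gamma_shape must be positive")
        for a in self.areas:
            if a.weight < 0:
                raise ValueError(f"area {a.area_id}: negative weight")
            tilted = shares * np.array(
                [a.tilt.get(c, 1.0) for c in self.codes], dtype=float
            )
            if np.any(tilted < 0) or tilted.sum() <= 0:
                raise ValueError(f"area {a.area_id}: tilt gives invalid shares")

    @property
    def codes(self) -> list[int]:
        return sorted(self.amg_shares)


def _area_shares(config: SimConfig) -> pd.DataFrame:
    """Per-area tilted AMG share vectors (rows: area, columns: code)."""
    base = np.array([config.amg_shares[c] for c in config.codes], dtype=float)
    rows = {}
    for a in config.areas:
        tilted = base * np.array(
            [a.tilt.get(c, 1.0) for c in config.codes], dtype=float
        )
        rows[a.area_id] = tilted / tilted.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=config.codes)


def _conditional_means(
    records: pd.DataFrame, coefficients: pd.Series
) -> np.ndarray:
    """mu_i = exp(x_i' beta) under the log-linear truth."""
    bands = sorted(age_band(records["age_years"]).unique())
    codes = sorted(records["amg_code"].unique())
    enc = DesignEncoding(tuple(int(b) for b in bands), tuple(int(c) for c in codes))
    X, _, _ = build_design(records, enc)
    # a term absent from the coefficient vector is only an error if it is
    # active for some record (e.g. an all-male sample needs no sex term)
    missing = [
        c for c in X.columns
        if c not in coefficients.index and X[c].abs().sum() > 0
    ]
    if missing:
        raise ValueError(f"true_coefficients missing level(s): {missing}")
    beta = coefficients.reindex(X.columns, fill_value=0.0).to_numpy()
    eta = np.asarray(X, dtype=float) @ beta
    return np.exp(eta)


def sample_costs(
    records: pd.DataFrame,
    true_coefficients: pd.Series,
    gamma_shape: float,
    seed: int,
    area_multipliers: dict | None = None,
) -> pd.DataFrame:
    """Draw gamma costs: cost_i ~ Gamma(shape=nu, mean=mu_i * area mult).

    Variance within a stratum is (mean)^2 / nu, the variance-proportional-
    to-mean-squared structure of the gamma family. Returns a copy with
    ``cost_eur`` filled; all costs are strictly positive.
    """
    if not gamma_shape > 0:
        raise ValueError("gamma_shape must be positive")
    rng = np.random.default_rng(seed)
    mu = _conditional_means(records, true_coefficients)
    if area_multipliers:
        mult = records["area_id"].map(lambda a: area_multipliers.get(a, 1.0))
        mu = mu * mult.to_numpy(dtype=float)
    out = records.copy()
    # Gamma(shape=nu, scale=mu/nu) has mean mu, variance mu^2/nu
    out["cost_eur"] = rng.gamma(shape=gamma_shape, scale=mu / gamma_shape)
    # guard against underflow to exactly 0 at tiny shape values
    tiny = np.finfo(float).tiny
    out.loc[out["cost_eur"] <= 0, "cost_eur"] = tiny
    return out


def generate_population(config: SimConfig) -> pd.DataFrame:
    """Generate the person-level analytic table.

    Column order matches the on-disk schema:
    ``person_id, area_id, sex, age_years, amg_code, cost_eur``.
    Deterministic given the config (single seeded generator, fixed
    draw order: area, AMG, age, sex, cost).
    """
    config.validate()
    n = config.n_persons
    cols = ["person_id", "area_id", "sex", "age_years", "amg_code", "cost_eur"]
    if n == 0:
        return pd.DataFrame(columns=cols)

    rng = np.random.default_rng(config.seed)
    area_ids = [a.area_id for a in config.areas]
    w = np.array([a.weight for a in config.areas], dtype=float)
    w = w / w.sum()
    area_idx = rng.choice(len(area_ids), size=n, p=w)

    shares = _area_shares(config)
    codes = np.array(config.codes)
    amg = np.empty(n, dtype=int)
    for i, a in enumerate(area_ids):
        mask = area_idx == i
        if mask.any():
            amg[mask] = rng.choice(codes, size=int(mask.sum()), p=shares.loc[a].to_numpy())

    age = np.empty(n, dtype=float)
    sex = np.empty(n, dtype=int)
    for c in codes:
        mask = amg == c
        m = int(mask.sum())
        if m == 0:
            continue
        mean, sd = config.age_means[c], config.age_sds[c]
        if sd <= 0:
            age[mask] = mean
        else:
            lo, hi = (0 - mean) / sd, (MAX_AGE - mean) / sd
            age[mask] = stats.truncnorm.rvs(
                lo, hi, loc=mean, scale=sd, size=m, random_state=rng
            )
        sex[mask] = rng.random(m) < config.female_shares[c]

    records = pd.DataFrame(
        {
            "person_id": np.arange(1, n + 1),
            "area_id": [area_ids[i] for i in area_idx],
            "sex": sex,
            "age_years": np.floor(age).astype(int),
            "amg_code": amg,
        }
    )
    multipliers = {a.area_id: a.cost_multiplier for a in config.areas}
    cost_seed = int(rng.integers(0, 2**31 - 1))
    records = sample_costs(
        records,
        config.true_coefficients,
        config.gamma_shape,
        seed=cost_seed,
        area_multipliers=multipliers,
    )
    return records[cols]


def area_table(config: SimConfig, records: pd.DataFrame) -> pd.DataFrame:
    """Area-level table: covered population and historical budget share.

    Covered population inflates each area's analytic user count by its
    coverage factor; the historical share is each area's share of total
    realised cost (spending so far follows observed, distorted cost).
    """
    users = records.groupby("area_id").size()
    cost = records.groupby("area_id")["cost_eur"].sum()
    rows = []
    for a in config.areas:
        n_users = int(users.get(a.area_id, 0))
        rows.append(
            {
                "area_id": a.area_id,
                "covered_population": int(round(n_users * a.coverage_inflation)),
                "historical_share": float(cost.get(a.area_id, 0.0)),
            }
        )
    out = pd.DataFrame(rows).set_index("area_id")
    total = out["historical_share"].sum()
    if total > 0:
        out["historical_share"] /= total
    return out


def summarize_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Per-AMG summary (mean/SD age and cost, % female, n) plus a Total row.

    The Total row's mean cost is the n-weighted average of group means by
    construction (it is computed over all records).
    """
    if len(records) == 0:
        raise ValueError("cannot summarise an empty collection")

    def _stats(df):
        return pd.Series(
            {
                "age_mean": df["age_years"].mean(),
                "cost_mean": df["cost_eur"].mean(),
                "pct_female": 100.0 * df["sex"].mean(),
                "age_sd": df["age_years"].std(ddof=1),
                "cost_sd": df["cost_eur"].std(ddof=1),
                "n": len(df),
            }
        )

    by_group = (
        records.groupby("amg_code").apply(_stats, include_groups=False).sort_index()
    )
    total = _stats(records).rename("Total")
    out = pd.concat([by_group, total.to_frame().T])
    out["n"] = out["n"].astype(int)
    out.index.name = "amg_code"
    return out
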