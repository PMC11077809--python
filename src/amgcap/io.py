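"""Readers and writers for the pipeline's plain-text tables."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .catalog import is_valid_code

logger = logging.getLogger(__name__)

PERSON_COLUMNS = ["person_id", "area_id", "sex", "age_years", "amg_code", "cost_eur"]
AREA_COLUMNS = ["area_id", "covered_population", "historical_share"]


class SchemaError(ValueError):
    pass


def load_person_table(path) -> pd.DataFrame:
    """Load and validate a person-level CSV.

    Rows violating the record invariants (non-positive cost, unknown AMG
    code, negative age, sex outside {0, 1}) are rejected with a
    line-numbered report in the log; accepted/rejected counts are logged.
    A missing column or an empty file raises :class:`SchemaError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in PERSON_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")

    bad = pd.DataFrame(
        {
            "cost": ~(df["cost_eur"] > 0),
            "amg": ~df["amg_code"].map(is_valid_code),
            "age": ~(df["age_years"] >= 0),
            "sex": ~df["sex"].isin([0, 1]),
        }
    )
    reject = bad.any(axis=1)
    if reject.any():
        for idx in df.index[reject]:
            reasons = [k for k, v in bad.loc[idx].items() if v]
            # +2: header line plus 1-based numbering
            logger.warning(
                "%s line %d rejected (%s): %s",
                path.name, idx + 2, ",".join(reasons), df.loc[idx].to_dict(),
            )
    kept = df[~reject].reset_index(drop=True)
    logger.info(
        "%s: accepted %d row(s), rejected %d", path.name, len(kept), int(reject.sum())
    )
    if len(kept) == 0:
        raise SchemaError(f"{path}: all rows rejected")
    return kept[PERSON_COLUMNS]


def save_person_table(records: pd.DataFrame, path) -> None:
    records[PERSON_COLUMNS].to_csv(path, index=False)


def load_area_table(path) -> pd.DataFrame:
    """Load the area-level CSV (covered population, historical share)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in AREA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    return df.set_index("area_id")


def save_area_table(areas: pd.DataFrame, path) -> None:
    out = areas.reset_index() if areas.index.name == "area_id" else areas
    out[AREA_COLUMNS].to_csv(path, index=False)
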