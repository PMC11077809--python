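"""Adjusted Morbidity Group (AMG) catalogue.

AMGs stratify an insured population into 31 mutually exclusive groups:
a healthy base group plus six morbidity types (acute pathology, pregnancy
and childbirth, chronic disease in 1 / 2-3 / 4+ organ systems, and active
neoplasm), each split into five complexity levels. Complexity level 5 is
the most severe. Codes are integers: the hundreds digit(s) identify the
morbidity type and the final digit the complexity level; the healthy
group is the single code 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

HEALTHY = "healthy"
ACUTE = "acute"
PREGNANCY = "pregnancy"
CHRONIC_1 = "chronic-1-system"
CHRONIC_2_3 = "chronic-2-3-systems"
CHRONIC_4P = "chronic-4plus-systems"
NEOPLASM = "neoplasm"

#: morbidity-type prefix -> label; each non-healthy type spans codes
#: prefix*10 + 1 .. prefix*10 + 5 (complexity 1..5)
_PREFIX_LABELS = {
    10: ACUTE,
    20: PREGNANCY,
    31: CHRONIC_1,
    32: CHRONIC_2_3,
    33: CHRONIC_4P,
    40: NEOPLASM,
}


@dataclass(frozen=True)
class AMGEntry:
    """One AMG code with its morbidity group and complexity level."""

    code: int
    group: str
    complexity: int | None  # None for the healthy group


def _build_entries() -> tuple[AMGEntry, ...]:
    entries = [AMGEntry(1, HEALTHY, None)]
    for prefix, label in _PREFIX_LABELS.items():
        for level in range(1, 6):
            entries.append(AMGEntry(prefix * 10 + level, label, level))
    return tuple(entries)


AMG_ENTRIES: tuple[AMGEntry, ...] = _build_entries()
AMG_CODES: tuple[int, ...] = tuple(e.code for e in AMG_ENTRIES)
_BY_CODE: dict[int, AMGEntry] = {e.code: e for e in AMG_ENTRIES}

assert len(AMG_CODES) == 31


def amg_entry(code: int) -> AMGEntry:
    """Look up an AMG code; raises KeyError with the offending code."""
    try:
        return _BY_CODE[int(code)]
    except (KeyError, ValueError):
        raise KeyError(f"unknown AMG code: {code!r}") from None


def is_valid_code(code: int) -> bool:
    try:
        return int(code) in _BY_CODE
    except (TypeError, ValueError):
        return False


def catalog_frame() -> pd.DataFrame:
    """The full catalogue as a DataFrame indexed by code."""
    return pd.DataFrame(
        {
            "group": [e.group for e in AMG_ENTRIES],
            "complexity": [e.complexity for e in AMG_ENTRIES],
        },
        index=pd.Index(AMG_CODES, name="amg_code"),
    )


#: open-ended top age band starts at 85
TOP_AGE_BAND = 85
AGE_BANDS: tuple[int, ...] = tuple(range(0, TOP_AGE_BAND + 1, 5))


def age_band(age_years) -> "int | pd.Series":
    """Map age in years to its 5-year band: min(85, 5*floor(age/5)).

    Accepts scalars or array-likes; the top band (85) is open-ended.
    """
    import numpy as np

    banded = np.minimum(TOP_AGE_BAND, 5 * (np.asarray(age_years) // 5))
    if np.ndim(age_years) == 0 and not isinstance(age_years, pd.Series):
        return int(banded)
    return banded.astype(int) if not isinstance(age_years, pd.Series) else pd.Series(
        banded, index=age_years.index
    ).astype(int)
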