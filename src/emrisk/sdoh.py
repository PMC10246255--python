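"""Social-determinants-of-health (SDoH) encoding.

Sequence models in this package consume discrete tokens, so both individual
demographics (age, sex, race) and continuous neighborhood-level indices
(neighborhood socio-economic status, racial segregation, aridity, ...) are
mapped to categorical tokens that can be embedded exactly like diagnosis
codes. Neighborhood indices are keyed by 5-digit zip code and discretized
into empirical quartile bins fitted on the zip-level table.

Binning convention: quartile edges are empirical quantiles (linear
interpolation); bins are right-closed, i.e. a value exactly on an edge falls
in the lower bin. A constant-valued index collapses to a single bin (with a
warning).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = "UNKNOWN"
DEFAULT_AGE_BAND_WIDTH = 10
QUARTILE_PROBS = (0.25, 0.50, 0.75)


def _clean(value: object) -> str:
    """Uppercase a categorical value and normalize whitespace to underscores."""
    return str(value).strip().upper().replace(" ", "_")


# ---------------------------------------------------------------------------
# individual-level demographics
# ---------------------------------------------------------------------------

def encode_individual(
    demographics_row,
    index_date,
    age_band_width: int = DEFAULT_AGE_BAND_WIDTH,
) -> set[str]:
    """Encode one patient's demographics as tokens at the index date.

    Emits ``AGE:<lo>-<hi>`` (age computed at the index date, banded),
    ``SEX:<value>`` and ``RACE:<value>``. A missing field yields the
    corresponding ``...:UNKNOWN`` token.
    """
    tokens: set[str] = set()

    birth_year = demographics_row.get("birth_year")
    if birth_year is None or (isinstance(birth_year, float) and np.isnan(birth_year)):
        tokens.add(f"AGE:{UNKNOWN}")
    else:
        age = int(pd.Timestamp(index_date).year) - int(birth_year)
        lo = (age // age_band_width) * age_band_width
        tokens.add(f"AGE:{lo}-{lo + age_band_width - 1}")

    for token_name, column in (("SEX", "sex"), ("RACE", "race")):
        value = demographics_row.get(column)
        if value is None or (isinstance(value, float) and np.isnan(value)) or str(value) == "":
            tokens.add(f"{token_name}:{UNKNOWN}")
        else:
            tokens.add(f"{token_name}:{_clean(value)}")
    return tokens


# ---------------------------------------------------------------------------
# neighborhood-level indices
# ---------------------------------------------------------------------------

@dataclass
class SDoHTokenization:
    """Per-index quartile bin edges fitted on a zip-level SDoH table.

    ``edges[name]`` holds the (up to 3) interior quantile edges for index
    ``name``; an empty edge array marks a constant (single-bin) index.
    """

    edges: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def index_names(self) -> list[str]:
        return list(self.edges)

    def bin_token(self, name: str, value: float) -> str:
        """Map one (index, value) pair to its bin token (right-closed bins)."""
        if name not in self.edges:
            raise KeyError(f"unknown SDoH index {name!r}")
        if value is None or np.isnan(value):
            return f"{_clean(name)}:{UNKNOWN}"
        # side='left': a value equal to an edge goes to the lower bin
        k = int(np.searchsorted(self.edges[name], value, side="left"))
        return f"{_clean(name)}:Q{k + 1}"

    def all_tokens(self) -> set[str]:
        """Every token this tokenization can emit (excluding UNKNOWN)."""
        out = set()
        for name, e in self.edges.items():
            for k in range(len(e) + 1):
                out.add(f"{_clean(name)}:Q{k + 1}")
        return out

    def to_json(self, path) -> None:
        payload = {name: np.asarray(e).tolist() for name, e in self.edges.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SDoHTokenization":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(edges={k: np.asarray(v, dtype=float) for k, v in payload.items()})


def fit_tokenization(sdoh_table: pd.DataFrame) -> SDoHTokenization:
    """Fit quartile bin edges for each numeric index column of a zip table.

    The table must have one row per zip (column ``zip``) and at least 4 rows.
    Edges are the empirical 25/50/75% quantiles (linear interpolation).
    """
    if len(sdoh_table) < 4:
        raise ValueError("need at least 4 zips to fit quartile bins")
    edges: dict[str, np.ndarray] = {}
    for name in sdoh_table.columns:
        if name == "zip":
            continue
        values = sdoh_table[name].to_numpy(dtype=float)
        values = values[~np.isnan(values)]
        if values.size and np.all(values == values[0]):
            warnings.warn(f"SDoH index {name!r} is constant; using a single bin")
            edges[name] = np.empty(0)
        else:
            edges[name] = np.quantile(values, QUARTILE_PROBS)
    return SDoHTokenization(edges=edges)


def encode_neighborhood(
    zip_code: str,
    sdoh_table: pd.DataFrame,
    tokenization: SDoHTokenization,
) -> set[str]:
    """Encode one zip's neighborhood indices as quartile-bin tokens.

    A zip absent from the table yields ``<INDEX>:UNKNOWN`` for every index.
    """
    rows = sdoh_table.loc[sdoh_table["zip"].astype(str) == str(zip_code)]
    if rows.empty:
        return {f"{_clean(name)}:{UNKNOWN}" for name in tokenization.index_names}
    row = rows.iloc[0]
    return {
        tokenization.bin_token(name, float(row[name]))
        for name in tokenization.index_names
    }
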