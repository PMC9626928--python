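"""Frailty Index construction from a declarative deficit schema.

The Frailty Index (FI) quantifies deficit accumulation: a person's health
deficits (symptoms, diagnoses, impairments spanning physical, psychological
and cognitive systems) are coded present/absent against fixed cutoffs and the
FI is the proportion of deficits present out of the number considered.  The
index lives in [0, 1]; higher values indicate greater frailty, and 0.2 is the
conventional cutpoint separating robust individuals from those approaching a
frail state.

The deficit list is data, not code: a :class:`DeficitSchema` declares, per
item, the source variable, a comparison operator and a cutoff.  Cohorts supply
their own schema (YAML); :func:`default_schema` ships a generic 30-item
schema of threshold rules for simulation and testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaMismatchError

__all__ = [
    "DeficitRule",
    "DeficitSchema",
    "FrailtyScore",
    "default_schema",
    "binarize_deficits",
    "binarize_table",
    "compute_frailty_index",
    "frailty_table",
    "dichotomize_frailty",
]

_OPERATORS = ("ge", "le", "eq", "in_set")


@dataclass(frozen=True)
class DeficitRule:
    """One deficit: a total rule mapping a raw measure to {0, 1, missing}.

    ``direction`` is descriptive metadata (whether higher raw values indicate
    the deficit); the coding itself is fully determined by ``operator`` and
    ``threshold``/``values``.
    """

    name: str
    source: str
    operator: str
    threshold: float | None = None
    values: tuple = ()
    direction: str = "higher_is_deficit"

    def __post_init__(self):
        if self.operator not in _OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}; expected one of {_OPERATORS}")
        if self.operator in ("ge", "le", "eq") and self.threshold is None:
            raise ValueError(f"rule {self.name!r}: operator {self.operator!r} requires a threshold")
        if self.operator == "in_set" and not self.values:
            raise ValueError(f"rule {self.name!r}: operator 'in_set' requires values")

    def apply(self, value) -> float:
        """Code one raw value; missing (None/NaN) propagates as NaN."""
        if value is None:
            return math.nan
        if isinstance(value, float) and math.isnan(value):
            return math.nan
        if self.operator == "ge":
            return float(value >= self.threshold)
        if self.operator == "le":
            return float(value <= self.threshold)
        if self.operator == "eq":
            return float(value == self.threshold)
        return float(value in self.values)


@dataclass(frozen=True)
class DeficitSchema:
    """An ordered collection of deficit rules with unique item names."""

    items: tuple[DeficitRule, ...]

    def __post_init__(self):
        if len(self.items) < 1:
            raise ValueError("a deficit schema needs at least one item")
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate deficit names: {dupes}")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def source_variables(self) -> list[str]:
        return [it.source for it in self.items]

    @classmethod
    def from_yaml(cls, path) -> "DeficitSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        items = []
        for entry in raw["items"]:
            items.append(
                DeficitRule(
                    name=entry["name"],
                    source=entry.get("variable", entry.get("source", entry["name"])),
                    operator=entry["operator"],
                    threshold=entry.get("threshold"),
                    values=tuple(entry.get("values", ())),
                    direction=entry.get("direction", "higher_is_deficit"),
                )
            )
        return cls(tuple(items))

    def to_yaml(self, path) -> None:
        entries = []
        for it in self.items:
            e = {"name": it.name, "variable": it.source, "operator": it.operator,
                 "direction": it.direction}
            if it.threshold is not None:
                e["threshold"] = it.threshold
            if it.values:
                e["values"] = list(it.values)
            entries.append(e)
        with open(path, "w") as fh:
            yaml.safe_dump({"items": entries}, fh, sort_keys=False)


def default_schema(n_items: int = 30) -> DeficitSchema:
    """Generic schema of ``n_items`` binary deficits on 0/1 source variables.

    Source variables are ``d01 .. dNN``; a deficit is present when the raw
    value is >= 0.5 (so 0/1 indicators pass through unchanged).
    """
    items = tuple(
        DeficitRule(name=f"deficit_{i:02d}", source=f"d{i:02d}", operator="ge", threshold=0.5)
        for i in range(1, n_items + 1)
    )
    return DeficitSchema(items)


@dataclass(frozen=True)
class FrailtyScore:
    """Frailty Index for one person-wave."""

    person_id: object
    wave: int
    fi: float
    n_observed: int
    valid: bool


def binarize_deficits(raw_measures: Mapping, schema: DeficitSchema) -> np.ndarray:
    """Code one assessment's raw measures into a deficit vector.

    Returns a float array of length ``schema.n_items`` with entries in
    {0.0, 1.0, NaN}; a missing raw measure yields NaN for its deficit.
    Raises :class:`SchemaMismatchError` when the schema references a source
    variable the record does not carry at all.
    """
    missing_vars = [it.source for it in schema.items if it.source not in raw_measures]
    if missing_vars:
        raise SchemaMismatchError(
            f"schema source variables absent from record: {sorted(set(missing_vars))}"
        )
    return np.array([it.apply(raw_measures[it.source]) for it in schema.items], dtype=float)


def binarize_table(assessments: pd.DataFrame, schema: DeficitSchema) -> pd.DataFrame:
    """Vectorized deficit coding for a person-wave assessment table.

    ``assessments`` must have ``person_id`` and ``wave`` columns plus every
    schema source variable as a column.  Returns one column per deficit item.
    """
    missing = [v for v in schema.source_variables if v not in assessments.columns]
    if missing:
        raise SchemaMismatchError(f"schema source variables absent from table: {sorted(set(missing))}")
    out = assessments[["person_id", "wave"]].copy()
    for it in schema.items:
        col = assessments[it.source]
        vals = col.to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        coded = np.full(len(vals), np.nan)
        if it.operator == "ge":
            coded[ok] = (vals[ok] >= it.threshold).astype(float)
        elif it.operator == "le":
            coded[ok] = (vals[ok] <= it.threshold).astype(float)
        elif it.operator == "eq":
            coded[ok] = (vals[ok] == it.threshold).astype(float)
        else:
            coded[ok] = np.isin(vals[ok], list(it.values)).astype(float)
        out[it.name] = coded
    return out


def compute_frailty_index(
    values: Sequence[float] | np.ndarray,
    min_observed_fraction: float = 0.8,
    person_id=None,
    wave: int = 0,
) -> FrailtyScore:
    """Score one deficit vector as a Frailty Index.

    With complete data the FI is (number of deficits present) / (number of
    items).  With missing items the denominator is rescaled to the observed
    count provided at least ``min_observed_fraction`` of items were observed;
    below that the score is flagged invalid (``valid=False``, ``fi=NaN``)
    rather than raised.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("deficit vector must have length >= 1")
    observed = ~np.isnan(v)
    n_obs = int(observed.sum())
    if n_obs == 0 or n_obs / v.size < min_observed_fraction:
        return FrailtyScore(person_id, wave, math.nan, n_obs, False)
    fi = float(np.nansum(v) / n_obs)
    return FrailtyScore(person_id, wave, fi, n_obs, True)


def frailty_table(
    assessments: pd.DataFrame,
    schema: DeficitSchema,
    min_observed_fraction: float = 0.8,
) -> pd.DataFrame:
    """Frailty Index per person-wave from a raw assessment table.

    Returns columns ``person_id, wave, age (if present), fi, n_observed,
    valid``.
    """
    deficits = binarize_table(assessments, schema)
    mat = deficits[schema.item_names].to_numpy(dtype=float)
    observed = ~np.isnan(mat)
    n_obs = observed.sum(axis=1)
    with np.errstate(invalid="ignore"):
        fi = np.nansum(mat, axis=1) / np.where(n_obs > 0, n_obs, 1)
    valid = (n_obs / schema.n_items) >= min_observed_fraction
    fi = np.where(valid & (n_obs > 0), fi, np.nan)
    out = deficits[["person_id", "wave"]].copy()
    if "age" in assessments.columns:
        out["age"] = assessments["age"].to_numpy()
    out["fi"] = fi
    out["n_observed"] = n_obs
    out["valid"] = valid & (n_obs > 0)
    return out


def dichotomize_frailty(score: FrailtyScore | float, cutpoint: float = 0.2) -> str | float:
    """Classify a frailty score as ``"robust"`` or ``"frail"``.

    The cutpoint is inclusive: fi == cutpoint is classed frail.  An invalid
    score (or NaN fi) yields NaN (missing outcome).
    """
    if isinstance(score, FrailtyScore):
        if not score.valid:
            return math.nan
        fi = score.fi
    else:
        fi = float(score)
    if math.isnan(fi):
        return math.nan
    return "frail" if fi >= cutpoint else "robust"
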