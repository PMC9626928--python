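"""Neighborhood social deprivation (NSD) exposure encoding across the life course.

Ward-level deprivation indices, measured once per decade, are standardized
within decade (z-scores over wards), linked to each person's residential
history through ten-year windows centred on the index year, averaged within
three developmental periods — childhood (1936-1955), young adulthood
(1956-1975) and mid- to late adulthood (1976-2014) — and finally encoded as
six competing life-course hypothesis variables:

* three *sensitive period* variables (the period means themselves),
* *accumulation* (the mean of the three period means), and
* two *effect modification* products, early life (childhood x young
  adulthood) and later life (young adulthood x mid-late adulthood), each
  factor offset by +10 so the multiplication does not cross zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDecadeError

__all__ = [
    "PeriodDefinitions",
    "DEFAULT_PERIODS",
    "zscore_by_decade",
    "bin_address_years",
    "link_decades",
    "period_means",
    "encode_life_course",
    "tertile_encode",
    "EM_OFFSET",
]

logger = logging.getLogger(__name__)

#: Offset added to period means before forming effect-modification products.
EM_OFFSET = 10.0

_PERIOD_COLS = ("childhood", "young_adulthood", "mid_late_adulthood")


@dataclass(frozen=True)
class PeriodDefinitions:
    """Mapping of developmental periods to the decade index years they cover."""

    childhood: tuple[int, ...] = (1941, 1951)
    young_adulthood: tuple[int, ...] = (1961, 1971)
    mid_late_adulthood: tuple[int, ...] = (1981, 1991, 2001, 2011)

    def as_dict(self) -> dict[str, tuple[int, ...]]:
        return {
            "childhood": self.childhood,
            "young_adulthood": self.young_adulthood,
            "mid_late_adulthood": self.mid_late_adulthood,
        }

    def all_decades(self) -> list[int]:
        return sorted(self.childhood + self.young_adulthood + self.mid_late_adulthood)

    def truncated(self, last_calendar_year: int) -> "PeriodDefinitions":
        """Drop decades whose ten-year window extends past ``last_calendar_year``.

        A decade index year ``d`` covers calendar years [d-5, d+4]; it is kept
        when d+4 <= ``last_calendar_year``.
        """
        keep = lambda ds: tuple(d for d in ds if d + 4 <= last_calendar_year)
        return PeriodDefinitions(
            keep(self.childhood), keep(self.young_adulthood), keep(self.mid_late_adulthood)
        )


DEFAULT_PERIODS = PeriodDefinitions()


def zscore_by_decade(wards: pd.DataFrame) -> pd.DataFrame:
    """Standardize ward deprivation indices within each decade.

    ``wards`` has columns ``ward_id, decade_year, raw_index``.  Within every
    decade the raw index is centred and scaled by the sample standard
    deviation (n-1 denominator), making wards comparable across decades.
    Returns ``ward_id, decade_year, z``.

    Raises :class:`DegenerateDecadeError` (naming the decade) when a decade
    has fewer than two wards with data or zero spread.
    """
    out = []
    for decade, grp in wards.groupby("decade_year"):
        vals = grp["raw_index"].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if ok.sum() < 2:
            raise DegenerateDecadeError(f"decade {decade}: fewer than 2 wards with index values")
        sd = vals[ok].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateDecadeError(f"decade {decade}: zero spread in ward index values")
        z = (vals - vals[ok].mean()) / sd
        out.append(pd.DataFrame({"ward_id": grp["ward_id"], "decade_year": decade, "z": z}))
    return pd.concat(out, ignore_index=True)


def bin_address_years(years) -> np.ndarray:
    """Map raw address calendar years to decade index years.

    The decade indexed at year ``d`` (1941, 1951, ...) covers addresses from
    ``d - 5`` through ``d + 4``; e.g. the 1941 index is linked to addresses
    from 1936-1945.
    """
    y = np.asarray(years, dtype=int)
    return ((y - 6) // 10) * 10 + 11


def link_decades(
    history: pd.DataFrame,
    zscores: pd.DataFrame,
    year_range: tuple[int, int] = (1936, 2014),
) -> pd.DataFrame:
    """Attach decade ward z-scores to a residential history.

    ``history`` has columns ``person_id, decade_year, ward_id`` (ward_id may
    be missing for addresses outside the study area); ``zscores`` is the
    output of :func:`zscore_by_decade`.  A person with several wards recorded
    in one decade receives the mean of their z-scores.  Decades outside
    ``year_range`` are dropped with a logged warning.  Returns one row per
    (person, decade) with column ``nsd`` (NaN when unlinkable).
    """
    h = history.copy()
    d = h["decade_year"].to_numpy()
    in_range = (d >= bin_address_years([year_range[0]])[0] - 10) & (d - 5 <= year_range[1])
    if (~in_range).any():
        bad = sorted(set(d[~in_range].tolist()))
        logger.warning("ignoring %d history rows in decades outside %s: %s",
                       int((~in_range).sum()), year_range, bad)
        h = h.loc[in_range]
    merged = h.merge(zscores, on=["ward_id", "decade_year"], how="left")
    out = (
        merged.groupby(["person_id", "decade_year"], as_index=False)["z"]
        .mean()
        .rename(columns={"z": "nsd"})
    )
    return out


def period_means(
    exposures: pd.DataFrame,
    periods: PeriodDefinitions = DEFAULT_PERIODS,
) -> pd.DataFrame:
    """Average per-decade NSD within developmental periods.

    Each period mean uses whichever of its decades carry an exposure (equal
    decade weights); a person is ``eligible`` only when all three period
    means are defined — i.e. at least one linked address in every period.
    """
    pdefs = periods.as_dict()
    persons = exposures[["person_id"]].drop_duplicates().reset_index(drop=True)
    out = persons.copy()
    for name, decades in pdefs.items():
        sub = exposures[exposures["decade_year"].isin(decades)]
        m = sub.groupby("person_id")["nsd"].mean()
        out[name] = out["person_id"].map(m)
    out["eligible"] = out[list(_PERIOD_COLS)].notna().all(axis=1)
    return out


def encode_life_course(period_exposures: pd.DataFrame) -> pd.DataFrame:
    """Encode the six competing life-course variables per eligible person.

    Rows with ``eligible == False`` are excluded (reason logged).  The
    effect-modification products offset both factors by ``EM_OFFSET`` (+10)
    to avoid sign flips during multiplication; period means at or below -10
    trigger a warning because they defeat the offset.
    """
    pe = period_exposures
    if "eligible" in pe.columns:
        n_drop = int((~pe["eligible"]).sum())
        if n_drop:
            logger.info("excluding %d persons without exposure in all three periods", n_drop)
        pe = pe[pe["eligible"]]
    ch = pe["childhood"].to_numpy(dtype=float)
    yo = pe["young_adulthood"].to_numpy(dtype=float)
    mi = pe["mid_late_adulthood"].to_numpy(dtype=float)
    if np.any(np.concatenate([ch, yo, mi]) <= -EM_OFFSET):
        warnings.warn(
            f"period mean NSD at or below -{EM_OFFSET:g}; effect-modification offset "
            "does not guarantee positive factors", stacklevel=2,
        )
    return pd.DataFrame(
        {
            "person_id": pe["person_id"].to_numpy(),
            "sp_child": ch,
            "sp_young": yo,
            "sp_midlate": mi,
            "accumulation": (ch + yo + mi) / 3.0,
            "em_early": (ch + EM_OFFSET) * (yo + EM_OFFSET),
            "em_late": (yo + EM_OFFSET) * (mi + EM_OFFSET),
        }
    )


def tertile_encode(values) -> pd.Categorical:
    """Cut a continuous exposure into low / moderate / high tertiles.

    Cutpoints are the 1/3 and 2/3 sample quantiles (nearest-rank style via
    the empirical distribution); under no ties the three groups differ in
    size by at most one.  Heavy ties that empty a category produce a warning
    and the category is retained (possibly empty) in the categorical's levels.
    """
    v = np.asarray(values, dtype=float)
    finite = v[~np.isnan(v)]
    if np.unique(finite).size < 3:
        warnings.warn("fewer than 3 distinct exposure values; tertiles are degenerate",
                      stacklevel=2)
    q1, q2 = np.quantile(finite, [1 / 3, 2 / 3], method="inverted_cdf")
    labels = np.full(v.shape, None, dtype=object)
    labels[~np.isnan(v)] = "moderate"
    labels[v <= q1] = "low"
    labels[v > q2] = "high"
    cat = pd.Categorical(labels, categories=["low", "moderate", "high"], ordered=True)
    counts = cat.value_counts()
    if (counts == 0).any():
        warnings.warn(f"tie-collapsed tertile categories: {counts.to_dict()}", stacklevel=2)
    return cat
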