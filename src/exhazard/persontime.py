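"""Lexis expansion of waitlist follow-up into piecewise-constant intervals.

Each candidate's follow-up (waitlist activation to death / transplant /
administrative censoring) is split into maximal sub-intervals on which

* follow-up band (time since listing),
* analysis age category (0-12, 13-24, 25-44, 45-59, >=60 y),
* life-table age band, and
* calendar year

are all constant, so that the expected hazard and every time-varying
covariate are constant within a row.  Breakpoints are the union of listing
anniversaries and configured follow-up band edges, every January 1, and every
birthday on which the candidate crosses a life-table band edge or an analysis
age-category edge.  Intervals are half-open ``[t_start, t_stop)`` with the
death indicator on the final interval; splitting finer never changes
aggregate (O, E, PY) by stratum.

Time is measured in years of 365.25 days; age-category and band transitions
occur on the calendar birthday.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .lifetables import LifeTable, hazard_from_annual_prob

__all__ = [
    "AGE_CATEGORY_EDGES",
    "AGE_CATEGORY_LABELS",
    "DEFAULT_FOLLOWUP_BANDS",
    "DEFAULT_ERA_PARTITION",
    "Candidate",
    "PersonInterval",
    "CohortSchemaError",
    "split_follow_up",
    "expand_cohort",
    "expected_deaths",
    "read_cohort",
    "write_cohort",
    "write_persontime",
    "assign_era",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
#: Minimum follow-up (years) for an outcome on the listing date: half a day.
MIN_FOLLOWUP_YEARS = 0.5 / DAYS_PER_YEAR

AGE_CATEGORY_EDGES = (0, 13, 25, 45, 60)
AGE_CATEGORY_LABELS = ("0-12", "13-24", "25-44", "45-59", ">=60")

#: Default follow-up band edges (years since listing); last band is open.
DEFAULT_FOLLOWUP_BANDS = (0.0, 1.0, 2.0, 3.0, 5.0, 10.0)

#: Waitlisting-era partition used throughout unless overridden.
DEFAULT_ERA_PARTITION = ((1988, 1998), (1999, 2008), (2009, 2019))

OUTCOME_TYPES = ("death", "transplant", "administrative")

COHORT_COLUMNS = [
    "id",
    "sex",
    "race",
    "birth_date",
    "listing_date",
    "organ",
    "primary_disease",
    "outcome_date",
    "outcome_type",
]

PERSONTIME_COLUMNS = [
    "candidate_id",
    "t_start",
    "t_stop",
    "duration",
    "death",
    "expected_hazard",
    "followup_band",
    "age_category",
    "calendar_year",
    "age_years",
    "sex",
    "race",
    "primary_disease",
    "organ",
    "listing_year",
    "era",
]


class CohortSchemaError(ValueError):
    """Raised when a cohort table violates the documented schema."""


@dataclass(frozen=True)
class Candidate:
    """One waitlisted person with covariates and outcome."""

    id: str
    sex: str
    race: str
    birth_date: date
    listing_date: date
    organ: str
    primary_disease: str
    outcome_date: date
    outcome_type: str

    def __post_init__(self):
        if self.outcome_date < self.listing_date:
            raise CohortSchemaError(
                f"candidate {self.id}: outcome before listing"
            )
        if self.birth_date >= self.listing_date:
            raise CohortSchemaError(
                f"candidate {self.id}: birth date not before listing date"
            )
        if self.outcome_type not in OUTCOME_TYPES:
            raise CohortSchemaError(
                f"candidate {self.id}: unknown outcome type {self.outcome_type!r}"
            )


@dataclass(frozen=True)
class PersonInterval:
    """One row of the expanded dynamic dataset."""

    candidate_id: str
    t_start: float
    t_stop: float
    duration: float
    death: int
    expected_hazard: float
    followup_band: str
    age_category: str
    calendar_year: int
    age_years: float
    sex: str
    race: str
    primary_disease: str
    organ: str
    listing_year: int
    era: str


def assign_era(listing_years, partition=DEFAULT_ERA_PARTITION):
    """Map listing years to era labels ``"lo-hi"`` under ``partition``.

    Raises if any year is not covered (the partition must cover the cohort).
    """
    years = np.asarray(listing_years, dtype=int)
    labels = np.empty(years.shape, dtype=object)
    covered = np.zeros(years.shape, dtype=bool)
    for lo, hi in partition:
        m = (years >= lo) & (years <= hi)
        labels[m] = f"{lo}-{hi}"
        covered |= m
    if not covered.all():
        missing = sorted(set(years[~covered].tolist()))
        raise CohortSchemaError(
            f"era partition {partition} does not cover listing years {missing}"
        )
    return labels


def _add_years(d: date, n: int) -> date:
    """The n-th birthday of someone born on ``d`` (Feb 29 -> Feb 28)."""
    try:
        return d.replace(year=d.year + n)
    except ValueError:
        return d.replace(year=d.year + n, month=2, day=28)


def _completed_age(birth: date, on: date) -> int:
    a = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        a -= 1
    return a


def _candidate_breakpoints(
    birth: date,
    listing: date,
    total_days: float,
    fu_edges_days: np.ndarray,
    age_edges: np.ndarray,
    cat_edge_set: frozenset,
):
    """Breakpoints (days since listing) with state-change annotations.

    Returns a sorted list of ``(day, kind, value)`` where kind is ``"y"``
    (January 1; value unused), ``"b"`` (birthday crossing an age edge; value
    is the integer age attained), or ``"a"`` (anniversary / follow-up band
    edge; no state change).
    """
    pts = []
    l_ord = listing.toordinal()
    end = total_days

    # (a) listing anniversaries and configured follow-up band edges
    n_years = int(end / DAYS_PER_YEAR) + 1
    anniv = {round(k * DAYS_PER_YEAR, 6) for k in range(1, n_years + 1)}
    anniv.update(round(e, 6) for e in fu_edges_days)
    for t in anniv:
        if 0.0 < t < end:
            pts.append((t, "a", 0))

    # (b) January 1
    y = listing.year + 1
    while True:
        t = float(date(y, 1, 1).toordinal() - l_ord)
        if t >= end:
            break
        if t > 0:
            pts.append((t, "y", 0))
        y += 1

    # (c) birthdays crossing a life-table band edge or age-category edge
    a0 = _completed_age(birth, listing)
    for a in age_edges:
        a = int(a)
        if a <= a0:
            continue
        t = float(_add_years(birth, a).toordinal() - l_ord)
        if t >= end:
            break
        if t > 0:
            pts.append((t, "b", a))

    pts.sort(key=lambda p: p[0])
    return pts


def _expand_arrays(
    cohort: pd.DataFrame,
    table: LifeTable,
    fu_bands,
    era_partition,
):
    """Core expansion: returns the person-time table as a DataFrame.

    Operates on the cohort row-wise (breakpoint logic is inherently
    per-candidate) but defers every life-table lookup to one vectorised
    fancy-indexing pass at the end.
    """
    fu_edges = np.asarray(sorted(set(fu_bands)), dtype=float)
    if fu_edges[0] != 0 or np.any(np.diff(fu_edges) <= 0):
        raise CohortSchemaError(
            "follow-up bands must be strictly increasing and start at 0"
        )
    fu_edges_days = fu_edges[1:] * DAYS_PER_YEAR

    lt_edges = table.band_edges[1:]  # band-crossing ages (0 excluded)
    cat_edges = np.asarray(AGE_CATEGORY_EDGES[1:], dtype=float)
    age_edges = np.unique(np.concatenate([lt_edges, cat_edges])).astype(int)
    cat_edge_set = frozenset(int(a) for a in cat_edges)
    cat_edges_arr = np.asarray(AGE_CATEGORY_EDGES, dtype=float)

    sex_idx_map = {s: table.sex_index(s) for s in cohort["sex"].unique()}
    race_idx_map = {r: table.race_index(r) for r in cohort["race"].unique()}

    ids = cohort["id"].to_numpy()
    sexes = cohort["sex"].to_numpy()
    races = cohort["race"].to_numpy()
    births = cohort["birth_date"].to_numpy()
    listings = cohort["listing_date"].to_numpy()
    outcomes = cohort["outcome_date"].to_numpy()
    otypes = cohort["outcome_type"].to_numpy()

    # per-row accumulators (python lists; converted once at the end)
    r_cand = []
    r_start = []
    r_stop = []
    r_year = []
    r_band = []
    r_cat = []
    r_death = []

    band_edges = table.band_edges

    for i in range(len(cohort)):
        birth = births[i]
        listing = listings[i]
        outcome = outcomes[i]
        if outcome < listing:
            raise CohortSchemaError(f"candidate {ids[i]}: outcome before listing")
        if birth >= listing:
            raise CohortSchemaError(
                f"candidate {ids[i]}: birth date not before listing date"
            )
        total_days = float((outcome - listing).days)
        if total_days == 0.0:
            total_days = 0.5  # epsilon rule: half a registry day

        pts = _candidate_breakpoints(
            birth, listing, total_days, fu_edges_days, age_edges, cat_edge_set
        )

        a0 = _completed_age(birth, listing)
        band = int(np.searchsorted(band_edges, a0, side="right") - 1)
        cat = int(np.searchsorted(cat_edges_arr, a0, side="right") - 1)
        year = listing.year
        prev = 0.0
        is_death = otypes[i] == "death"

        for t, kind, val in pts:
            if t <= prev:  # duplicate breakpoint (e.g. anniversary == Jan 1)
                if kind == "y":
                    year += 1
                elif kind == "b":
                    band = int(np.searchsorted(band_edges, val, side="right") - 1)
                    if val in cat_edge_set:
                        cat = int(
                            np.searchsorted(cat_edges_arr, val, side="right") - 1
                        )
                continue
            r_cand.append(i)
            r_start.append(prev)
            r_stop.append(t)
            r_year.append(year)
            r_band.append(band)
            r_cat.append(cat)
            r_death.append(0)
            prev = t
            if kind == "y":
                year += 1
            elif kind == "b":
                band = int(np.searchsorted(band_edges, val, side="right") - 1)
                if val in cat_edge_set:
                    cat = int(np.searchsorted(cat_edges_arr, val, side="right") - 1)
        # final interval
        r_cand.append(i)
        r_start.append(prev)
        r_stop.append(total_days)
        r_year.append(year)
        r_band.append(band)
        r_cat.append(cat)
        r_death.append(1 if is_death else 0)

    cand = np.asarray(r_cand, dtype=np.int64)
    start_d = np.asarray(r_start, dtype=float)
    stop_d = np.asarray(r_stop, dtype=float)
    year = np.asarray(r_year, dtype=np.int64)
    band = np.asarray(r_band, dtype=np.int64)
    cat = np.asarray(r_cat, dtype=np.int64)
    death = np.asarray(r_death, dtype=np.int64)

    # vectorised expected-hazard lookup
    haz_grid = table.hazard_grid()
    sx = np.fromiter((sex_idx_map[s] for s in sexes[cand]), dtype=np.int64,
                     count=len(cand))
    rc = np.fromiter((race_idx_map[r] for r in races[cand]), dtype=np.int64,
                     count=len(cand))
    yi = np.asarray(table.clamp_year(year)) - table.year_range[0]
    lam = haz_grid[sx, rc, yi, band]
    if np.isnan(lam).any():
        raise CohortSchemaError("life table has missing cells for some intervals")

    t_start = start_d / DAYS_PER_YEAR
    t_stop = stop_d / DAYS_PER_YEAR
    fu_band_idx = np.searchsorted(fu_edges, t_start, side="right") - 1
    fu_labels = _band_labels(fu_edges)

    l_years = np.fromiter((d.year for d in listings), dtype=np.int64,
                          count=len(listings))
    age_at_listing = (
        np.fromiter((d.toordinal() for d in listings), dtype=float,
                    count=len(listings))
        - np.fromiter((d.toordinal() for d in births), dtype=float,
                      count=len(births))
    ) / DAYS_PER_YEAR

    df = pd.DataFrame(
        {
            "candidate_id": ids[cand],
            "t_start": t_start,
            "t_stop": t_stop,
            "duration": (stop_d - start_d) / DAYS_PER_YEAR,
            "death": death,
            "expected_hazard": lam,
            "followup_band": pd.Categorical.from_codes(
                fu_band_idx, categories=fu_labels
            ),
            "age_category": pd.Categorical.from_codes(
                cat, categories=list(AGE_CATEGORY_LABELS)
            ),
            "calendar_year": year,
            "age_years": age_at_listing[cand] + t_start,
            "sex": sexes[cand],
            "race": races[cand],
            "primary_disease": cohort["primary_disease"].to_numpy()[cand],
            "organ": cohort["organ"].to_numpy()[cand],
            "listing_year": l_years[cand],
        }
    )
    df["era"] = assign_era(df["listing_year"], era_partition)
    return df


def _band_labels(edges: np.ndarray) -> list:
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    labels.append(f"[{edges[-1]:g},inf)")
    return labels


def expand_cohort(
    cohort: pd.DataFrame,
    table: LifeTable,
    fu_bands=DEFAULT_FOLLOWUP_BANDS,
    era_partition=DEFAULT_ERA_PARTITION,
) -> pd.DataFrame:
    """Expand a cohort table into the person-time (Lexis) table.

    Parameters
    ----------
    cohort : DataFrame
        Columns ``id, sex, race, birth_date, listing_date, organ,
        primary_disease, outcome_date, outcome_type`` with
        :class:`datetime.date` (or ISO-8601 string) date columns.
    table : LifeTable
        Source of expected hazards; calendar years outside its coverage are
        clamped with a warning.
    fu_bands : sequence of float
        Follow-up band edges in years since listing, starting at 0; the last
        band is open-ended.  Listing anniversaries are always added as
        breakpoints, so bands finer than 1 year only refine the split.
    era_partition : sequence of (lo, hi)
        Waitlisting-era partition applied to the listing year.

    Returns
    -------
    DataFrame
        One :class:`PersonInterval` per row (documented column order in
        ``PERSONTIME_COLUMNS``), ordered by candidate then ``t_start``.
    """
    cohort = _coerce_cohort(cohort)
    df = _expand_arrays(cohort, table, fu_bands, era_partition)
    return df[PERSONTIME_COLUMNS]


def split_follow_up(
    candidate: Candidate,
    table: LifeTable,
    bands=DEFAULT_FOLLOWUP_BANDS,
    era_partition=DEFAULT_ERA_PARTITION,
):
    """Split one candidate's follow-up; returns an ordered list of intervals.

    Thin single-candidate wrapper over :func:`expand_cohort`.
    """
    cohort = pd.DataFrame([{c: getattr(candidate, c) for c in COHORT_COLUMNS}])
    df = expand_cohort(cohort, table, bands, era_partition)
    return [PersonInterval(**row) for row in df.to_dict("records")]


def expected_deaths(intervals: pd.DataFrame, by=None) -> pd.DataFrame:
    """Observed deaths O, expected deaths E and person-years PY by stratum.

    ``E = sum(lambda*_j t_j)``, ``O = sum(d_j)``, ``PY = sum(t_j)``; totals
    over strata equal the unstratified totals by construction.

    Parameters
    ----------
    intervals : DataFrame
        Person-time table from :func:`expand_cohort`.
    by : list of str, optional
        Stratification columns; ``None`` gives a single overall row.
    """
    if len(intervals) == 0:
        raise CohortSchemaError("no person-time intervals supplied")
    work = intervals.assign(
        _e=intervals["expected_hazard"] * intervals["duration"]
    )
    if by:
        unknown = set(by) - set(intervals.columns)
        if unknown:
            raise CohortSchemaError(f"unknown grouping keys {sorted(unknown)}")
        g = work.groupby(list(by), observed=True)
        out = g.agg(O=("death", "sum"), E=("_e", "sum"), PY=("duration", "sum"))
        return out.reset_index()
    return pd.DataFrame(
        {
            "O": [int(work["death"].sum())],
            "E": [float(work["_e"].sum())],
            "PY": [float(work["duration"].sum())],
        }
    )


# -- cohort I/O --------------------------------------------------------


def _coerce_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise CohortSchemaError(f"cohort table missing columns {sorted(missing)}")
    df = cohort[COHORT_COLUMNS].copy()
    for col in ("birth_date", "listing_date", "outcome_date"):
        if len(df) and not isinstance(df[col].iloc[0], date):
            df[col] = pd.to_datetime(df[col], format="ISO8601").dt.date
    bad = ~df["outcome_type"].isin(OUTCOME_TYPES)
    if bad.any():
        raise CohortSchemaError(
            f"unknown outcome_type in rows {list(df.index[bad])}"
        )
    return df


def read_cohort(path) -> pd.DataFrame:
    """Read a candidate CSV (ISO-8601 dates; ``#`` comment lines ignored)."""
    df = pd.read_csv(path, comment="#", dtype={"id": str})
    return _coerce_cohort(df)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def write_persontime(intervals: pd.DataFrame, path) -> None:
    """Write the expanded person-time table (documented column order)."""
    intervals[PERSONTIME_COLUMNS].to_csv(path, index=False)
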