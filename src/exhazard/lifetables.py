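"""General-population life tables and expected (background) hazards.

A :class:`LifeTable` stores annual death probabilities ``q`` of the general
population indexed by sex, race, calendar year and abridged age band
(``<1``, ``1-4``, ``5-9``, then 5-year bands).  Under the constant-hazard-
within-interval assumption each ``q`` is equivalent to a hazard rate
``lambda = -ln(1 - q)`` per person-year, which is what relative-survival
models consume as the *expected* hazard of a matched population member.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SEX_LEVELS",
    "RACE_LEVELS",
    "LifeTableCell",
    "LifeTable",
    "LifeTableError",
    "hazard_from_annual_prob",
    "expected_death_prob",
    "read_lifetable",
    "write_lifetable",
    "standard_band_edges",
]

logger = logging.getLogger(__name__)

SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("White", "Black", "other")

#: Conventional open upper bound of the last age band.
MAX_AGE = 120


class LifeTableError(ValueError):
    """Raised for invalid life-table values, schemas or lookups."""


def standard_band_edges(max_age: int = MAX_AGE) -> np.ndarray:
    """Lower edges of the abridged age-band scheme <1, 1-4, 5-9, 10-14, ...

    Returns the array ``[0, 1, 5, 10, 15, ...]`` up to (excluding) ``max_age``.
    """
    return np.concatenate([[0, 1], np.arange(5, max_age, 5)])


def hazard_from_annual_prob(q, cell: str | None = None):
    """Constant hazard (per person-year) equivalent to annual death probability.

    Solves ``1 - exp(-lambda) = q`` for ``lambda``; accepts scalars or arrays.

    Parameters
    ----------
    q : float or array-like
        Annual probability of death, in ``[0, 1)``.
    cell : str, optional
        Label used in the error message when ``q`` is out of range.

    Raises
    ------
    LifeTableError
        If any ``q`` is negative or >= 1.
    """
    arr = np.asarray(q, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        where = f" in cell {cell}" if cell else ""
        raise LifeTableError(
            f"annual death probability must lie in [0, 1); got {arr!r}{where}"
        )
    lam = -np.log1p(-arr)
    return float(lam) if np.isscalar(q) or arr.ndim == 0 else lam


def expected_death_prob(hazard, duration):
    """Probability of death within ``duration`` years under a constant hazard.

    ``1 - exp(-hazard * duration)``, the inverse of
    :func:`hazard_from_annual_prob` when ``duration == 1``.
    """
    h = np.asarray(hazard, dtype=float)
    d = np.asarray(duration, dtype=float)
    if np.any(h < 0) or np.any(d < 0):
        raise LifeTableError("hazard and duration must be non-negative")
    p = -np.expm1(-h * d)
    scalar = np.isscalar(hazard) and np.isscalar(duration)
    return float(p) if scalar else p


@dataclass(frozen=True)
class LifeTableCell:
    """One stratum-year-band cell of an abridged life table."""

    sex: str
    race: str
    year: int
    age_lo: int
    age_hi: int
    annual_q: float

    def __post_init__(self):
        if not 0 <= self.annual_q < 1:
            raise LifeTableError(
                f"annual_q must be in [0, 1) in cell "
                f"({self.sex}, {self.race}, {self.year}, {self.age_lo}-{self.age_hi}): "
                f"{self.annual_q}"
            )
        if self.age_hi <= self.age_lo:
            raise LifeTableError(
                f"age_hi must exceed age_lo in cell "
                f"({self.sex}, {self.race}, {self.year}, {self.age_lo}-{self.age_hi})"
            )


@dataclass
class LifeTable:
    """Expected-mortality table over sex x race x calendar year x age band.

    The constructor validates the full cross-product: every (sex, race, year,
    age band) within the declared coverage must resolve to exactly one cell,
    and age bands must tile ``[0, age_max)`` without gaps or overlaps with the
    same band scheme in every stratum.

    Internally the probabilities are held in a dense array
    ``q[sex, race, year, band]`` so that vectorised lookups over millions of
    person-intervals are a single fancy-indexing operation.
    """

    cells: pd.DataFrame
    provenance: str = ""
    # derived, filled in __post_init__
    sexes: tuple = field(init=False)
    races: tuple = field(init=False)
    year_range: tuple = field(init=False)
    band_edges: np.ndarray = field(init=False)

    _COLUMNS = ["sex", "race", "year", "age_lo", "age_hi", "annual_q"]

    def __post_init__(self):
        if isinstance(self.cells, pd.DataFrame):
            df = self.cells[self._COLUMNS].copy()
        else:  # iterable of LifeTableCell
            df = pd.DataFrame(
                [
                    (c.sex, c.race, c.year, c.age_lo, c.age_hi, c.annual_q)
                    for c in self.cells
                ],
                columns=self._COLUMNS,
            )
        if df.empty:
            raise LifeTableError("life table has no cells")
        bad = df[(df.annual_q < 0) | (df.annual_q >= 1)]
        if len(bad):
            raise LifeTableError(
                f"annual_q outside [0, 1) in rows {list(bad.index)}"
            )
        dup = df.duplicated(subset=["sex", "race", "year", "age_lo"])
        if dup.any():
            raise LifeTableError(f"duplicate cells in rows {list(df.index[dup])}")

        self.sexes = tuple(sorted(df.sex.unique()))
        self.races = tuple(sorted(df.race.unique()))
        unknown_sex = set(self.sexes) - set(SEX_LEVELS)
        unknown_race = set(self.races) - set(RACE_LEVELS)
        if unknown_sex or unknown_race:
            raise LifeTableError(
                f"unknown sex/race levels: {unknown_sex | unknown_race}"
            )
        years = np.sort(df.year.unique())
        if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise LifeTableError("calendar-year coverage has gaps")
        self.year_range = (int(years[0]), int(years[-1]))

        # every stratum must share one contiguous band scheme starting at 0
        ref = None
        for (sex, race, year), grp in df.groupby(["sex", "race", "year"]):
            g = grp.sort_values("age_lo")
            lo = g.age_lo.to_numpy()
            hi = g.age_hi.to_numpy()
            if lo[0] != 0 or np.any(lo[1:] != hi[:-1]):
                raise LifeTableError(
                    f"age bands not contiguous from 0 in stratum "
                    f"({sex}, {race}, {year}): rows {list(g.index)}"
                )
            if ref is None:
                ref = lo
            elif not np.array_equal(lo, ref):
                raise LifeTableError(
                    f"band scheme differs in stratum ({sex}, {race}, {year})"
                )
        self.band_edges = ref.astype(float)
        self.age_max = int(df.age_hi.max())

        n_expected = (
            len(self.sexes) * len(self.races) * len(years) * len(self.band_edges)
        )
        if len(df) != n_expected:
            raise LifeTableError(
                "missing cells inside declared coverage: expected "
                f"{n_expected} rows, found {len(df)}"
            )

        # dense grid for vectorised lookup
        sx = df.sex.map({s: i for i, s in enumerate(self.sexes)}).to_numpy()
        rc = df.race.map({r: i for i, r in enumerate(self.races)}).to_numpy()
        yr = (df.year - self.year_range[0]).to_numpy()
        bd = np.searchsorted(self.band_edges, df.age_lo.to_numpy(), side="right") - 1
        grid = np.full(
            (len(self.sexes), len(self.races), len(years), len(self.band_edges)),
            np.nan,
        )
        grid[sx, rc, yr, bd] = df.annual_q.to_numpy()
        self._q_grid = grid
        self.cells = df.sort_values(["sex", "race", "year", "age_lo"]).reset_index(
            drop=True
        )

    # -- index helpers -------------------------------------------------

    def sex_index(self, sex):
        try:
            return self.sexes.index(sex)
        except ValueError:
            raise LifeTableError(f"unknown sex level {sex!r}; table has {self.sexes}")

    def race_index(self, race):
        try:
            return self.races.index(race)
        except ValueError:
            raise LifeTableError(
                f"unknown race level {race!r}; table has {self.races}"
            )

    def band_index(self, age):
        """Index of the age band containing exact ``age`` (years)."""
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise LifeTableError("age must be non-negative")
        idx = np.searchsorted(self.band_edges, age, side="right") - 1
        return idx if idx.ndim else int(idx)

    def clamp_year(self, year):
        """Clamp calendar years to coverage, warning once per call if needed."""
        y = np.asarray(year)
        lo, hi = self.year_range
        if np.any(y < lo) or np.any(y > hi):
            logger.warning(
                "calendar year(s) outside life-table coverage %s-%s; "
                "clamping to nearest covered year",
                lo,
                hi,
            )
        return np.clip(y, lo, hi)

    # -- lookups -------------------------------------------------------

    def lookup_q(self, sex, race, year, age) -> float:
        """Annual death probability for one person-moment."""
        yi = int(self.clamp_year(int(year))) - self.year_range[0]
        q = self._q_grid[
            self.sex_index(sex), self.race_index(race), yi, self.band_index(age)
        ]
        if np.isnan(q):
            raise LifeTableError(
                f"missing cell for ({sex}, {race}, {year}, age {age})"
            )
        return float(q)

    def lookup_hazard(self, sex, race, year, age) -> float:
        """Expected hazard (per person-year) for one person-moment."""
        return hazard_from_annual_prob(
            self.lookup_q(sex, race, year, age),
            cell=f"({sex}, {race}, {year}, age {age})",
        )

    def hazard_grid(self) -> np.ndarray:
        """Dense ``lambda*[sex, race, year, band]`` array (vectorised path)."""
        return -np.log1p(-self._q_grid)


def lookup_expected_hazard(table: LifeTable, sex, race, year, age) -> float:
    """Functional alias for :meth:`LifeTable.lookup_hazard`."""
    return table.lookup_hazard(sex, race, year, age)


def read_lifetable(path, provenance: str | None = None) -> LifeTable:
    """Read a life-table CSV (``sex,race,year,age_lo,age_hi,annual_q``).

    Lines starting with ``#`` are ignored.  All :class:`LifeTable` invariants
    are validated on load; violations raise :class:`LifeTableError` naming the
    offending rows.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(LifeTable._COLUMNS) - set(df.columns)
    if missing:
        raise LifeTableError(f"life-table CSV missing columns {sorted(missing)}")
    return LifeTable(df, provenance=provenance or str(path))


def write_lifetable(table: LifeTable, path) -> None:
    """Write a life table to CSV in the canonical column order."""
    table.cells[LifeTable._COLUMNS].to_csv(path, index=False)
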