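"""Crude excess and absolute mortality rates per 100 person-years.

Descriptive companions to the regression model: within each stratum
(sex x current-age category, optionally x organ),

* absolute rate  = O * 100 / PY
* excess rate    = (O - E) * 100 / PY

where O are observed deaths, E the expected deaths from the matched general
population (person-year-weighted sum of expected hazards) and PY the
person-years observed in the stratum.  95% CIs use a normal approximation
with variance from the observed deaths only (``Var(O - E) ~ O``, E treated
as fixed) — the standard descriptive relative-survival choice; the exact CI
construction is recorded in the output metadata.  Excess rates may be
negative (mortality below the general population) and are reported as-is.

Crude rates compare strata without accounting for time since waitlisting;
the regression model in :mod:`exhazard.excess_model` does.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .persontime import expected_deaths

__all__ = [
    "crude_excess_rate",
    "absolute_rate",
    "rate_table",
    "mortality_by_year",
    "RATE_CI_METHOD",
]

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054

RATE_CI_METHOD = (
    "normal approximation, Var(O-E) ~ O with E fixed; "
    "absolute-rate CI floored at 0"
)


def crude_excess_rate(O, E, PY):
    """Crude excess mortality rate (O - E) * 100 / PY with a 95% CI.

    The CI is ``((O - E) +/- 1.96 sqrt(O)) * 100 / PY``; it and the point
    estimate may be negative.
    """
    O, E, PY = float(O), float(E), float(PY)
    if PY <= 0:
        raise ValueError("person-years must be positive")
    if O < 0 or E < 0:
        raise ValueError("death counts must be non-negative")
    rate = (O - E) * 100.0 / PY
    half = Z95 * np.sqrt(O) * 100.0 / PY
    return rate, rate - half, rate + half


def absolute_rate(O, PY):
    """Absolute mortality rate O * 100 / PY with a Poisson-normal 95% CI.

    CI is ``(O +/- 1.96 sqrt(O)) * 100 / PY``, floored at 0.
    """
    O, PY = float(O), float(PY)
    if PY <= 0:
        raise ValueError("person-years must be positive")
    if O < 0:
        raise ValueError("death count must be non-negative")
    rate = O * 100.0 / PY
    half = Z95 * np.sqrt(O) * 100.0 / PY
    return rate, max(rate - half, 0.0), rate + half


def rate_table(intervals: pd.DataFrame, by=("sex", "age_category")
               ) -> pd.DataFrame:
    """Crude absolute and excess rates per stratum of the person-time table.

    One row per stratum (default sex x age category; add ``"organ"`` for
    multi-organ tables).  Strata with no person-time are omitted with a
    warning.  Note: crude rates do not take time since waitlisting into
    account.
    """
    logger.info(
        "crude rates compare strata without accounting for time since "
        "waitlisting; CI method: %s", RATE_CI_METHOD,
    )
    agg = expected_deaths(intervals, by=list(by))
    empty = agg["PY"] <= 0
    if empty.any():
        logger.warning("omitting %d empty strata", int(empty.sum()))
        agg = agg[~empty]
    rows = []
    for _, r in agg.iterrows():
        abs_rate, abs_lo, abs_hi = absolute_rate(r.O, r.PY)
        exc_rate, exc_lo, exc_hi = crude_excess_rate(r.O, r.E, r.PY)
        rows.append(
            {
                **{k: r[k] for k in by},
                "O": int(r.O),
                "E": float(r.E),
                "PY": float(r.PY),
                "absolute_rate": abs_rate,
                "abs_ci_lo": abs_lo,
                "abs_ci_hi": abs_hi,
                "excess_rate": exc_rate,
                "exc_ci_lo": exc_lo,
                "exc_ci_hi": exc_hi,
            }
        )
    return pd.DataFrame(rows)


def mortality_by_year(
    cohort: pd.DataFrame, horizon: float = 2.0
) -> pd.DataFrame:
    """Deaths per 100 PY by sex and listing year within a follow-up horizon.

    Used to localise when a sex difference in early waitlist mortality
    changes over calendar time.  Follow-up is truncated at ``horizon`` years
    after listing; deaths beyond the horizon count as censored.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    fu_days = np.array(
        [(o - l).days for o, l in zip(cohort["outcome_date"],
                                      cohort["listing_date"])],
        dtype=float,
    )
    fu = np.maximum(fu_days / 365.25, 0.5 / 365.25)
    clipped = np.minimum(fu, horizon)
    died = (cohort["outcome_type"].to_numpy() == "death") & (fu <= horizon)
    years = np.array([l.year for l in cohort["listing_date"]])
    df = pd.DataFrame(
        {"sex": cohort["sex"].to_numpy(), "listing_year": years,
         "py": clipped, "death": died.astype(int)}
    )
    out = (
        df.groupby(["listing_year", "sex"])
        .agg(O=("death", "sum"), PY=("py", "sum"))
        .reset_index()
    )
    rates = [absolute_rate(o, py) for o, py in zip(out.O, out.PY)]
    out[["rate_per_100py", "ci_lo", "ci_hi"]] = pd.DataFrame(
        rates, index=out.index
    )
    return out
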