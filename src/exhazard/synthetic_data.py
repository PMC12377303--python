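"""Synthetic waitlist cohorts with known ground truth.

Real transplant-registry data sit behind data-use agreements, so every test
of the analysis pipeline runs on simulated cohorts that have exactly the
statistical structure the relative-survival model assumes:

* staggered listing dates over an enrollment window;
* a death hazard equal to the matched general-population (expected) hazard
  plus a multiplicative excess ``mu(t) = exp(alpha_b(t)) * RER_agecat(t)``
  for females (with optional per-era scaling of the female multiplier);
* independent exponential censoring at transplant;
* administrative censoring at the study end.

Death times are drawn exactly from the resulting piecewise-constant total
hazard: one Exp(1) deviate per candidate is inverted through the piecewise-
linear cumulative hazard (equivalent to drawing segment-wise exponentials
and carrying unused cumulative hazard forward).  Identical seeds give
bit-identical cohorts.

Every draw's ground truth (latent death and transplant times, per-segment
true hazards) is exposed for parameter-recovery and calibration tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .lifetables import LifeTable, LifeTableError, standard_band_edges
from .persontime import (
    AGE_CATEGORY_LABELS,
    DAYS_PER_YEAR,
    DEFAULT_ERA_PARTITION,
    DEFAULT_FOLLOWUP_BANDS,
    assign_era,
    expand_cohort,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "make_toy_lifetable",
    "simulate_cohort",
    "validate_simulation",
    "write_truth",
    "KIDNEY_DISEASES",
    "HEART_DISEASES",
    "LIVER_DISEASES",
]

logger = logging.getLogger(__name__)

KIDNEY_DISEASES = {
    "diabetes": 0.33,
    "hypertension": 0.22,
    "glomerulonephritis": 0.19,
    "CAKUT": 0.02,
    "cystic": 0.08,
    "other": 0.16,
}
HEART_DISEASES = {
    "congenital": 0.10,
    "coronary_ischemic": 0.32,
    "myocarditis_cardiomyopathy": 0.44,
    "other": 0.14,
}
LIVER_DISEASES = {
    "biliary_atresia": 0.03,
    "alcohol_related": 0.18,
    "cancer": 0.08,
    "metabolic": 0.03,
    "fulminant_failure": 0.06,
    "autoimmune": 0.10,
    "hepatitis_c": 0.29,
    "other": 0.23,
}
_ORGAN_DISEASES = {
    "kidney": KIDNEY_DISEASES,
    "heart": HEART_DISEASES,
    "liver": LIVER_DISEASES,
}

#: Age-at-listing mixture (lo, hi, weight): mostly middle-aged adults, a
#: small paediatric tail — the qualitative shape of a kidney waitlist.
DEFAULT_AGE_WEIGHTS = (
    (0.5, 13.0, 0.02),
    (13.0, 25.0, 0.04),
    (25.0, 45.0, 0.22),
    (45.0, 60.0, 0.42),
    (60.0, 75.0, 0.30),
)

DEFAULT_RACE_WEIGHTS = {"White": 0.63, "Black": 0.29, "other": 0.08}

#: Baseline excess death rates (per person-year) on the default follow-up
#: bands 0-1, 1-2, 2-3, 3-5, 5-10, 10+ y: highest shortly after listing.
DEFAULT_EXCESS_RATES = (0.065, 0.055, 0.05, 0.045, 0.04, 0.035)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults are the package's study conditions.

    ``true_rer`` maps age-category labels to the female:male excess-hazard
    multiplier (1.0 = no sex difference); ``era_multipliers`` optionally
    scales the *female* multiplier per listing era.  Setting
    ``transplant_rate_female_factor != 1`` makes transplant censoring
    informative — a clearly labelled stress test, not a default condition.
    """

    n_candidates: int
    seed: int
    enrollment_start: date = date(1988, 1, 1)
    enrollment_end: date = date(2019, 12, 31)
    study_end: date = date(2019, 12, 31)
    age_weights: tuple = DEFAULT_AGE_WEIGHTS
    sex_ratio: float = 0.39  # probability female
    race_weights: dict = field(default_factory=lambda: dict(DEFAULT_RACE_WEIGHTS))
    organ: str = "kidney"
    disease_weights: dict | None = None
    followup_bands: tuple = DEFAULT_FOLLOWUP_BANDS
    excess_rates: tuple = DEFAULT_EXCESS_RATES
    true_rer: dict = field(
        default_factory=lambda: {c: 1.0 for c in AGE_CATEGORY_LABELS}
    )
    era_partition: tuple = DEFAULT_ERA_PARTITION
    era_multipliers: dict | None = None
    transplant_rate: float = 0.25  # per person-year
    transplant_rate_female_factor: float = 1.0

    def __post_init__(self):
        if self.n_candidates < 0:
            raise ValueError("n_candidates must be non-negative")
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be a probability")
        if self.study_end < self.enrollment_end:
            raise ValueError("study_end must not precede enrollment_end")
        if not self.age_weights:
            raise ValueError("age distribution must be non-empty")
        w = np.array([g[2] for g in self.age_weights], dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("age weights must be non-negative and sum to 1")
        rw = np.array(list(self.race_weights.values()), dtype=float)
        if np.any(rw < 0) or not np.isclose(rw.sum(), 1.0):
            raise ValueError("race weights must be non-negative and sum to 1")
        if len(self.excess_rates) != len(self.followup_bands):
            raise ValueError(
                "excess_rates must give one rate per follow-up band"
            )
        if any(r < 0 for r in self.excess_rates):
            raise ValueError("excess rates must be non-negative")
        if self.transplant_rate < 0:
            raise ValueError("transplant_rate must be non-negative")
        missing = set(AGE_CATEGORY_LABELS) - set(self.true_rer)
        if missing:
            raise ValueError(f"true_rer missing age categories {sorted(missing)}")

    @property
    def diseases(self) -> dict:
        dw = self.disease_weights or _ORGAN_DISEASES[self.organ]
        w = np.array(list(dw.values()), dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("disease weights must be non-negative and sum to 1")
        return dw


@dataclass
class SimulationResult:
    """Simulated cohort plus its ground truth."""

    cohort: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def summary(self) -> dict:
        ot = self.cohort["outcome_type"]
        return {
            "n": len(self.cohort),
            "deaths": int((ot == "death").sum()),
            "transplants": int((ot == "transplant").sum()),
            "administrative": int((ot == "administrative").sum()),
            "person_years": float(self.truth["outcome_time"].sum()),
        }


def make_toy_lifetable(
    year_range=(1988, 2019),
    base_rate: float = 1e-4,
    age_slope: float = 0.075,
    sex_gap: float = 0.45,
    max_age: int = 120,
) -> LifeTable:
    """Gompertz-like general-population life table on the standard bands.

    ``annual_q(age) = 1 - exp(-base_rate * exp(age_slope*age + sex_gap*male))``
    evaluated at each band's lower edge; all three race levels are populated
    identically.  ``sex_gap > 0`` gives males the higher mortality seen in
    real populations.
    """
    if base_rate <= 0:
        raise LifeTableError("base_rate must be positive")
    y0, y1 = int(year_range[0]), int(year_range[1])
    if y1 < y0:
        raise LifeTableError("empty year range")
    edges = standard_band_edges(max_age)
    rows = []
    for sex, gap in (("female", 0.0), ("male", sex_gap)):
        haz = base_rate * np.exp(age_slope * edges + gap)
        q = -np.expm1(-haz)
        if np.any(q >= 1) or not np.all(np.isfinite(q)):
            raise LifeTableError(
                "annual death probability reaches 1 at the oldest band; "
                "use a smaller age_slope or base_rate"
            )
        for race in ("White", "Black", "other"):
            for year in range(y0, y1 + 1):
                for i, lo in enumerate(edges):
                    hi = edges[i + 1] if i + 1 < len(edges) else max_age
                    rows.append((sex, race, year, int(lo), int(hi), q[i]))
    df = pd.DataFrame(
        rows, columns=["sex", "race", "year", "age_lo", "age_hi", "annual_q"]
    )
    return LifeTable(df, provenance="synthetic Gompertz toy table")


def _true_excess(shadow: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """True excess hazard per shadow person-time segment."""
    log_base = np.log(np.maximum(config.excess_rates, 1e-300))
    band_codes = shadow["followup_band"].cat.codes.to_numpy()
    mu = np.exp(log_base[band_codes])
    female = shadow["sex"].to_numpy() == "female"
    rer = np.array(
        [config.true_rer[c] for c in AGE_CATEGORY_LABELS], dtype=float
    )
    cat_codes = shadow["age_category"].cat.codes.to_numpy()
    mult = np.where(female, rer[cat_codes], 1.0)
    if config.era_multipliers:
        eras = shadow["era"].to_numpy()
        em = np.array(
            [config.era_multipliers.get(e, 1.0) for e in eras], dtype=float
        )
        mult = np.where(female, mult * em, mult)
    return mu * mult


def _shadow_segments(cohort: pd.DataFrame, config: SimulationConfig,
                     table: LifeTable) -> pd.DataFrame:
    shadow = cohort.copy()
    shadow["outcome_date"] = config.study_end
    shadow["outcome_type"] = "administrative"
    seg = expand_cohort(
        shadow, table, config.followup_bands, config.era_partition
    )
    seg["true_excess"] = _true_excess(seg, config)
    seg["true_hazard"] = seg["expected_hazard"] + seg["true_excess"]
    return seg


def simulate_cohort(
    config: SimulationConfig, table: LifeTable
) -> SimulationResult:
    """Draw a waitlist cohort under the additive expected-plus-excess model.

    Returns a :class:`SimulationResult` whose ``cohort`` is the candidate
    table the rest of the package consumes and whose ``truth`` records the
    latent death/transplant times (death times are ``inf`` when the latent
    death falls beyond administrative censoring, where the trajectory is
    undefined).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_candidates
    empty_cols = [
        "id", "sex", "race", "birth_date", "listing_date", "organ",
        "primary_disease", "outcome_date", "outcome_type",
    ]
    if n == 0:
        return SimulationResult(
            cohort=pd.DataFrame(columns=empty_cols),
            truth=pd.DataFrame(
                columns=["id", "death_time", "transplant_time", "admin_time",
                         "outcome_time", "outcome_type"]
            ),
            config=config,
        )

    # covariates (fixed draw order => bit-identical cohorts per seed)
    e_start = config.enrollment_start.toordinal()
    e_end = config.enrollment_end.toordinal()
    listing_ord = rng.integers(e_start, e_end + 1, size=n)
    groups = rng.choice(
        len(config.age_weights),
        size=n,
        p=[g[2] for g in config.age_weights],
    )
    lo = np.array([g[0] for g in config.age_weights])
    hi = np.array([g[1] for g in config.age_weights])
    age = lo[groups] + rng.random(n) * (hi[groups] - lo[groups])
    sex = np.where(rng.random(n) < config.sex_ratio, "female", "male")
    races = list(config.race_weights)
    race = rng.choice(races, size=n, p=list(config.race_weights.values()))
    diseases = config.diseases
    disease = rng.choice(
        list(diseases), size=n, p=list(diseases.values())
    )
    e_tx = rng.exponential(1.0, size=n)
    e_death = rng.exponential(1.0, size=n)

    birth_ord = listing_ord - np.maximum(
        np.round(age * DAYS_PER_YEAR).astype(int), 1
    )
    cohort = pd.DataFrame(
        {
            "id": [f"c{i:06d}" for i in range(n)],
            "sex": sex,
            "race": race,
            "birth_date": [date.fromordinal(int(o)) for o in birth_ord],
            "listing_date": [date.fromordinal(int(o)) for o in listing_ord],
            "organ": config.organ,
            "primary_disease": disease,
            "outcome_date": date(1900, 1, 1),  # placeholder
            "outcome_type": "administrative",
        }
    )

    seg = _shadow_segments(cohort, config, table)

    # invert the piecewise-linear cumulative hazard at one Exp(1) per person
    cand = pd.factorize(seg["candidate_id"])[0]  # 0..n-1, contiguous blocks
    inc = (seg["true_hazard"] * seg["duration"]).to_numpy()
    cum = np.cumsum(inc)
    starts = np.searchsorted(cand, np.arange(n), side="left")
    base = np.where(starts > 0, cum[starts - 1], 0.0)
    totals = cum[np.searchsorted(cand, np.arange(n), side="right") - 1] - base
    target = base + e_death
    idx = np.searchsorted(cum, target, side="left")
    has_death = e_death < totals
    idx = np.minimum(idx, len(cum) - 1)
    cum_before = cum[idx] - inc[idx]
    h = seg["true_hazard"].to_numpy()[idx]
    t_seg = seg["t_start"].to_numpy()[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        death_time = np.where(
            has_death, t_seg + (target - cum_before) / h, np.inf
        )

    rate = config.transplant_rate * np.where(
        sex == "female", config.transplant_rate_female_factor, 1.0
    )
    with np.errstate(divide="ignore"):
        tx_time = np.where(rate > 0, e_tx / rate, np.inf)
    admin_time = np.maximum(
        (config.study_end.toordinal() - listing_ord) / DAYS_PER_YEAR,
        0.5 / DAYS_PER_YEAR,
    )

    outcome_time = np.minimum(np.minimum(death_time, tx_time), admin_time)
    otype = np.where(
        death_time <= outcome_time,
        "death",
        np.where(tx_time <= outcome_time, "transplant", "administrative"),
    )
    out_days = np.clip(
        np.round(outcome_time * DAYS_PER_YEAR).astype(int),
        0,
        (config.study_end.toordinal() - listing_ord),
    )
    cohort["outcome_date"] = [
        date.fromordinal(int(o)) for o in listing_ord + out_days
    ]
    cohort["outcome_type"] = otype

    truth = pd.DataFrame(
        {
            "id": cohort["id"],
            "sex": sex,
            "race": race,
            "age_at_listing": age,
            "listing_year": [date.fromordinal(int(o)).year for o in listing_ord],
            "death_time": death_time,
            "transplant_time": tx_time,
            "admin_time": admin_time,
            "outcome_time": outcome_time,
            "outcome_type": otype,
        }
    )
    logger.info("simulated cohort: %s", SimulationResult(cohort, truth, config).summary())
    return SimulationResult(cohort=cohort, truth=truth, config=config)


def validate_simulation(result: SimulationResult, table: LifeTable,
                        z_flag: float = 4.0) -> pd.DataFrame:
    """Check realized death counts against the configured hazards.

    Re-derives each candidate's true piecewise-constant hazard, clips
    exposure at the realized outcome, and compares observed deaths O with
    expected deaths ``E = sum(h * exposed time)`` per follow-up band via
    ``z = (O - E)/sqrt(E)``.  Rows with ``|z| > z_flag`` are flagged.
    """
    if len(result.cohort) == 0:
        return pd.DataFrame(
            columns=["followup_band", "O", "E", "PY", "z", "flag"]
        )
    seg = _shadow_segments(result.cohort, result.config, table)
    cand = pd.factorize(seg["candidate_id"])[0]
    t_out = result.truth["outcome_time"].to_numpy()[cand]
    exposed = np.clip(
        t_out - seg["t_start"].to_numpy(), 0.0, seg["duration"].to_numpy()
    )
    died_here = (
        (result.truth["outcome_type"].to_numpy()[cand] == "death")
        & (t_out > seg["t_start"].to_numpy())
        & (t_out <= seg["t_stop"].to_numpy())
    )
    work = pd.DataFrame(
        {
            "followup_band": seg["followup_band"],
            "O": died_here.astype(int),
            "E": seg["true_hazard"].to_numpy() * exposed,
            "PY": exposed,
        }
    )
    out = (
        work.groupby("followup_band", observed=True)
        .agg(O=("O", "sum"), E=("E", "sum"), PY=("PY", "sum"))
        .reset_index()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["z"] = (out["O"] - out["E"]) / np.sqrt(out["E"])
    out.loc[out["E"] == 0, "z"] = 0.0
    out["flag"] = out["z"].abs() > z_flag
    if out["flag"].any():
        logger.warning(
            "simulation diagnostics flagged bands:\n%s", out[out["flag"]]
        )
    return out


def write_truth(result: SimulationResult, path) -> None:
    """Write the ground-truth record (config + per-candidate latents) as JSON."""
    cfg = asdict(result.config)
    for k, v in cfg.items():
        if isinstance(v, date):
            cfg[k] = v.isoformat()
    payload = {
        "config": cfg,
        "summary": result.summary(),
        "candidates": result.truth.replace({np.inf: None}).to_dict("records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
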