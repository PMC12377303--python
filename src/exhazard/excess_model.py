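"""Additive excess-hazard (relative survival) regression.

The observed death hazard of a waitlisted candidate is modelled as the sum
of the expected hazard ``lambda*`` of the demographically matched general
population and an excess hazard attributable to organ failure / waitlisting:

    h_j = lambda*_j + mu_j,      mu_j = exp(alpha_b(j) + x_j' beta)

on person-time intervals ``j`` with constant hazards (see
:mod:`exhazard.persontime`).  ``alpha`` is a piecewise-constant baseline
excess log-hazard on follow-up bands; ``beta`` acts multiplicatively on the
excess hazard only.  With durations ``t_j`` and death indicators ``d_j`` the
log likelihood is

    l = sum_j d_j log(lambda*_j + mu_j) - (lambda*_j + mu_j) t_j ,

maximised here by Newton-Raphson on the analytic score with step-halving
(full-likelihood Esteve-type estimation).  Exponentiated contrasts of
``beta`` are relative excess risks (RER), reported with Wald 95% CIs on the
log scale; ``RER > 1`` for the female contrast means higher female excess
mortality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .persontime import (
    AGE_CATEGORY_LABELS,
    DEFAULT_ERA_PARTITION,
    DEFAULT_FOLLOWUP_BANDS,
    assign_era,
)

__all__ = [
    "ModelSpec",
    "FittedModel",
    "RerEstimate",
    "ModelError",
    "NotEstimableError",
    "neg_log_likelihood",
    "fit_excess_model",
    "rer_contrast",
    "lr_test",
    "era_stratified_rer",
    "rer_table",
]

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    """Invalid model specification or data/spec mismatch."""


class NotEstimableError(ModelError):
    """A requested contrast involves an aliased or absent coefficient."""


_DEFAULT_REFS = {"sex": "male", "race": "White", "age_category": "25-44"}


@dataclass(frozen=True)
class ModelSpec:
    """Design of an excess-hazard model.

    Parameters
    ----------
    followup_bands : tuple of float
        Edges (years since listing) of the piecewise-constant baseline
        excess log-hazard; last band open-ended.
    covariates : tuple of str
        Categorical main effects; column names of the person-time table.
        ``"era"`` is derived from the listing year via ``era_partition``.
    interactions : tuple of (str, str)
        Pairs of covariates whose non-reference dummy products enter the
        design.  ``("sex", "age_category")`` is required whenever RERs by
        age are requested and is present by default.
    references : mapping
        Reference level per term.  Defaults: male, White, age 25-44; for
        other terms the most frequent level in the data (earliest era for
        ``era``).
    era_partition : tuple of (lo, hi)
        Waitlisting-era partition (era of listing year, fixed per candidate).
    """

    followup_bands: tuple = DEFAULT_FOLLOWUP_BANDS
    covariates: tuple = ("sex", "age_category", "race", "primary_disease", "era")
    interactions: tuple = (("sex", "age_category"),)
    references: dict = field(default_factory=dict)
    era_partition: tuple = DEFAULT_ERA_PARTITION

    def with_sex_era_interaction(self) -> "ModelSpec":
        inter = tuple(self.interactions)
        if ("sex", "era") not in inter:
            inter = inter + (("sex", "era"),)
        return replace(self, interactions=inter)

    def without_era(self) -> "ModelSpec":
        """Spec for a single-era subset (era terms would be aliased)."""
        return replace(
            self,
            covariates=tuple(c for c in self.covariates if c != "era"),
            interactions=tuple(
                (a, b) for a, b in self.interactions if "era" not in (a, b)
            ),
        )


def _reference_level(term: str, levels: list, spec: ModelSpec):
    if term in spec.references:
        ref = spec.references[term]
        if ref not in levels:
            raise ModelError(
                f"reference level {ref!r} for {term!r} not present in data "
                f"(levels: {levels})"
            )
        return ref
    if term in _DEFAULT_REFS and _DEFAULT_REFS[term] in levels:
        return _DEFAULT_REFS[term]
    return levels[0]


def _term_levels(term: str, values: pd.Series):
    levels = [str(v) for v in pd.unique(values)]
    if term == "age_category":
        return [l for l in AGE_CATEGORY_LABELS if l in levels]
    if term == "era":
        return sorted(levels, key=lambda s: int(s.split("-")[0]))
    return sorted(levels)


class _Design:
    """Design matrix (baseline-band indicators + covariate contrasts)."""

    def __init__(self, intervals: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        n = len(intervals)
        edges = np.asarray(sorted(set(spec.followup_bands)), dtype=float)
        if edges[0] != 0:
            raise ModelError("followup_bands must start at 0")
        idx = np.searchsorted(edges, intervals["t_start"].to_numpy(), "right") - 1
        stop_band = (
            np.searchsorted(edges, intervals["t_stop"].to_numpy() - 1e-9, "right")
            - 1
        )
        if np.any(stop_band != idx):
            raise ModelError(
                "person-time intervals straddle followup_bands edges; re-expand "
                "the cohort with bands at least as fine as the model's"
            )
        present = np.unique(idx)
        self.band_labels = [_band_label(edges, b) for b in present]
        band_cols = np.zeros((n, len(present)))
        band_cols[np.arange(n), np.searchsorted(present, idx)] = 1.0

        work = intervals
        if "era" in spec.covariates or any(
            "era" in pair for pair in spec.interactions
        ):
            work = intervals.assign(
                era=assign_era(intervals["listing_year"], spec.era_partition)
            )

        cols = []
        names = []
        self.dummies = {}  # (term, level) -> column vector
        for term in spec.covariates:
            if term not in work.columns:
                raise ModelError(f"covariate {term!r} not in person-time table")
            vals = work[term].astype(str)
            levels = _term_levels(term, vals)
            ref = _reference_level(term, levels, spec)
            for lev in levels:
                v = (vals == lev).to_numpy(dtype=float)
                self.dummies[(term, lev)] = v
                if lev != ref:
                    cols.append(v)
                    names.append(f"{term}[{lev}]")
        for a, b in spec.interactions:
            for term in (a, b):
                if not any(k[0] == term for k in self.dummies):
                    raise ModelError(
                        f"interaction term {term!r} is not among covariates"
                    )
            for (ta, la), va in list(self.dummies.items()):
                if ta != a or f"{a}[{la}]" not in names:
                    continue
                for (tb, lb), vb in list(self.dummies.items()):
                    if tb != b or f"{b}[{lb}]" not in names:
                        continue
                    prod = va * vb
                    cols.append(prod)
                    names.append(f"{a}[{la}]:{b}[{lb}]")

        X = np.column_stack(cols) if cols else np.empty((n, 0))
        self.aliased = []
        keep = []
        for j, nm in enumerate(names):
            if X[:, j].sum() == 0:
                self.aliased.append(nm)
            else:
                keep.append(j)
        if self.aliased:
            warnings.warn(
                f"dropping aliased (empty) design columns: {self.aliased}",
                stacklevel=3,
            )
        self.Z = np.column_stack([band_cols, X[:, keep]])
        self.names = [f"base{b}" for b in self.band_labels] + [
            names[j] for j in keep
        ]
        self.n_base = len(self.band_labels)


def _band_label(edges: np.ndarray, b: int) -> str:
    if b == len(edges) - 1:
        return f"[{edges[b]:g},inf)"
    return f"[{edges[b]:g},{edges[b + 1]:g})"


def _nll_core(theta, Z, d, t, lam, derivs=True):
    eta = Z @ theta
    with np.errstate(over="ignore"):
        mu = np.exp(eta)
    h = lam + mu
    if not np.all(np.isfinite(mu)) or np.any(h <= 0):
        return np.inf, None, None
    with np.errstate(divide="ignore"):
        ll = float(np.sum(d * np.log(h)) - np.sum(h * t))
    if not np.isfinite(ll):
        return np.inf, None, None
    if not derivs:
        return -ll, None, None
    # score and observed information of -l
    w1 = d * mu / h - mu * t
    grad = -(Z.T @ w1)
    w2 = mu * t - d * mu * lam / (h * h)
    hess = (Z.T * w2) @ Z
    return -ll, grad, hess


def neg_log_likelihood(params, data: pd.DataFrame, spec: ModelSpec,
                       derivs: bool = False):
    """Negative log likelihood (optionally with gradient and Hessian).

    ``params`` is the stacked vector (baseline band log-hazards first, then
    covariate coefficients in design order).  Mostly useful for testing and
    for external optimisers; :func:`fit_excess_model` uses the same core.
    """
    des = _Design(data, spec)
    theta = np.asarray(params, dtype=float)
    if theta.shape != (len(des.names),):
        raise ModelError(
            f"expected {len(des.names)} parameters ({des.names}), "
            f"got {theta.shape}"
        )
    out = _nll_core(
        theta,
        des.Z,
        data["death"].to_numpy(dtype=float),
        data["duration"].to_numpy(dtype=float),
        data["expected_hazard"].to_numpy(dtype=float),
        derivs=derivs,
    )
    return out if derivs else out[0]


@dataclass
class FittedModel:
    """A maximised excess-hazard model."""

    params: pd.Series  # stacked (alpha, beta)
    covariance: pd.DataFrame
    loglik: float
    n_intervals: int
    n_deaths: int
    converged: bool
    n_iter: int
    spec: ModelSpec
    n_base: int
    aliased: list

    @property
    def alpha(self) -> pd.Series:
        """Baseline excess log-hazard per follow-up band."""
        return self.params.iloc[: self.n_base]

    @property
    def beta(self) -> pd.Series:
        """Covariate coefficients (log excess-hazard ratios)."""
        return self.params.iloc[self.n_base:]

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.clip(np.diag(self.covariance.to_numpy()), 0, None))
        return pd.DataFrame(
            {"coef": self.params, "se": se,
             "exp_coef": np.exp(self.params.to_numpy())}
        )


@dataclass(frozen=True)
class RerEstimate:
    """Relative excess risk, female vs male, with a 95% Wald CI."""

    label: str
    rer: float
    ci_lo: float
    ci_hi: float
    se_log: float


def fit_excess_model(
    data: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    max_iter: int = 100,
    tol_loglik: float = 1e-8,
    tol_score: float = 1e-6,
) -> FittedModel:
    """Maximise the excess-hazard likelihood by Newton-Raphson.

    Deterministic given the data (no randomness).  Convergence requires both
    ``|delta loglik| < tol_loglik`` and ``max |score| < tol_score``; up to 50
    step-halvings per iteration guard against overshooting, with a gradient-
    ascent fallback step when the information matrix is not positive
    definite.  The covariance is the inverse observed information at the
    optimum (pseudo-inverse, with a warning, when the information is
    ill-conditioned).

    Raises
    ------
    ModelError
        If there are no intervals or no deaths (the excess scale is then
        unidentifiable).
    """
    if len(data) == 0:
        raise ModelError("no person-time intervals")
    d = data["death"].to_numpy(dtype=float)
    t = data["duration"].to_numpy(dtype=float)
    lam = data["expected_hazard"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ModelError("all interval durations must be positive")
    if d.sum() < 1:
        raise ModelError("at least one death is required to fit the model")

    des = _Design(data, spec)
    Z = des.Z
    p = Z.shape[1]

    # moment start: overall excess rate on every band, zero coefficients
    crude = max(d.sum() - float(lam @ t), 0.1 * d.sum()) / t.sum()
    theta = np.zeros(p)
    theta[: des.n_base] = np.log(max(crude, 1e-8))

    nll, grad, hess = _nll_core(theta, Z, d, t, lam)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = linalg.solve(hess, -grad, assume_a="sym")
        except linalg.LinAlgError:
            step = -grad  # gradient ascent fallback on -l
        if not np.all(np.isfinite(step)) or (grad @ step) > 0:
            step = -grad
        new_nll = np.inf
        scale = 1.0
        for _ in range(50):
            cand = theta + scale * step
            new_nll, new_grad, new_hess = _nll_core(cand, Z, d, t, lam)
            if new_nll < nll + 1e-12:
                break
            scale *= 0.5
        if not np.isfinite(new_nll) or new_nll >= nll + 1e-12:
            break  # no improving step
        delta = nll - new_nll
        theta, nll, grad, hess = cand, new_nll, new_grad, new_hess
        if delta < tol_loglik and np.max(np.abs(grad)) < tol_score:
            converged = True
            break
    if not converged and np.max(np.abs(grad)) < tol_score:
        converged = True
    if not converged:
        logger.warning(
            "excess model did not converge in %d iterations "
            "(|score|_max=%.3g, delta loglik=%.3g)",
            it, float(np.max(np.abs(grad))), float("nan"),
        )

    cond = np.linalg.cond(hess)
    if cond > 1e10:
        warnings.warn(
            f"observed information ill-conditioned (cond={cond:.3g}); "
            "using pseudo-inverse covariance",
            stacklevel=2,
        )
        cov = linalg.pinvh(hess)
    else:
        cov = linalg.inv(hess)
    cov = (cov + cov.T) / 2.0

    names = des.names
    return FittedModel(
        params=pd.Series(theta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        loglik=-nll,
        n_intervals=len(data),
        n_deaths=int(d.sum()),
        converged=converged,
        n_iter=it,
        spec=spec,
        n_base=des.n_base,
        aliased=des.aliased,
    )


def rer_contrast(
    fit: FittedModel,
    age_category: str | None = None,
    era: str | None = None,
    z: float = 1.959963984540054,
) -> RerEstimate:
    """Female-vs-male relative excess risk for one age category (and era).

    Builds the contrast ``c`` selecting the female main effect plus the
    relevant interaction terms and returns ``RER = exp(c'theta)`` with the
    Wald CI ``exp(c'theta +/- z sqrt(c'Sigma c))``.  ``RER > 1`` means higher
    female excess mortality.
    """
    names = list(fit.params.index)
    c = pd.Series(0.0, index=names)
    main = "sex[female]"
    if main in fit.aliased or main not in names:
        raise NotEstimableError(
            "female-vs-male contrast not estimable: no 'sex[female]' term "
            "(single-sex data or sex not in the model)"
        )
    c[main] = 1.0

    def _add_interaction(term: str, level: str):
        col = f"sex[female]:{term}[{level}]"
        ref = _fitted_reference(fit, term)
        if level == ref:
            return
        if col in names:
            c[col] = 1.0
        elif col in fit.aliased or _has_interaction(fit.spec, term):
            raise NotEstimableError(
                f"contrast for {term}={level!r} not estimable "
                f"(term {col!r} aliased or absent)"
            )

    if age_category is not None:
        if str(age_category) not in AGE_CATEGORY_LABELS:
            raise ModelError(
                f"unknown age category {age_category!r}; "
                f"expected one of {AGE_CATEGORY_LABELS}"
            )
        _add_interaction("age_category", str(age_category))
    if era is not None:
        _add_interaction("era", str(era))

    est = float(c @ fit.params)
    var = float(c @ fit.covariance.to_numpy() @ c)
    se = np.sqrt(max(var, 0.0))
    label = str(age_category) if age_category is not None else "overall"
    if era is not None:
        label += f" / {era}"
    return RerEstimate(
        label=label,
        rer=float(np.exp(est)),
        ci_lo=float(np.exp(est - z * se)),
        ci_hi=float(np.exp(est + z * se)),
        se_log=float(se),
    )


def _has_interaction(spec: ModelSpec, term: str) -> bool:
    return ("sex", term) in spec.interactions or (term, "sex") in spec.interactions


def _fitted_reference(fit: FittedModel, term: str) -> str | None:
    if term in fit.spec.references:
        return fit.spec.references[term]
    # infer: the level with a main-effect column is non-reference
    if term in _DEFAULT_REFS:
        return _DEFAULT_REFS[term]
    return None


def lr_test(fit_full: FittedModel, fit_reduced: FittedModel):
    """Likelihood-ratio test of nested excess-hazard models.

    Returns ``(statistic, df, p)`` with ``statistic = 2 (l_full - l_reduced)``
    and a chi-square upper-tail p-value.  Models must be fitted to the same
    data and the reduced parameter set must be contained in the full one.
    """
    full = set(fit_full.params.index)
    red = set(fit_reduced.params.index)
    if not red <= full:
        raise ModelError(
            f"models are not nested: reduced has extra terms {sorted(red - full)}"
        )
    if fit_full.n_intervals != fit_reduced.n_intervals or (
        fit_full.n_deaths != fit_reduced.n_deaths
    ):
        raise ModelError("nested models must be fitted to the same data")
    stat = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    df = len(full) - len(red)
    if df == 0:
        return stat, 0, 1.0
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    return stat, df, p


def era_stratified_rer(
    data: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    era_partition=None,
) -> pd.DataFrame:
    """Per-era female-vs-male RERs by age category (one model per era).

    Each era's subset is fitted with era terms removed (they would be
    aliased within a stratum).  Era strata with no deaths are reported with
    ``estimable=False`` rather than dropped.
    """
    partition = era_partition or spec.era_partition
    eras = assign_era(data["listing_year"], partition)
    rows = []
    for lo, hi in partition:
        label = f"{lo}-{hi}"
        sub = data[eras == label]
        sub_spec = replace(spec, era_partition=partition).without_era()
        cats = [
            c for c in AGE_CATEGORY_LABELS
            if len(sub) and (sub["age_category"].astype(str) == c).any()
        ]
        if len(sub) == 0 or sub["death"].sum() < 1:
            rows.append(
                dict(era=label, age_category=None, rer=np.nan, ci_lo=np.nan,
                     ci_hi=np.nan, n_deaths=int(sub["death"].sum()) if len(sub)
                     else 0, estimable=False)
            )
            continue
        fit = fit_excess_model(sub, sub_spec)
        for cat in cats:
            n_deaths = int(
                sub.loc[sub["age_category"].astype(str) == cat, "death"].sum()
            )
            try:
                est = rer_contrast(fit, age_category=cat)
                rows.append(
                    dict(era=label, age_category=cat, rer=est.rer,
                         ci_lo=est.ci_lo, ci_hi=est.ci_hi,
                         n_deaths=n_deaths, estimable=True)
                )
            except NotEstimableError:
                rows.append(
                    dict(era=label, age_category=cat, rer=np.nan,
                         ci_lo=np.nan, ci_hi=np.nan,
                         n_deaths=n_deaths, estimable=False)
                )
    return pd.DataFrame(rows)


def rer_table(fit: FittedModel, data: pd.DataFrame, era: str | None = None
              ) -> pd.DataFrame:
    """Female-vs-male RERs for every age category present in ``data``."""
    rows = []
    for cat in AGE_CATEGORY_LABELS:
        mask = data["age_category"].astype(str) == cat
        if not mask.any():
            continue
        n_deaths = int(data.loc[mask, "death"].sum())
        try:
            est = rer_contrast(fit, age_category=cat, era=era)
            rows.append(
                dict(age_category=cat, era=era or "all", rer=est.rer,
                     ci_lo=est.ci_lo, ci_hi=est.ci_hi, n_deaths=n_deaths,
                     estimable=True)
            )
        except NotEstimableError:
            rows.append(
                dict(age_category=cat, era=era or "all", rer=np.nan,
                     ci_lo=np.nan, ci_hi=np.nan, n_deaths=n_deaths,
                     estimable=False)
            )
    return pd.DataFrame(rows)
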