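"""Logistic-regression triangulation and additive-scale interaction (RERI).

The data-driven combinations found by the tree ensemble are checked against
conventional epidemiological modelling: per-condition odds ratios, joint
exposure odds ratios from a two-condition interaction model, the relative
excess risk due to interaction

    RERI = OR11 - OR10 - OR01 + 1,

and within-stratum odds ratios (the association of each condition estimated
separately in the presence and absence of the other), assembled in a
Knol-VanderWeele-style presentation table. A positive RERI indicates a
super-additive (synergistic) joint effect; its significance is judged by a
95% CI excluding 0.

Confidence intervals for RERI use the Hosmer-Lemeshow delta method on the
odds-ratio scale by default; a nonparametric participant-resampling bootstrap
is available as an alternative. Odds ratios are used as risk-ratio
approximations inside RERI; with a common outcome this is an approximation,
which reports carry as a caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ensemble import CombinationRecord
from .registry import ConditionRegistry

logger = logging.getLogger(__name__)

_Z95 = stats.norm.ppf(0.975)


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows (quasi-)complete separation."""


@dataclass
class LogisticFit:
    """A fitted logistic model: coefficients, covariance and diagnostics."""

    params: pd.Series
    cov: pd.DataFrame
    terms: list[str]
    n: int
    converged: bool
    separation: bool

    def odds_ratio(self, term: str) -> tuple[float, tuple[float, float]]:
        """OR = exp(coefficient) with its Wald 95% CI."""
        b = self.params[term]
        se = float(np.sqrt(self.cov.loc[term, term]))
        with np.errstate(over="ignore"):  # separated fits: CI bound may be inf
            return float(np.exp(b)), (float(np.exp(b - _Z95 * se)),
                                      float(np.exp(b + _Z95 * se)))


@dataclass
class ReriEstimate:
    """Additive-interaction estimate with the odds ratios composing it."""

    or10: float
    or01: float
    or11: float
    reri: float
    ci: Optional[tuple[float, float]]
    method: str
    or10_ci: Optional[tuple[float, float]] = None
    or01_ci: Optional[tuple[float, float]] = None
    or11_ci: Optional[tuple[float, float]] = None
    stratum_ors: Optional[dict] = None

    @property
    def significant(self) -> Optional[bool]:
        if self.ci is None:
            return None
        return self.ci[0] > 0 or self.ci[1] < 0


def reri_point(or10: float, or01: float, or11: float) -> float:
    """RERI point estimate from three odds ratios: OR11 - OR10 - OR01 + 1."""
    return or11 - or10 - or01 + 1.0


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _design(
    cohort: pd.DataFrame,
    main_terms: Sequence[str],
    interaction: Optional[tuple[str, str]],
    adjust_age: bool,
) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(cohort))}, index=cohort.index)
    for t in main_terms:
        X[t] = cohort[t].to_numpy(dtype=float)
    if interaction is not None:
        a, b = interaction
        X[f"{a}:{b}"] = (cohort[a] * cohort[b]).to_numpy(dtype=float)
    if adjust_age:
        X["age_years"] = cohort["age_years"].to_numpy(dtype=float)
    return X


def fit_logistic(
    cohort: pd.DataFrame,
    terms: Sequence[str],
    adjust_age: bool = False,
    *,
    interaction: Optional[tuple[str, str]] = None,
    on_separation: str = "flag",
) -> LogisticFit:
    """Maximum-likelihood logistic fit of at-risk status on condition terms.

    IRLS via statsmodels GLM with a binomial family; deviance tolerance 1e-8,
    at most 100 iterations. (Quasi-)complete separation — fitted probabilities
    numerically at 0/1 with a diverging coefficient — is flagged (or raised
    with ``on_separation='raise'``) rather than silently reported.
    """
    y = cohort["at_risk"].astype(bool).to_numpy(dtype=float)
    X = _design(cohort, terms, interaction, adjust_age)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8, scale=1.0)
    if not res.converged:
        raise RuntimeError(
            f"logistic fit did not converge in 100 iterations (terms={list(terms)})"
        )
    mu = res.fittedvalues
    separation = bool(
        ((mu < 1e-8) | (mu > 1 - 1e-8)).any() and np.abs(res.params).max() > 15
    )
    if separation:
        msg = f"separation detected in logistic fit (terms={list(terms)})"
        if on_separation == "raise":
            raise SeparationError(msg)
        logger.warning(msg)
    return LogisticFit(
        params=res.params,
        cov=res.cov_params(),
        terms=[c for c in X.columns if c != "intercept"],
        n=len(y),
        converged=bool(res.converged),
        separation=separation,
    )


def joint_exposure_ors(
    cohort: pd.DataFrame,
    a: str,
    b: str,
    adjust_age: bool = False,
) -> tuple[LogisticFit, ReriEstimate]:
    """Joint-exposure odds ratios from logit(P) = b0 + b1 A + b2 B + b3 A·B.

    OR10 = exp(b1) (A only vs neither), OR01 = exp(b2), OR11 = exp(b1+b2+b3),
    each with Wald CIs (for OR11 via the variance of the coefficient sum).
    The returned :class:`ReriEstimate` carries the delta-method RERI CI.
    """
    if a == b:
        raise ValueError("the two conditions must differ")
    av = cohort[a].to_numpy(dtype=int)
    bv = cohort[b].to_numpy(dtype=int)
    for xa in (0, 1):
        for xb in (0, 1):
            if not np.any((av == xa) & (bv == xb)):
                raise ValueError(f"empty exposure cell (A={xa}, B={xb}) for ({a}, {b})")
    fit = fit_logistic(cohort, [a, b], adjust_age, interaction=(a, b))
    return fit, reri(fit, a, b)


def reri(fit: LogisticFit, a: str, b: str, method: str = "delta") -> ReriEstimate:
    """RERI (with CI) from a fitted two-condition interaction model.

    ``method='delta'`` propagates the coefficient covariance through
    RERI = exp(b1+b2+b3) - exp(b1) - exp(b2) + 1 (Hosmer-Lemeshow).
    """
    if method != "delta":
        raise ValueError("reri() computes the delta-method CI; "
                         "use reri_bootstrap() for the resampling CI")
    if fit.cov is None:
        raise ValueError("delta-method RERI needs the fit covariance")
    inter = f"{a}:{b}"
    terms = [a, b, inter]
    beta = fit.params[terms].to_numpy()
    V = fit.cov.loc[terms, terms].to_numpy()
    b1, b2, b3 = beta
    s = b1 + b2 + b3
    or10, or01, or11 = float(np.exp(b1)), float(np.exp(b2)), float(np.exp(s))
    point = reri_point(or10, or01, or11)
    grad = np.array([np.exp(s) - np.exp(b1), np.exp(s) - np.exp(b2), np.exp(s)])
    var = float(grad @ V @ grad)
    se = float(np.sqrt(var))
    ci = (point - _Z95 * se, point + _Z95 * se)

    def or_ci(c: np.ndarray) -> tuple[float, float]:
        v = float(c @ V @ c)
        est = float(c @ beta)
        h = _Z95 * np.sqrt(v)
        return (float(np.exp(est - h)), float(np.exp(est + h)))

    return ReriEstimate(
        or10=or10, or01=or01, or11=or11, reri=point, ci=ci, method="delta",
        or10_ci=or_ci(np.array([1.0, 0, 0])),
        or01_ci=or_ci(np.array([0, 1.0, 0])),
        or11_ci=or_ci(np.array([1.0, 1.0, 1.0])),
    )


def reri_bootstrap(
    cohort: pd.DataFrame,
    a: str,
    b: str,
    adjust_age: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
) -> ReriEstimate:
    """Nonparametric RERI CI: resample participants, refit, percentile interval."""
    fit = fit_logistic(cohort, [a, b], adjust_age, interaction=(a, b))
    base = reri(fit, a, b)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(cohort)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = cohort.iloc[idx]
        try:
            f = fit_logistic(sample, [a, b], adjust_age, interaction=(a, b))
            draws.append(reri(f, a, b).reri)
        except (ValueError, RuntimeError):
            continue  # degenerate resample (empty cell); skip
    if len(draws) < n_boot * 0.5:
        logger.warning("bootstrap RERI: only %d/%d usable resamples", len(draws), n_boot)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return ReriEstimate(
        or10=base.or10, or01=base.or01, or11=base.or11, reri=base.reri,
        ci=(float(lo), float(hi)), method="bootstrap",
        or10_ci=base.or10_ci, or01_ci=base.or01_ci, or11_ci=base.or11_ci,
    )


def stratified_ors(
    cohort: pd.DataFrame, a: str, b: str, adjust_age: bool = False
) -> dict:
    """Within-stratum associations: OR of each condition in the presence and
    absence of the other (an estimate of effect modification).

    A stratum with no exposure contrast or no outcome contrast yields a
    missing OR with the reason recorded.
    """
    if a == b:
        raise ValueError("the two conditions must differ")
    out: dict = {}
    for exposure, stratifier in ((a, b), (b, a)):
        for level in (0, 1):
            key = f"OR({exposure} | {stratifier}={level})"
            sub = cohort[cohort[stratifier] == level]
            if sub.empty:
                out[key] = {"or": None, "ci": None, "reason": "empty stratum"}
                continue
            xv = sub[exposure].astype(int)
            yv = sub["at_risk"].astype(bool)
            if xv.nunique() < 2:
                out[key] = {"or": None, "ci": None, "reason": "no exposure contrast"}
                continue
            if yv.nunique() < 2:
                out[key] = {"or": None, "ci": None, "reason": "no outcome contrast"}
                continue
            fit = fit_logistic(sub, [exposure], adjust_age)
            orr, ci = fit.odds_ratio(exposure)
            out[key] = {"or": orr, "ci": ci,
                        "reason": "separation" if fit.separation else None}
    return out


def knol_vanderweele_table(
    cohort: pd.DataFrame, a: str, b: str, adjust_age: bool = False
) -> pd.DataFrame:
    """Joint and stratified ORs with RERI in the recommended reporting layout."""
    _, est = joint_exposure_ors(cohort, a, b, adjust_age)
    strata = stratified_ors(cohort, a, b, adjust_age)
    av = cohort[a].astype(int).to_numpy()
    bv = cohort[b].astype(int).to_numpy()
    risk = cohort["at_risk"].astype(bool).to_numpy()
    rows = []
    cells = {(0, 0): (1.0, (1.0, 1.0)), (1, 0): (est.or10, est.or10_ci),
             (0, 1): (est.or01, est.or01_ci), (1, 1): (est.or11, est.or11_ci)}
    for (xa, xb), (orr, ci) in cells.items():
        mask = (av == xa) & (bv == xb)
        rows.append({
            "cell": f"{a}={xa}, {b}={xb}",
            "n": int(mask.sum()),
            "n_at_risk": int((mask & risk).sum()),
            "or": round(orr, 2),
            "ci_low": round(ci[0], 2),
            "ci_high": round(ci[1], 2),
        })
    for key, v in strata.items():
        rows.append({
            "cell": key,
            "n": None, "n_at_risk": None,
            "or": round(v["or"], 2) if v["or"] is not None else None,
            "ci_low": round(v["ci"][0], 2) if v["ci"] else None,
            "ci_high": round(v["ci"][1], 2) if v["ci"] else None,
        })
    rows.append({
        "cell": "RERI", "n": None, "n_at_risk": None,
        "or": round(est.reri, 2),
        "ci_low": round(est.ci[0], 2), "ci_high": round(est.ci[1], 2),
    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Triangulation of the ranked combinations
# ---------------------------------------------------------------------------

@dataclass
class TriangulationEntry:
    label: str
    conditions: tuple[str, ...]
    condition_ors: dict[str, dict]
    joint: Optional[ReriEstimate] = None  # pairs only
    joint_all_or: Optional[dict] = None   # 3+ conditions: OR of all-present
    error: Optional[str] = None


def triangulate(
    cohort: pd.DataFrame,
    records: Sequence[CombinationRecord],
    registry: ConditionRegistry,
    adjust_age: bool = False,
) -> list[TriangulationEntry]:
    """Regression check of each retained combination.

    Every combination gets per-condition odds ratios (each from its own
    logistic fit). Two-condition combinations additionally get the joint
    exposure ORs, RERI with CI and within-stratum ORs; combinations of three
    or more get the odds ratio of the all-conditions-present exposure (no
    RERI — the additive-interaction contrast is defined here for two
    specified conditions). Per-record failures are recorded, not raised, so
    the report always completes.
    """
    entries = []
    n_tests = 0
    for rec in records:
        conds = registry.sorted_conditions(rec.conditions)
        entry = TriangulationEntry(label=rec.label, conditions=conds, condition_ors={})
        try:
            for cid in conds:
                fit = fit_logistic(cohort, [cid], adjust_age)
                orr, ci = fit.odds_ratio(cid)
                entry.condition_ors[cid] = {"or": orr, "ci": ci,
                                            "separation": fit.separation}
                n_tests += 1
            if len(conds) == 2:
                _, est = joint_exposure_ors(cohort, conds[0], conds[1], adjust_age)
                est.stratum_ors = stratified_ors(cohort, conds[0], conds[1], adjust_age)
                entry.joint = est
                n_tests += 1
            elif len(conds) >= 3:
                tmp = cohort.copy()
                col = "__all_present"
                tmp[col] = (tmp[list(conds)].sum(axis=1) == len(conds)).astype(int)
                fit = fit_logistic(tmp, [col], adjust_age)
                orr, ci = fit.odds_ratio(col)
                entry.joint_all_or = {"or": orr, "ci": ci}
                n_tests += 1
        except (ValueError, RuntimeError) as exc:
            entry.error = str(exc)
        entries.append(entry)
    logger.info("triangulation performed %d regression tests "
                "(no multiplicity correction applied)", n_tests)
    return entries


def triangulation_to_frame(entries: Sequence[TriangulationEntry]) -> pd.DataFrame:
    """Long-format report: one row per combination x term."""
    rows = []
    for e in entries:
        for cid, v in e.condition_ors.items():
            rows.append({
                "label": e.label, "term": cid,
                "or": round(v["or"], 2),
                "ci_low": round(v["ci"][0], 2), "ci_high": round(v["ci"][1], 2),
                "reri": None, "reri_ci_low": None, "reri_ci_high": None,
            })
        if e.joint is not None:
            rows.append({
                "label": e.label, "term": "joint (both present)",
                "or": round(e.joint.or11, 2),
                "ci_low": round(e.joint.or11_ci[0], 2),
                "ci_high": round(e.joint.or11_ci[1], 2),
                "reri": round(e.joint.reri, 2),
                "reri_ci_low": round(e.joint.ci[0], 2),
                "reri_ci_high": round(e.joint.ci[1], 2),
            })
        if e.joint_all_or is not None:
            rows.append({
                "label": e.label, "term": "joint (all present)",
                "or": round(e.joint_all_or["or"], 2),
                "ci_low": round(e.joint_all_or["ci"][0], 2),
                "ci_high": round(e.joint_all_or["ci"][1], 2),
                "reri": None, "reri_ci_low": None, "reri_ci_high": None,
            })
        if e.error:
            rows.append({"label": e.label, "term": f"ERROR: {e.error}",
                         "or": None, "ci_low": None, "ci_high": None,
                         "reri": None, "reri_ci_low": None, "reri_ci_high": None})
    return pd.DataFrame(rows)
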