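"""Analytic cohort table: sarcopenia-risk classification, multimorbidity
restriction, descriptive statistics and the cohort CSV dialect.

A cohort is a pandas DataFrame with one row per participant and columns::

    participant_id, sex ('F'/'M'), age_years, grip_max_kg (nullable),
    unable_health (bool), <one 0/1 column per registry condition_id>,
    n_ltc (derived), at_risk (derived, nullable boolean)

"At risk of sarcopenia" means maximum grip strength strictly below a
sex-specific cutoff; participants unable to perform the grip test for health
reasons are also classified at risk. Participants with missing grip strength
who were able to attempt the test cannot be classified and are excluded when
the sample is restricted to classifiable multimorbid (>=2 LTC) participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Union
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .registry import ConditionRegistry

META_COLUMNS = ["participant_id", "sex", "age_years", "grip_max_kg", "unable_health"]
SEXES = ("F", "M")


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the expected schema."""


@dataclass(frozen=True)
class ClassificationConfig:
    """Sex-specific grip-strength cutoffs (kg) defining 'at risk of sarcopenia'.

    Comparison is strict: a value exactly at the threshold is *not* at risk.
    ``unable_counts_as_at_risk`` places participants who could not attempt the
    grip test for health reasons in the at-risk class.
    """

    male_threshold_kg: float = 32.0
    female_threshold_kg: float = 19.0
    unable_counts_as_at_risk: bool = True

    def __post_init__(self) -> None:
        if self.male_threshold_kg <= 0 or self.female_threshold_kg <= 0:
            raise ValueError("grip thresholds must be strictly positive")

    def threshold_for(self, sex: str) -> float:
        return self.male_threshold_kg if sex == "M" else self.female_threshold_kg


#: Main-analysis cutoffs: 2 SD below young-adult reference means.
MAIN_THRESHOLDS = ClassificationConfig(32.0, 19.0)
#: EWGSOP2 probable-sarcopenia cutoffs (sensitivity analysis).
EWGSOP2_THRESHOLDS = ClassificationConfig(27.0, 16.0)


def validate_cohort(cohort: pd.DataFrame, registry: ConditionRegistry) -> None:
    """Check schema: meta columns, condition columns, sex codes, restrictions."""
    missing = [c for c in META_COLUMNS if c not in cohort.columns]
    missing += [c for c in registry.condition_ids if c not in cohort.columns]
    if missing:
        raise CohortValidationError(f"cohort is missing columns: {missing}")
    bad_sex = set(cohort["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise CohortValidationError(f"unknown sex codes: {sorted(bad_sex)}")
    for sex in SEXES:
        mask = cohort["sex"] == sex
        for cid in registry.restricted_ids(sex):
            if cohort.loc[mask, cid].to_numpy().sum() > 0:
                raise CohortValidationError(
                    f"sex-restricted condition {cid!r} is positive for sex {sex}"
                )


def add_ltc_count(cohort: pd.DataFrame, registry: ConditionRegistry) -> pd.DataFrame:
    """Return a copy with ``n_ltc`` = row-wise count of positive conditions."""
    out = cohort.copy()
    out["n_ltc"] = out[registry.condition_ids].to_numpy(dtype=np.int64).sum(axis=1)
    return out


def classify_sarcopenia_risk(
    cohort: pd.DataFrame, cfg: ClassificationConfig = MAIN_THRESHOLDS
) -> pd.DataFrame:
    """Derive the nullable-boolean ``at_risk`` column.

    at_risk is True when grip strength is strictly below the sex cutoff, or
    when the participant was unable to attempt the test (if configured);
    missing when grip is missing and the participant was able to attempt.
    Idempotent: re-running on its own output changes nothing.
    """
    bad_sex = set(cohort["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise CohortValidationError(f"unknown sex codes: {sorted(bad_sex)}")
    out = cohort.copy()
    grip = out["grip_max_kg"].astype("Float64")
    thresholds = out["sex"].map(
        {"M": cfg.male_threshold_kg, "F": cfg.female_threshold_kg}
    ).astype("Float64")
    at_risk = grip < thresholds  # pandas nullable: NA where grip missing
    unable = out["unable_health"].astype(bool)
    if cfg.unable_counts_as_at_risk:
        at_risk = at_risk.mask(unable, True)
    out["at_risk"] = at_risk.astype("boolean")
    return out


def restrict_to_mltc(cohort: pd.DataFrame, min_ltc: int = 2) -> pd.DataFrame:
    """Keep classifiable participants with at least ``min_ltc`` conditions.

    Requires ``n_ltc`` and ``at_risk`` to be present; preserves row order.
    """
    for col in ("n_ltc", "at_risk"):
        if col not in cohort.columns:
            raise CohortValidationError(f"restrict_to_mltc requires column {col!r}")
    keep = (cohort["n_ltc"] >= min_ltc) & cohort["at_risk"].notna()
    out = cohort.loc[keep]
    if out.empty:
        warnings.warn("MLTC restriction produced an empty cohort", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

@dataclass
class SexDescriptives:
    n: int
    age_median: float
    age_iqr: tuple[float, float]
    grip_mean: Optional[float]
    grip_sd: Optional[float]
    at_risk_n: int
    at_risk_pct: float
    ltc_count_distribution: dict[int, int]
    condition_prevalence: dict[str, float]
    condition_counts: dict[str, int]


@dataclass
class CohortDescriptives:
    """Per-sex summaries plus between-sex p-values.

    Age is compared with a two-sided Mann-Whitney U test; every binary
    variable (at-risk status and each condition) with a Pearson chi-square
    test. Yates continuity correction is off by default (large-sample use);
    it can be enabled for small tables.
    """

    by_sex: dict[str, SexDescriptives]
    p_values: dict[str, Optional[float]]

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "by_sex": {s: asdict(d) for s, d in self.by_sex.items()},
            "p_values": self.p_values,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


def _chi2_p(table: np.ndarray, correction: bool) -> Optional[float]:
    # A variable absent (or universal) in both sexes gives a degenerate table.
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return None
    return float(stats.chi2_contingency(table, correction=correction)[1])


def describe_cohort(
    cohort: pd.DataFrame,
    registry: ConditionRegistry,
    *,
    yates_correction: bool = False,
) -> CohortDescriptives:
    """Baseline characteristics by sex with between-sex tests."""
    by_sex: dict[str, SexDescriptives] = {}
    for sex in SEXES:
        sub = cohort[cohort["sex"] == sex]
        grip = sub["grip_max_kg"].dropna().astype(float)
        at_risk = sub["at_risk"].astype(bool)
        counts = {
            cid: int(sub[cid].sum()) for cid in registry.condition_ids
        }
        n = len(sub)
        by_sex[sex] = SexDescriptives(
            n=n,
            age_median=float(sub["age_years"].median()) if n else float("nan"),
            age_iqr=(
                float(sub["age_years"].quantile(0.25)) if n else float("nan"),
                float(sub["age_years"].quantile(0.75)) if n else float("nan"),
            ),
            grip_mean=float(grip.mean()) if len(grip) else None,
            grip_sd=float(grip.std(ddof=1)) if len(grip) > 1 else None,
            at_risk_n=int(at_risk.sum()),
            at_risk_pct=float(100.0 * at_risk.mean()) if n else float("nan"),
            ltc_count_distribution={
                int(k): int(v) for k, v in sub["n_ltc"].value_counts().sort_index().items()
            },
            condition_prevalence={c: (counts[c] / n if n else float("nan")) for c in counts},
            condition_counts=counts,
        )

    p_values: dict[str, Optional[float]] = {}
    f = cohort[cohort["sex"] == "F"]
    m = cohort[cohort["sex"] == "M"]
    if len(f) and len(m):
        p_values["age_years"] = float(
            stats.mannwhitneyu(
                f["age_years"], m["age_years"], alternative="two-sided"
            ).pvalue
        )
        def table_for(col: str) -> np.ndarray:
            fv = f[col].astype(bool)
            mv = m[col].astype(bool)
            return np.array(
                [[int(fv.sum()), len(fv) - int(fv.sum())],
                 [int(mv.sum()), len(mv) - int(mv.sum())]]
            )
        p_values["at_risk"] = _chi2_p(table_for("at_risk"), yates_correction)
        for cid in registry.condition_ids:
            p_values[cid] = _chi2_p(table_for(cid), yates_correction)
    return CohortDescriptives(by_sex=by_sex, p_values=p_values)


def descriptives_to_frames(desc: CohortDescriptives) -> dict[str, pd.DataFrame]:
    """Per-sex condition prevalence tables (for CSV export)."""
    frames = {}
    for sex, d in desc.by_sex.items():
        frames[sex] = pd.DataFrame(
            {
                "condition_id": list(d.condition_counts),
                "n": list(d.condition_counts.values()),
                "prevalence_pct": [
                    round(100.0 * p, 2) for p in d.condition_prevalence.values()
                ],
            }
        )
    return frames


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_cohort_csv(
    path: Union[str, Path], registry: ConditionRegistry
) -> pd.DataFrame:
    """Read a cohort CSV (missing grip encoded as an empty field)."""
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "sex": str},
    )
    validate_cohort(df, registry)
    df["grip_max_kg"] = df["grip_max_kg"].astype("Float64")
    df["unable_health"] = df["unable_health"].astype(bool)
    for cid in registry.condition_ids:
        df[cid] = df[cid].astype(np.int8)
    return add_ltc_count(df, registry)


def write_cohort_csv(
    cohort: pd.DataFrame, path: Union[str, Path], registry: ConditionRegistry
) -> None:
    """Write the canonical column order; derived columns are not persisted."""
    cols = META_COLUMNS + registry.condition_ids
    out = cohort[cols].copy()
    out["unable_health"] = out["unable_health"].astype(bool)
    out.to_csv(path, index=False)
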