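"""Synthetic multimorbid cohorts with a threshold-crossing grip-strength model.

The generator emulates the statistical structure the downstream analysis
assumes: sex-stratified condition prevalences spanning roughly 0.02%-67%,
a multimorbidity profile with most participants carrying 2-4 conditions, and
maximum grip strength built from a sex/age baseline minus additive condition
decrements, minus extra *synergistic* decrements when a planted pair of
conditions co-occurs, plus Gaussian noise. Sarcopenia risk is then exactly
the analysis outcome: the latent grip crossing a sex-specific cutoff.

Because the mechanism is an explicit latent-threshold model, the true
additive-scale interaction (RERI) of any condition pair can be computed by
Monte-Carlo integration over the covariate and noise distributions — the
oracle used by the parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .cohort import ClassificationConfig, MAIN_THRESHOLDS, add_ltc_count, META_COLUMNS
from .registry import ConditionRegistry, load_registry


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


class SynergyEffect(BaseModel):
    """Extra grip decrement (kg) applied when both conditions are present."""

    condition_a: str
    condition_b: str
    effect_kg: float
    sex: Optional[str] = None  # None = both sexes (narrowed by sex restriction)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.condition_a, self.condition_b)


class GripModel(BaseModel):
    """Latent grip strength: baseline minus condition decrements plus noise."""

    intercept_kg: dict[str, float] = Field(default_factory=lambda: {"F": 27.5, "M": 44.0})
    age_slope_kg_per_year: float = 0.2
    main_effects_kg: dict[str, float] = Field(default_factory=dict)
    synergy_effects_kg: list[SynergyEffect] = Field(default_factory=list)
    noise_sd_kg: dict[str, float] = Field(default_factory=lambda: {"F": 6.0, "M": 8.5})

    @model_validator(mode="after")
    def _check(self) -> "GripModel":
        if any(sd <= 0 for sd in self.noise_sd_kg.values()):
            raise SimulationConfigError("noise_sd_kg must be strictly positive")
        return self


class Dependence(BaseModel):
    """Pairwise latent (tetrachoric-style) correlations for a Gaussian copula."""

    pairs: list[tuple[str, str, float]] = Field(default_factory=list)


class SimulationConfig(BaseModel):
    """Full specification of a synthetic cohort draw."""

    n_per_sex: dict[str, int] = Field(default_factory=lambda: {"F": 5000, "M": 5000})
    age_range_years: tuple[int, int] = (40, 70)
    prevalence: dict[str, dict[str, float]] = Field(default_factory=dict)  # sex -> cid -> p
    dependence: Optional[Dependence] = None
    grip_model: GripModel = Field(default_factory=GripModel)
    unable_rate: float = 0.0012
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for sex, prev in self.prevalence.items():
            for cid, p in prev.items():
                if not 0.0 <= p <= 1.0:
                    raise SimulationConfigError(f"prevalence of {cid!r} ({sex}) not in [0,1]")
        if not 0.0 <= self.unable_rate <= 1.0:
            raise SimulationConfigError("unable_rate must be in [0,1]")
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json")))


@dataclass
class GroundTruth:
    """What the generator planted: the grip model and the synergistic pairs."""

    planted_pairs: list[dict]
    grip_model: dict
    thresholds: dict[str, float]

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "planted_pairs": self.planted_pairs,
                    "grip_model": self.grip_model,
                    "thresholds": self.thresholds,
                },
                indent=1,
            )
        )


def _validate_against_registry(cfg: SimulationConfig, registry: ConditionRegistry) -> None:
    for sex, prev in cfg.prevalence.items():
        restricted = set(registry.restricted_ids(sex))
        for cid, p in prev.items():
            if cid not in registry:
                raise SimulationConfigError(f"prevalence references unknown condition {cid!r}")
            if cid in restricted and p > 0:
                raise SimulationConfigError(
                    f"condition {cid!r} is sex-restricted but has prevalence {p} for sex {sex}"
                )
    for cid in cfg.grip_model.main_effects_kg:
        if cid not in registry:
            raise SimulationConfigError(f"main effect references unknown condition {cid!r}")
    for syn in cfg.grip_model.synergy_effects_kg:
        for cid in syn.pair:
            if cid not in registry:
                raise SimulationConfigError(f"synergy references unknown condition {cid!r}")
            if syn.sex is not None and cid in registry.restricted_ids(syn.sex):
                raise SimulationConfigError(
                    f"synergy pair {syn.pair} names {cid!r}, which cannot occur for sex {syn.sex}"
                )


def _synergies_for_sex(cfg: SimulationConfig, registry: ConditionRegistry, sex: str):
    """Synergy effects applicable to one sex (sex-restricted pairs are narrowed)."""
    out = []
    restricted = set(registry.restricted_ids(sex))
    for syn in cfg.grip_model.synergy_effects_kg:
        if syn.sex is not None and syn.sex != sex:
            continue
        if syn.sex is None and restricted.intersection(syn.pair):
            continue  # pair impossible for this sex
        out.append(syn)
    return out


def _draw_conditions(
    cfg: SimulationConfig, registry: ConditionRegistry, sex: str, n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary condition matrix for one sex (independent or Gaussian-copula)."""
    ids = registry.condition_ids
    p = np.array([cfg.prevalence.get(sex, {}).get(cid, 0.0) for cid in ids])
    if cfg.dependence is None or not cfg.dependence.pairs:
        return (rng.random((n, len(ids))) < p).astype(np.int8)
    # Latent multivariate normal thresholded at the prevalence quantiles.
    k = len(ids)
    corr = np.eye(k)
    idx = {cid: i for i, cid in enumerate(ids)}
    for a, b, rho in cfg.dependence.pairs:
        if a not in idx or b not in idx:
            raise SimulationConfigError(f"dependence pair ({a}, {b}) not in registry")
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise SimulationConfigError("dependence matrix is not positive semi-definite")
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    z = rng.standard_normal((n, k)) @ chol.T
    with np.errstate(divide="ignore"):
        thresh = stats.norm.ppf(p)
    return (z < thresh).astype(np.int8)


def _grip_mean(
    cfg: SimulationConfig, registry: ConditionRegistry, sex: str,
    X: np.ndarray, ages: np.ndarray,
) -> np.ndarray:
    """Latent mean grip given covariates (the deterministic part of the model)."""
    gm = cfg.grip_model
    ids = registry.condition_ids
    idx = {cid: i for i, cid in enumerate(ids)}
    effects = np.array([gm.main_effects_kg.get(cid, 0.0) for cid in ids])
    mu = (
        gm.intercept_kg[sex]
        - gm.age_slope_kg_per_year * (ages - cfg.age_range_years[0])
        - X @ effects
    )
    for syn in _synergies_for_sex(cfg, registry, sex):
        both = X[:, idx[syn.condition_a]] * X[:, idx[syn.condition_b]]
        mu = mu - syn.effect_kg * both
    return mu


def generate_cohort(
    cfg: SimulationConfig,
    registry: Optional[ConditionRegistry] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a synthetic cohort; reproducible given ``cfg.seed``.

    Returns the cohort table (with ``n_ltc`` derived, before classification)
    and the planted ground truth.
    """
    registry = registry or load_registry()
    _validate_against_registry(cfg, registry)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    frames = []
    lo, hi = cfg.age_range_years
    for sex in ("F", "M"):
        n = cfg.n_per_sex.get(sex, 0)
        if n == 0:
            continue
        ages = rng.integers(lo, hi + 1, size=n)
        X = _draw_conditions(cfg, registry, sex, n, rng)
        mu = _grip_mean(cfg, registry, sex, X, ages.astype(float))
        grip = mu + rng.normal(0.0, cfg.grip_model.noise_sd_kg[sex], size=n)
        unable = rng.random(n) < cfg.unable_rate
        grip = np.where(unable, np.nan, grip)
        df = pd.DataFrame(X, columns=registry.condition_ids)
        df.insert(0, "unable_health", unable)
        df.insert(0, "grip_max_kg", grip)
        df.insert(0, "age_years", ages)
        df.insert(0, "sex", sex)
        frames.append(df)
    cohort = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=META_COLUMNS + registry.condition_ids
    )
    cohort.insert(0, "participant_id", [f"P{i:07d}" for i in range(len(cohort))])
    cohort["grip_max_kg"] = cohort["grip_max_kg"].astype("Float64")
    truth = GroundTruth(
        planted_pairs=[
            {"pair": list(s.pair), "effect_kg": s.effect_kg, "sex": s.sex}
            for s in cfg.grip_model.synergy_effects_kg
        ],
        grip_model=cfg.grip_model.model_dump(mode="json"),
        thresholds={"F": MAIN_THRESHOLDS.female_threshold_kg,
                    "M": MAIN_THRESHOLDS.male_threshold_kg},
    )
    return add_ltc_count(cohort, registry), truth


# ---------------------------------------------------------------------------
# True-interaction oracle
# ---------------------------------------------------------------------------

@dataclass
class TruePairEffect:
    """Monte-Carlo estimate of a pair's true additive interaction.

    ``reri_rr`` is on the risk-ratio scale (risks in the four exposure cells
    relative to the doubly-unexposed cell); ``reri_or`` is the analogous
    quantity with odds ratios, which is the exact estimand of the saturated
    logistic interaction model fitted downstream. Both come with Monte-Carlo
    standard errors from batching.
    """

    reri_rr: float
    reri_or: float
    se_rr: float
    se_or: float
    cell_risks: dict[str, float]


def true_pair_reri(
    cfg: SimulationConfig,
    pair: tuple[str, str],
    sex: str,
    classification: ClassificationConfig = MAIN_THRESHOLDS,
    *,
    n_draws: int = 1_000_000,
    oracle_seed: int = 12345,
    registry: Optional[ConditionRegistry] = None,
) -> TruePairEffect:
    """True RERI of a condition pair by Monte-Carlo integration.

    Draws ages and the *other* conditions from the generator's model, forces
    the pair into each of the four exposure cells with common random numbers,
    and integrates the Gaussian grip noise analytically:
    ``P(at risk | covariates) = u + (1-u) * Phi((threshold - mu) / sd)``
    where ``u`` is the unable rate. Cell risks are then averaged over draws.
    """
    registry = registry or load_registry()
    _validate_against_registry(cfg, registry)
    a, b = pair
    ia, ib = registry.index_of(a), registry.index_of(b)
    rng = np.random.default_rng(np.random.SeedSequence(oracle_seed))
    lo, hi = cfg.age_range_years
    ages = rng.integers(lo, hi + 1, size=n_draws).astype(float)
    X = _draw_conditions(cfg, registry, sex, n_draws, rng)
    thr = classification.threshold_for(sex)
    sd = cfg.grip_model.noise_sd_kg[sex]
    u = cfg.unable_rate if classification.unable_counts_as_at_risk else 0.0

    def cell_risk_draws(xa: int, xb: int) -> np.ndarray:
        Xc = X.copy()
        Xc[:, ia] = xa
        Xc[:, ib] = xb
        mu = _grip_mean(cfg, registry, sex, Xc, ages)
        return u + (1.0 - u) * stats.norm.cdf((thr - mu) / sd)

    draws = {(xa, xb): cell_risk_draws(xa, xb) for xa in (0, 1) for xb in (0, 1)}
    risks = {k: float(v.mean()) for k, v in draws.items()}
    if risks[(0, 0)] <= 0 or any(r >= 1 for r in risks.values()):
        raise SimulationConfigError(
            f"degenerate exposure cell risks {risks}: RERI undefined"
        )

    def reri_from(risks_: dict) -> tuple[float, float]:
        rr = {k: risks_[k] / risks_[(0, 0)] for k in risks_}
        odds = {k: risks_[k] / (1 - risks_[k]) for k in risks_}
        orr = {k: odds[k] / odds[(0, 0)] for k in odds}
        reri_rr = rr[(1, 1)] - rr[(1, 0)] - rr[(0, 1)] + 1
        reri_or = orr[(1, 1)] - orr[(1, 0)] - orr[(0, 1)] + 1
        return reri_rr, reri_or

    reri_rr, reri_or = reri_from(risks)
    # Monte-Carlo SE by batch means.
    n_batches = 20
    splits = {k: np.array_split(v, n_batches) for k, v in draws.items()}
    batch_rr, batch_or = [], []
    for i in range(n_batches):
        rr_i, or_i = reri_from({k: float(splits[k][i].mean()) for k in splits})
        batch_rr.append(rr_i)
        batch_or.append(or_i)
    se_rr = float(np.std(batch_rr, ddof=1) / np.sqrt(n_batches))
    se_or = float(np.std(batch_or, ddof=1) / np.sqrt(n_batches))
    return TruePairEffect(
        reri_rr=reri_rr, reri_or=reri_or, se_rr=se_rr, se_or=se_or,
        cell_risks={f"{k[0]}{k[1]}": v for k, v in risks.items()},
    )


# ---------------------------------------------------------------------------
# Packaged presets
# ---------------------------------------------------------------------------

# Per-sex prevalences (proportions) for the default calibration, spanning the
# realistic range from very rare (~0.02%) to very common (~67%).
_PREVALENCE_PCT: dict[str, tuple[float, float]] = {
    # condition_id: (female %, male %)
    "stroke": (3.33, 5.90),
    "coronary_artery_disease": (7.43, 20.65),
    "heart_failure": (0.14, 0.31),
    "peripheral_artery_disease": (0.66, 0.81),
    "heart_valve_disorders": (2.17, 1.81),
    "arrhythmia": (3.00, 5.15),
    "venous_thromboembolic_disease": (7.32, 6.17),
    "aneurysm": (0.02, 0.13),
    "hypertension": (52.71, 67.20),
    "diabetes": (10.85, 21.43),
    "addisons_disease": (0.13, 0.08),
    "thyroid_disorders": (21.71, 5.20),
    "copd": (6.34, 7.37),
    "asthma": (27.47, 22.53),
    "bronchiectasis": (0.80, 0.47),
    "parkinsons_disease": (0.28, 0.54),
    "epilepsy": (1.75, 2.07),
    "multiple_sclerosis": (0.98, 0.42),
    "paralysis": (1.05, 1.55),
    "transient_ischaemic_attack": (0.91, 1.22),
    "peripheral_neuropathy": (0.32, 0.48),
    "chronic_primary_pain": (0.70, 0.11),
    "solid_organ_cancers": (19.31, 12.58),
    "haematological_cancers": (0.94, 1.47),
    "metastatic_cancers": (0.05, 0.04),
    "melanoma": (1.81, 1.54),
    "benign_cerebral_tumours": (0.09, 0.04),
    "dementia": (0.05, 0.09),
    "schizophrenia": (0.18, 0.43),
    "depression": (16.58, 10.77),
    "anxiety": (4.09, 2.79),
    "bipolar_disorder": (0.71, 0.67),
    "drug_alcohol_misuse": (0.23, 0.83),
    "eating_disorder": (0.32, 0.03),
    "post_traumatic_stress_disorder": (0.18, 0.21),
    "connective_tissue_disease": (6.31, 3.22),
    "osteoarthritis": (26.68, 17.38),
    "musculoskeletal_injury": (5.63, 7.30),
    "osteoporosis": (6.63, 1.16),
    "gout": (0.62, 7.91),
    "chronic_liver_disease": (1.30, 1.55),
    "inflammatory_bowel_disease": (1.95, 1.93),
    "chronic_pancreatic_disease": (0.52, 0.67),
    "peptic_ulcer": (2.27, 3.79),
    "chronic_kidney_disease": (0.70, 0.89),
    "end_stage_kidney_disease": (0.13, 0.25),
    "endometriosis": (3.33, 0.0),
    "anaemia": (3.85, 1.49),
    "uncorrectable_vision_problems": (4.32, 6.20),
    "menieres_disease": (0.79, 0.53),
    "hiv_aids": (0.06, 0.43),
    "tuberculosis": (1.30, 1.30),
    "congenital_disease": (0.15, 0.18),
}

# Mean grip decrements (kg) for conditions with recognised muscle-strength
# associations; conditions not listed contribute no decrement.
_MAIN_EFFECTS_KG: dict[str, float] = {
    "stroke": 3.0,
    "coronary_artery_disease": 1.5,
    "heart_failure": 3.0,
    "paralysis": 4.0,
    "multiple_sclerosis": 4.0,
    "parkinsons_disease": 3.0,
    "diabetes": 2.0,
    "osteoarthritis": 2.0,
    "osteoporosis": 2.5,
    "connective_tissue_disease": 3.0,
    "copd": 1.5,
    "depression": 1.0,
    "chronic_primary_pain": 2.0,
    "musculoskeletal_injury": 1.5,
    "anaemia": 1.5,
    "dementia": 3.0,
    "epilepsy": 1.5,
    "uncorrectable_vision_problems": 1.0,
    "drug_alcohol_misuse": 1.0,
    "chronic_kidney_disease": 1.5,
    "end_stage_kidney_disease": 3.0,
}


def _prevalence_maps() -> dict[str, dict[str, float]]:
    return {
        "F": {cid: f / 100.0 for cid, (f, _m) in _PREVALENCE_PCT.items() if f > 0},
        "M": {cid: m / 100.0 for cid, (_f, m) in _PREVALENCE_PCT.items() if m > 0},
    }


def biobank_like_config(seed: int, n_per_sex: int = 5000) -> SimulationConfig:
    """Default calibration: realistic prevalences, no planted synergy."""
    return SimulationConfig(
        n_per_sex={"F": n_per_sex, "M": n_per_sex},
        prevalence=_prevalence_maps(),
        grip_model=GripModel(main_effects_kg=dict(_MAIN_EFFECTS_KG)),
        seed=seed,
    )


def full_scale_config(seed: int) -> SimulationConfig:
    """Same calibration at full analytic-sample scale (77 488 F / 62 513 M)."""
    cfg = biobank_like_config(seed)
    cfg.n_per_sex = {"F": 77488, "M": 62513}
    return cfg


#: The two pairs planted by the recovery preset (moderately prevalent, so an
#: at-risk leaf of >= 25 observations is reliably formable).
RECOVERY_PAIRS: tuple[tuple[str, str], ...] = (
    ("diabetes", "osteoarthritis"),
    ("asthma", "depression"),
)


def recovery_config(seed: int, n_per_sex: int = 20000,
                    synergy_kg: float = 20.0) -> SimulationConfig:
    """Planted-combination recovery preset: two strongly synergistic pairs."""
    cfg = biobank_like_config(seed, n_per_sex=n_per_sex)
    cfg.grip_model.synergy_effects_kg = [
        SynergyEffect(condition_a=a, condition_b=b, effect_kg=synergy_kg)
        for a, b in RECOVERY_PAIRS
    ]
    return cfg


def coverage_config(seed: int, n_per_sex: int = 20000) -> SimulationConfig:
    """Two-condition configuration for interaction CI coverage studies.

    Only the pair of interest carries prevalence and grip effects, the age
    slope is zero and the unable rate is zero, so the four exposure-cell
    risks are clean functions of the grip model — the cleanest regime for
    checking confidence-interval calibration of the interaction estimator.
    """
    return SimulationConfig(
        n_per_sex={"F": 0, "M": n_per_sex},
        prevalence={"M": {"diabetes": 0.25, "osteoarthritis": 0.25}},
        grip_model=GripModel(
            intercept_kg={"F": 27.5, "M": 45.0},
            age_slope_kg_per_year=0.0,
            main_effects_kg={"diabetes": 3.0, "osteoarthritis": 3.0},
            synergy_effects_kg=[
                SynergyEffect(
                    condition_a="diabetes", condition_b="osteoarthritis",
                    effect_kg=4.0, sex="M",
                )
            ],
            noise_sd_kg={"F": 6.0, "M": 6.0},
        ),
        unable_rate=0.0,
        seed=seed,
    )


PRESETS = {
    "biobank-like": biobank_like_config,
    "full-scale": full_scale_config,
    "recovery": recovery_config,
    "coverage": coverage_config,
}
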