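"""Sensitivity analyses: rerun the pipeline under single perturbations.

Three perturbations probe the robustness of the mined combinations — the
stricter EWGSOP2 grip cutoffs, a doubled false-negative penalty, and removal
of the most prevalent condition (hypertension by default) from the feature
set — plus an age-adjusted rerun of the triangulation regressions. Each
variant applies exactly one perturbation and, by default, reuses the main
run's seed stream so that differences in the top-k lists reflect the
perturbation rather than bootstrap noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .cohort import EWGSOP2_THRESHOLDS, MAIN_THRESHOLDS, ClassificationConfig
from .ensemble import CombinationRecord
from .pipeline import RunResult, run_analysis
from .registry import ConditionRegistry
from .tree import TreeHyperparams

VARIANT_NAMES = (
    "ewgsop2_thresholds",
    "doubled_fn_penalty",
    "drop_condition",
    "age_adjusted_logistic",
)


@dataclass(frozen=True)
class SensitivityVariant:
    """One named perturbation of the main analysis."""

    name: str
    penalty_multiplier: float = 2.0
    condition_to_drop: str = "hypertension"

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ValueError(
                f"unknown variant {self.name!r}; expected one of {VARIANT_NAMES}"
            )


@dataclass
class OverlapReport:
    """Top-k agreement between a variant and the main analysis, per sex."""

    variant: str
    by_sex: dict[str, dict]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex, d in self.by_sex.items():
            rows.append({
                "variant": self.variant,
                "sex": sex,
                "overlap": d["overlap"],
                "k": d["k"],
                "shared": "; ".join(d["shared"]),
                "variant_only": "; ".join(d["variant_only"]),
            })
        return pd.DataFrame(rows)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps({"variant": self.variant, "by_sex": self.by_sex}, indent=1)
        )


def run_variant(
    cohort_raw: pd.DataFrame,
    registry: ConditionRegistry,
    variant: SensitivityVariant,
    *,
    hp: TreeHyperparams = TreeHyperparams(),
    n_trees: int = 1000,
    k: int = 12,
    seed: int = 0,
    classification: ClassificationConfig = MAIN_THRESHOLDS,
    fresh_seed: Optional[int] = None,
    n_jobs: int = 1,
) -> RunResult:
    """Rerun the full pipeline under one perturbation.

    The raw (unrestricted) cohort is required because the threshold variant
    changes who is classifiable before the multimorbidity restriction.
    ``fresh_seed`` draws a new seed stream instead of reusing the main one.
    """
    if variant.condition_to_drop not in registry and variant.name == "drop_condition":
        raise KeyError(f"condition to drop not in registry: {variant.condition_to_drop!r}")
    use_seed = seed if fresh_seed is None else fresh_seed
    kwargs = dict(hp=hp, n_trees=n_trees, k=k, seed=use_seed, n_jobs=n_jobs,
                  classification=classification)
    if variant.name == "ewgsop2_thresholds":
        kwargs["classification"] = EWGSOP2_THRESHOLDS
    elif variant.name == "doubled_fn_penalty":
        kwargs["fn_multiplier"] = variant.penalty_multiplier
    elif variant.name == "drop_condition":
        kwargs["drop_condition"] = variant.condition_to_drop
    elif variant.name == "age_adjusted_logistic":
        kwargs["adjust_age"] = True
    return run_analysis(cohort_raw, registry, **kwargs)


def topk_overlap(
    main_result: RunResult, variant_result: RunResult, variant_name: str
) -> OverlapReport:
    """Count shared top-k condition sets (set semantics; rank is ignored)."""
    by_sex = {}
    for sex, main_res in main_result.by_sex.items():
        if sex not in variant_result.by_sex:
            continue
        var_res = variant_result.by_sex[sex]
        by_sex[sex] = _overlap(main_res.top_records, var_res.top_records)
    return OverlapReport(variant=variant_name, by_sex=by_sex)


def _overlap(
    main_topk: Sequence[CombinationRecord], variant_topk: Sequence[CombinationRecord]
) -> dict:
    main_sets = {r.conditions: r.label for r in main_topk}
    var_sets = {r.conditions: r.label for r in variant_topk}
    shared = set(main_sets) & set(var_sets)
    return {
        "overlap": len(shared),
        "k": len(main_sets),
        "shared": sorted(main_sets[s] for s in shared),
        "variant_only": sorted(
            var_sets[s] for s in set(var_sets) - set(main_sets)
        ),
    }
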