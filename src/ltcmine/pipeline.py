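"""End-to-end orchestration: classify, restrict, mine, evaluate, triangulate.

The analysis is stratified by sex throughout (patterns of multimorbidity
differ between men and women). One master seed spawns per-stage child seeds
by a fixed counter scheme — stage k for sex s always receives the same child
seed — so adding a stage never perturbs earlier ones and a saved
configuration reproduces every output exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union
import json

import numpy as np
import pandas as pd

from . import cohort as cm
from .cohort import ClassificationConfig, MAIN_THRESHOLDS
from .ensemble import (
    CombinationRecord,
    EnsembleResult,
    bootstrap_ensemble,
    composite_scores,
    ensemble_summary,
    evaluate_combination,
    rank_and_retain,
    records_to_frame,
)
from .interaction import TriangulationEntry, triangulate, triangulation_to_frame
from .registry import ConditionRegistry
from .tree import TreeHyperparams

logger = logging.getLogger(__name__)

SEXES = ("F", "M")


def stage_seeds(master_seed: int) -> dict[str, np.random.SeedSequence]:
    """Fixed counter scheme: stage name -> child seed sequence."""
    names = ["simulate", "ensemble_F", "ensemble_M", "bootstrap_ci_F",
             "bootstrap_ci_M", "reserved_0", "reserved_1", "reserved_2"]
    children = np.random.SeedSequence(master_seed).spawn(len(names))
    return dict(zip(names, children))


@dataclass
class SexResult:
    sex: str
    n: int
    at_risk_pct: float
    summary: dict
    top_records: list[CombinationRecord]
    ranked_records: list[CombinationRecord]
    triangulation: list[TriangulationEntry]
    losses_used: list[float]


@dataclass
class RunResult:
    descriptives: cm.CohortDescriptives
    by_sex: dict[str, SexResult]
    settings: dict


def run_analysis(
    cohort_raw: pd.DataFrame,
    registry: ConditionRegistry,
    *,
    classification: ClassificationConfig = MAIN_THRESHOLDS,
    hp: TreeHyperparams = TreeHyperparams(),
    n_trees: int = 1000,
    k: int = 12,
    seed: int = 0,
    adjust_age: bool = False,
    fn_multiplier: float = 1.0,
    drop_condition: Optional[str] = None,
    min_ltc: int = 2,
    recompute_loss: bool = True,
    n_jobs: int = 1,
) -> RunResult:
    """Run the full pipeline on a raw (unrestricted, unclassified) cohort.

    ``drop_condition`` removes one condition from the feature set and the
    combination universe (multimorbidity eligibility is unchanged: the count
    of conditions still includes the dropped one, since removal probes the
    tree inputs, not the sample definition).
    """
    cohort = cm.classify_sarcopenia_risk(cohort_raw, classification)
    if "n_ltc" not in cohort.columns:
        cohort = cm.add_ltc_count(cohort, registry)
    analytic = cm.restrict_to_mltc(cohort, min_ltc=min_ltc)
    desc = cm.describe_cohort(analytic, registry)
    reg_view = registry.drop(drop_condition) if drop_condition else registry
    seeds = stage_seeds(seed)

    by_sex: dict[str, SexResult] = {}
    for sex in SEXES:
        sub = analytic[analytic["sex"] == sex]
        if sub.empty:
            logger.warning("no participants of sex %s after restriction; skipped", sex)
            continue
        logger.info("sex %s: n=%d, at-risk=%.2f%%", sex, len(sub),
                    100 * sub["at_risk"].astype(bool).mean())
        ens = bootstrap_ensemble(
            sub, reg_view, hp, n_trees=n_trees, seed=seeds[f"ensemble_{sex}"],
            recompute_loss=recompute_loss, fn_multiplier=fn_multiplier,
            n_jobs=n_jobs,
        )
        records = composite_scores(ens, reg_view)
        top, ranked = rank_and_retain(records, reg_view, k=k)
        for rec in ranked:
            rec.metrics = evaluate_combination(sub, rec.conditions)
        tri = triangulate(sub, top, reg_view, adjust_age=adjust_age)
        by_sex[sex] = SexResult(
            sex=sex,
            n=len(sub),
            at_risk_pct=float(100 * sub["at_risk"].astype(bool).mean()),
            summary=ensemble_summary(records, n_trees),
            top_records=top,
            ranked_records=ranked,
            triangulation=tri,
            losses_used=[l.fn_penalty for l in ens.losses],
        )
    return RunResult(
        descriptives=desc,
        by_sex=by_sex,
        settings={
            "classification": {
                "male_threshold_kg": classification.male_threshold_kg,
                "female_threshold_kg": classification.female_threshold_kg,
                "unable_counts_as_at_risk": classification.unable_counts_as_at_risk,
            },
            "hyperparams": {
                "max_depth": hp.max_depth,
                "min_node_size": hp.min_node_size,
                "min_split": hp.effective_min_split,
                "complexity_penalty": hp.complexity_penalty,
            },
            "n_trees": n_trees,
            "k": k,
            "seed": seed,
            "adjust_age": adjust_age,
            "fn_multiplier": fn_multiplier,
            "drop_condition": drop_condition,
            "min_ltc": min_ltc,
            "recompute_loss": recompute_loss,
        },
    )


def write_run_outputs(result: RunResult, outdir: Union[str, Path],
                      registry: ConditionRegistry) -> None:
    """Persist a run: descriptives, ranked combinations, triangulation, log of
    settings. CSV tables round percentages/ORs to 2 dp; JSON keeps full
    precision where it matters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.descriptives.to_json(outdir / "descriptives.json")
    for sex, frame in cm.descriptives_to_frames(result.descriptives).items():
        frame.to_csv(outdir / f"descriptives_{sex}.csv", index=False)
    for sex, res in result.by_sex.items():
        records_to_frame(res.top_records).to_csv(
            outdir / f"combinations_top_{sex}.csv", index=False
        )
        records_to_frame(res.ranked_records).to_csv(
            outdir / f"combinations_all_{sex}.csv", index=False
        )
        triangulation_to_frame(res.triangulation).to_csv(
            outdir / f"triangulation_{sex}.csv", index=False
        )
        (outdir / f"ensemble_summary_{sex}.json").write_text(
            json.dumps(res.summary, indent=1)
        )
    (outdir / "run_settings.json").write_text(json.dumps(result.settings, indent=1))
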