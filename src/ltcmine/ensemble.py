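"""Bootstrap tree ensembles and interpretable combination mining.

The ensemble stage bags the cost-sensitive tree: many trees are fitted on
with-replacement resamples of the (single-sex, multimorbid, classified)
cohort, each with its loss matrix recomputed from that resample's outcome
proportions. Every root-to-leaf path ending in an "at risk" leaf is read off
as a rule, reduced to its positive literals (conditions *required present* —
requirements of absence are disregarded), and the resulting condition
combinations are scored by summing, across all contributing leaves in the
ensemble, the leaf-level probability of a correct classification (the leaf's
at-risk fraction on its own bootstrap sample). The score therefore blends how
often a combination is discovered with how accurately it classifies.

The top-scoring combinations are then evaluated against the analytic sample
with standard confusion-matrix metrics (prevalence, PPV, sensitivity,
specificity, accuracy).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortValidationError
from .registry import ConditionRegistry
from .tree import (
    DecisionTreeModel,
    LossMatrix,
    TreeHyperparams,
    fit_tree,
    loss_from_proportions,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RulePath:
    """Root-to-leaf conjunction ending in an at-risk leaf."""

    literals: tuple[tuple[str, bool], ...]  # (condition_id, required present?)
    leaf_n: int
    leaf_n_at_risk: int
    tree_index: int

    @property
    def leaf_ppv(self) -> float:
        return self.leaf_n_at_risk / self.leaf_n


@dataclass
class CombinationMetrics:
    """Confusion-matrix metrics of a combination, as percentages."""

    prevalence: float
    positive_predictive_value: Optional[float]
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class CombinationRecord:
    """A positive-literal condition set with its ensemble evidence."""

    conditions: frozenset[str]
    label: str
    n_trees_appearing: int
    composite_score: float
    n_leaves: int = 0
    metrics: Optional[CombinationMetrics] = None


@dataclass
class EnsembleResult:
    trees: list[DecisionTreeModel]
    bootstrap_indices: list[np.ndarray]
    losses: list[LossMatrix]
    n_trees: int


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def design_matrix(
    cohort: pd.DataFrame, registry: ConditionRegistry
) -> tuple[np.ndarray, np.ndarray]:
    """Condition matrix (registry order) and at-risk labels from a cohort."""
    if cohort["at_risk"].isna().any():
        raise CohortValidationError("cohort contains unclassifiable participants")
    X = cohort[registry.condition_ids].to_numpy(dtype=np.float64)
    y = cohort["at_risk"].astype(bool).to_numpy().astype(np.float64)
    return X, y


def bootstrap_ensemble(
    cohort: pd.DataFrame,
    registry: ConditionRegistry,
    hp: TreeHyperparams = TreeHyperparams(),
    n_trees: int = 1000,
    seed: int = 0,
    *,
    recompute_loss: bool = True,
    fn_multiplier: float = 1.0,
    bootstrap: bool = True,
    n_jobs: int = 1,
) -> EnsembleResult:
    """Fit ``n_trees`` cost-sensitive trees on bootstrap resamples.

    The loss matrix is, by default, recomputed from each bootstrap sample's
    outcome proportions (``recompute_loss=False`` freezes it at the
    full-sample value). ``fn_multiplier`` scales the false-negative penalty
    (the doubled-penalty sensitivity analysis uses 2.0). ``bootstrap=False``
    is a test hook fitting every tree on the full sample.

    One child seed is drawn per tree from ``seed``, so results are
    reproducible and independent of evaluation order and of ``n_jobs``
    (tree fitting is embarrassingly parallel across replicates).
    """
    X, y = design_matrix(cohort, registry)
    n = len(y)
    p_full = float(y.mean())
    if not 0.0 < p_full < 1.0:
        raise CohortValidationError("cohort outcome is constant; nothing to learn")
    base_loss = loss_from_proportions(p_full).scaled(fn_multiplier)
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    seeds = seed.spawn(n_trees)
    n_stumps = [0]

    def fit_one(t: int) -> tuple[DecisionTreeModel, np.ndarray, LossMatrix]:
        rng = np.random.default_rng(seeds[t])
        idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        yb = y[idx]
        pb = float(yb.mean())
        if recompute_loss and 0.0 < pb < 1.0:
            loss = loss_from_proportions(pb).scaled(fn_multiplier)
        else:
            loss = base_loss
            if not 0.0 < pb < 1.0:
                n_stumps[0] += 1
        tree = fit_tree(X[idx], yb, loss, hp, feature_names=registry.condition_ids)
        return tree, idx, loss

    if n_jobs > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=n_jobs) as pool:
            fitted = list(pool.map(fit_one, range(n_trees)))
    else:
        fitted = [fit_one(t) for t in range(n_trees)]
    if n_stumps[0]:
        logger.warning("%d bootstrap samples had a single outcome class", n_stumps[0])
    return EnsembleResult(
        trees=[f[0] for f in fitted],
        bootstrap_indices=[f[1] for f in fitted],
        losses=[f[2] for f in fitted],
        n_trees=n_trees,
    )


# ---------------------------------------------------------------------------
# Rule extraction and scoring
# ---------------------------------------------------------------------------

def extract_rules(tree: DecisionTreeModel, tree_index: int = 0) -> list[RulePath]:
    """One rule per leaf predicting the at-risk class."""
    rules = []
    for leaf, path in tree.leaves():
        if leaf.predicted_class != 1:
            continue
        literals = tuple(
            (tree.feature_names[j], required) for j, required in path
        )
        rules.append(
            RulePath(
                literals=literals,
                leaf_n=leaf.n,
                leaf_n_at_risk=leaf.n_at_risk,
                tree_index=tree_index,
            )
        )
    return rules


def reduce_to_positive(path: RulePath) -> frozenset[str]:
    """Positive literals only; absence requirements are disregarded.

    May be empty (a path consisting solely of absence requirements); callers
    discard empty reductions.
    """
    return frozenset(cid for cid, required in path.literals if required)


def combination_label(
    conditions: frozenset[str], registry: ConditionRegistry
) -> str:
    """Human-readable label in registry order; singletons are read as the
    condition together with any other LTC (the cohort is all-multimorbid)."""
    ordered = registry.sorted_conditions(conditions)
    names = [registry[cid].display_name for cid in ordered]
    if len(names) == 1:
        return f"{names[0]} and any other LTC"
    return " and ".join(names)


def composite_scores(
    ensemble: EnsembleResult, registry: ConditionRegistry
) -> list[CombinationRecord]:
    """Aggregate reduced rules across the ensemble into scored combinations.

    Each contributing at-risk leaf adds its in-bag at-risk fraction to the
    combination's composite score; ``n_trees_appearing`` counts distinct
    trees. All-negative reductions are discarded (and counted in the log).
    """
    scores: dict[frozenset[str], float] = {}
    tree_sets: dict[frozenset[str], set[int]] = {}
    leaf_counts: dict[frozenset[str], int] = {}
    n_discarded = 0
    for t, tree in enumerate(ensemble.trees):
        for rule in extract_rules(tree, tree_index=t):
            combo = reduce_to_positive(rule)
            if not combo:
                n_discarded += 1
                continue
            scores[combo] = scores.get(combo, 0.0) + rule.leaf_ppv
            tree_sets.setdefault(combo, set()).add(t)
            leaf_counts[combo] = leaf_counts.get(combo, 0) + 1
    if n_discarded:
        logger.info("discarded %d all-negative rule reductions", n_discarded)
    return [
        CombinationRecord(
            conditions=combo,
            label=combination_label(combo, registry),
            n_trees_appearing=len(tree_sets[combo]),
            composite_score=scores[combo],
            n_leaves=leaf_counts[combo],
        )
        for combo in scores
    ]


def rank_and_retain(
    records: Sequence[CombinationRecord],
    registry: ConditionRegistry,
    k: int = 12,
) -> tuple[list[CombinationRecord], list[CombinationRecord]]:
    """Rank by descending composite score and keep the top ``k``.

    Ties break by higher tree-appearance count, then registry-lexicographic
    condition sets. Returns (top-k, full ranked list); if fewer than ``k``
    combinations exist, all are returned with a warning in the log.
    """
    def sort_key(r: CombinationRecord):
        idx = tuple(registry.index_of(c) for c in registry.sorted_conditions(r.conditions))
        return (-r.composite_score, -r.n_trees_appearing, idx)

    ranked = sorted(records, key=sort_key)
    if len(ranked) < k:
        logger.warning("only %d combinations available (requested top %d)",
                       len(ranked), k)
    return ranked[:k], ranked


# ---------------------------------------------------------------------------
# Evaluation on the analytic sample
# ---------------------------------------------------------------------------

def evaluate_combination(
    cohort: pd.DataFrame, conditions: frozenset[str] | set[str]
) -> CombinationMetrics:
    """Confusion-matrix metrics of "all conditions present" as a classifier.

    For singleton sets the exposure is simply having that condition; in an
    all-multimorbid cohort this is exactly "the condition and any other LTC".
    """
    if not conditions:
        raise ValueError("conditions must be non-empty")
    exposed = np.ones(len(cohort), dtype=bool)
    for cid in conditions:
        exposed &= cohort[cid].to_numpy() == 1
    at_risk = cohort["at_risk"].astype(bool).to_numpy()
    n = len(cohort)
    a = int(np.sum(exposed & at_risk))
    b = int(np.sum(exposed & ~at_risk))
    c = int(np.sum(~exposed & at_risk))
    d = int(np.sum(~exposed & ~at_risk))
    ppv = 100.0 * a / (a + b) if (a + b) else None
    return CombinationMetrics(
        prevalence=100.0 * (a + b) / n,
        positive_predictive_value=ppv,
        sensitivity=100.0 * a / (a + c) if (a + c) else 0.0,
        specificity=100.0 * d / (b + d) if (b + d) else 0.0,
        accuracy=100.0 * (a + d) / n,
    )


def ensemble_summary(records: Sequence[CombinationRecord], n_trees: int) -> dict:
    """Distinct combinations found, and how many appear in at least half the
    ensemble."""
    return {
        "n_distinct_combinations": len(records),
        "n_in_at_least_half": sum(
            1 for r in records if r.n_trees_appearing >= n_trees / 2
        ),
        "n_trees": n_trees,
    }


def count_combinations(
    n_conditions: int, size: Optional[int] = None, max_size: Optional[int] = None
) -> int:
    """Number of condition combinations: C(n, k), or the cumulative
    sum over sizes 1..max_size."""
    if n_conditions < 0:
        raise ValueError("n_conditions must be non-negative")
    if (size is None) == (max_size is None):
        raise ValueError("give exactly one of size or max_size")
    if size is not None:
        if size < 0 or size > n_conditions:
            raise ValueError("size must be in [0, n_conditions]")
        return math.comb(n_conditions, size)
    if max_size < 1 or max_size > n_conditions:
        raise ValueError("max_size must be in [1, n_conditions]")
    return sum(math.comb(n_conditions, k) for k in range(1, max_size + 1))


def records_to_frame(records: Sequence[CombinationRecord]) -> pd.DataFrame:
    """Ranked-combination table in the report layout (percentages to 2 dp)."""
    rows = []
    for rank, r in enumerate(records, start=1):
        m = r.metrics
        rows.append(
            {
                "rank": rank,
                "label": r.label,
                "conditions": "|".join(sorted(r.conditions)),
                "composite_score": round(r.composite_score, 4),
                "n_trees_appearing": r.n_trees_appearing,
                "prevalence_pct": round(m.prevalence, 2) if m else None,
                "ppv_pct": (
                    round(m.positive_predictive_value, 2)
                    if m and m.positive_predictive_value is not None else None
                ),
                "sensitivity_pct": round(m.sensitivity, 2) if m else None,
                "specificity_pct": round(m.specificity, 2) if m else None,
                "accuracy_pct": round(m.accuracy, 2) if m else None,
            }
        )
    return pd.DataFrame(rows)
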