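"""Rule ensemble: bootstrap bagging, rule extraction, positive-literal
reduction, composite scoring, ranking and combination evaluation."""

import numpy as np
import pandas as pd
import pytest

import ltcmine as lm
from ltcmine.ensemble import design_matrix
from ltcmine.tree import TreeNode

from conftest import make_cohort


def manual_tree(registry, spec_nodes):
    """Build a DecisionTreeModel from a nested dict spec (tests only)."""
    counter = [0]

    def build(s, depth):
        node = TreeNode(
            node_id=counter[0], depth=depth, n=s["n"], n_at_risk=s["n_at_risk"],
            predicted_class=s["class"],
        )
        counter[0] += 1
        if "split" in s:
            node.split = registry.index_of(s["split"])
            node.present = build(s["present"], depth + 1)
            node.absent = build(s["absent"], depth + 1)
        return node

    root = build(spec_nodes, 0)
    return lm.DecisionTreeModel(
        root=root, feature_names=registry.condition_ids,
        loss=lm.LossMatrix(2.0), hyperparams=lm.TreeHyperparams(), n_train=spec_nodes["n"],
    )


class TestRuleExtraction:
    def test_no_at_risk_leaf_gives_no_rules(self, registry):
        tree = manual_tree(registry, {"n": 100, "n_at_risk": 10, "class": 0})
        assert lm.extract_rules(tree) == []

    def test_depth_one_present_branch(self, registry):
        tree = manual_tree(registry, {
            "n": 100, "n_at_risk": 30, "class": 0, "split": "osteoarthritis",
            "present": {"n": 40, "n_at_risk": 25, "class": 1},
            "absent": {"n": 60, "n_at_risk": 5, "class": 0},
        })
        rules = lm.extract_rules(tree, tree_index=7)
        assert len(rules) == 1
        (rule,) = rules
        assert rule.literals == (("osteoarthritis", True),)
        assert rule.leaf_n == 40 and rule.leaf_n_at_risk == 25
        assert rule.tree_index == 7

    def test_depth_two_conjunction(self, registry):
        tree = manual_tree(registry, {
            "n": 200, "n_at_risk": 50, "class": 0, "split": "diabetes",
            "present": {
                "n": 80, "n_at_risk": 40, "class": 0, "split": "stroke",
                "present": {"n": 30, "n_at_risk": 25, "class": 1},
                "absent": {"n": 50, "n_at_risk": 15, "class": 0},
            },
            "absent": {"n": 120, "n_at_risk": 10, "class": 0},
        })
        (rule,) = lm.extract_rules(tree)
        assert rule.literals == (("diabetes", True), ("stroke", True))


class TestReduction:
    def test_negative_literals_disregarded(self):
        path = lm.RulePath(
            literals=(("diabetes", True), ("hypertension", False), ("stroke", True)),
            leaf_n=50, leaf_n_at_risk=30, tree_index=0,
        )
        assert lm.reduce_to_positive(path) == {"diabetes", "stroke"}

    def test_all_negative_reduces_to_empty(self):
        path = lm.RulePath(literals=(("hypertension", False),),
                           leaf_n=50, leaf_n_at_risk=30, tree_index=0)
        assert lm.reduce_to_positive(path) == frozenset()

    def test_singleton_label_any_other_ltc(self, registry):
        label = lm.combination_label(frozenset({"connective_tissue_disease"}), registry)
        assert label == "Connective tissue disease and any other LTC"

    def test_pair_label_registry_order(self, registry):
        label = lm.combination_label(frozenset({"osteoarthritis", "diabetes"}), registry)
        assert label == "Diabetes and Osteoarthritis"


class TestCompositeScores:
    def test_single_leaf_score(self, registry):
        tree = manual_tree(registry, {
            "n": 100, "n_at_risk": 40, "class": 0, "split": "asthma",
            "present": {"n": 80, "n_at_risk": 40, "class": 1},
            "absent": {"n": 20, "n_at_risk": 0, "class": 0},
        })
        ens = lm.EnsembleResult(trees=[tree], bootstrap_indices=[np.arange(100)],
                                losses=[lm.LossMatrix(2.0)], n_trees=1)
        (rec,) = lm.composite_scores(ens, registry)
        assert rec.conditions == {"asthma"}
        assert rec.composite_score == pytest.approx(0.5)
        assert rec.n_trees_appearing == 1

    def test_cross_tree_summation(self, registry):
        # {diabetes} collected from two trees (leaf PPVs 0.4 and 0.5, the
        # first via a disregarded hypertension-absent literal) sums to 0.9;
        # the {diabetes, hypertension} sibling leaf is a separate combination
        t1 = manual_tree(registry, {
            "n": 300, "n_at_risk": 100, "class": 0, "split": "diabetes",
            "present": {
                "n": 150, "n_at_risk": 80, "class": 0, "split": "hypertension",
                "present": {"n": 50, "n_at_risk": 30, "class": 1},   # PPV 0.6
                "absent": {"n": 100, "n_at_risk": 40, "class": 1},   # PPV 0.4
            },
            "absent": {"n": 150, "n_at_risk": 20, "class": 0},
        })
        t2 = manual_tree(registry, {
            "n": 300, "n_at_risk": 100, "class": 0, "split": "diabetes",
            "present": {"n": 100, "n_at_risk": 50, "class": 1},      # PPV 0.5
            "absent": {"n": 200, "n_at_risk": 50, "class": 0},
        })
        ens = lm.EnsembleResult(trees=[t1, t2], bootstrap_indices=[None, None],
                                losses=[lm.LossMatrix(2.0)] * 2, n_trees=2)
        recs = {frozenset(r.conditions): r for r in lm.composite_scores(ens, registry)}
        assert set(recs) == {frozenset({"diabetes"}),
                             frozenset({"diabetes", "hypertension"})}
        solo = recs[frozenset({"diabetes"})]
        assert solo.composite_score == pytest.approx(0.4 + 0.5)
        assert solo.n_trees_appearing == 2 and solo.n_leaves == 2
        both = recs[frozenset({"diabetes", "hypertension"})]
        assert both.composite_score == pytest.approx(0.6)
        assert both.n_trees_appearing == 1

    def test_empty_ensemble(self, registry):
        ens = lm.EnsembleResult(trees=[], bootstrap_indices=[], losses=[], n_trees=0)
        assert lm.composite_scores(ens, registry) == []


class TestRanking:
    def _rec(self, conditions, score, n_trees):
        return lm.CombinationRecord(
            conditions=frozenset(conditions), label="x",
            n_trees_appearing=n_trees, composite_score=score,
        )

    def test_descending_score_top_k(self, registry):
        recs = [self._rec({"asthma"}, 1.0, 5), self._rec({"gout"}, 3.0, 5),
                self._rec({"stroke"}, 2.0, 5)]
        top, ranked = lm.rank_and_retain(recs, registry, k=2)
        assert [r.composite_score for r in top] == [3.0, 2.0]
        assert len(ranked) == 3

    def test_tie_broken_by_tree_count_then_registry_order(self, registry):
        recs = [self._rec({"gout"}, 2.0, 300), self._rec({"asthma"}, 2.0, 700),
                self._rec({"stroke"}, 2.0, 700)]
        top, _ = lm.rank_and_retain(recs, registry, k=3)
        # 700-tree records first; stroke precedes asthma in the registry
        assert [sorted(r.conditions)[0] for r in top] == ["stroke", "asthma", "gout"]

    def test_k_larger_than_list(self, registry):
        recs = [self._rec({"asthma"}, 1.0, 1)]
        top, _ = lm.rank_and_retain(recs, registry, k=12)
        assert len(top) == 1


class TestEvaluation:
    def test_hand_computed_confusion_matrix(self, registry):
        # exposed/at-risk cells: a=50, b=50, c=10, d=890 (n=1000)
        rows = (
            [{"sex": "F", "grip_max_kg": 10.0, "conditions": ["asthma", "gout"]}] * 50
            + [{"sex": "F", "grip_max_kg": 30.0, "conditions": ["asthma", "gout"]}] * 50
            + [{"sex": "F", "grip_max_kg": 10.0, "conditions": ["stroke", "gout"]}] * 10
            + [{"sex": "F", "grip_max_kg": 30.0, "conditions": ["stroke", "gout"]}] * 890
        )
        cohort = lm.restrict_to_mltc(
            lm.classify_sarcopenia_risk(make_cohort(rows, registry))
        )
        m = lm.evaluate_combination(cohort, {"asthma", "gout"})
        assert m.prevalence == pytest.approx(10.0)
        assert m.positive_predictive_value == pytest.approx(50.0)
        assert m.sensitivity == pytest.approx(83.33, abs=0.005)
        assert m.specificity == pytest.approx(94.68, abs=0.005)
        assert m.accuracy == pytest.approx(94.0)

    def test_perfect_exposure(self, registry):
        rows = (
            [{"sex": "M", "grip_max_kg": 10.0, "conditions": ["asthma", "gout"]}] * 30
            + [{"sex": "M", "grip_max_kg": 50.0, "conditions": ["stroke", "copd"]}] * 70
        )
        cohort = lm.restrict_to_mltc(
            lm.classify_sarcopenia_risk(make_cohort(rows, registry))
        )
        m = lm.evaluate_combination(cohort, {"asthma", "gout"})
        assert (m.positive_predictive_value, m.sensitivity, m.specificity) == (100, 100, 100)

    def test_zero_exposed_ppv_missing(self, registry, analytic_cohort):
        m = lm.evaluate_combination(analytic_cohort, {"dementia", "aneurysm", "hiv_aids"})
        assert m.prevalence == 0.0
        assert m.positive_predictive_value is None

    def test_accuracy_identity(self, registry, analytic_cohort):
        # accuracy = sensitivity * p + specificity * (1 - p)
        sub = analytic_cohort[analytic_cohort["sex"] == "F"]
        p = sub["at_risk"].astype(bool).mean()
        for conds in ({"hypertension"}, {"diabetes", "osteoarthritis"},
                      {"asthma", "depression"}):
            m = lm.evaluate_combination(sub, conds)
            assert m.accuracy == pytest.approx(
                m.sensitivity * p + m.specificity * (1 - p), abs=0.01
            )


class TestEnsembleFitting:
    def test_same_seed_identical_ensembles(self, registry, analytic_cohort):
        sub = analytic_cohort[analytic_cohort["sex"] == "M"]
        a = lm.bootstrap_ensemble(sub, registry, n_trees=5, seed=13)
        b = lm.bootstrap_ensemble(sub, registry, n_trees=5, seed=13)
        assert [t.to_json() for t in a.trees] == [t.to_json() for t in b.trees]

    def test_thread_count_does_not_change_results(self, registry, analytic_cohort):
        sub = analytic_cohort[analytic_cohort["sex"] == "M"]
        a = lm.bootstrap_ensemble(sub, registry, n_trees=6, seed=3, n_jobs=1)
        b = lm.bootstrap_ensemble(sub, registry, n_trees=6, seed=3, n_jobs=3)
        assert [t.to_json() for t in a.trees] == [t.to_json() for t in b.trees]

    def test_full_sample_single_tree_equals_fit_tree(self, registry, analytic_cohort):
        sub = analytic_cohort[analytic_cohort["sex"] == "F"]
        ens = lm.bootstrap_ensemble(sub, registry, n_trees=1, seed=0, bootstrap=False)
        X, y = design_matrix(sub, registry)
        direct = lm.fit_tree(X, y, lm.loss_from_proportions(y.mean()),
                             lm.TreeHyperparams(), feature_names=registry.condition_ids)
        assert ens.trees[0].to_json() == direct.to_json()

    def test_constraints_hold_across_ensemble(self, registry, analytic_cohort):
        sub = analytic_cohort[analytic_cohort["sex"] == "F"]
        hp = lm.TreeHyperparams(max_depth=10, min_node_size=25)
        ens = lm.bootstrap_ensemble(sub, registry, hp, n_trees=10, seed=2)
        for tree in ens.trees:
            for leaf, _ in tree.leaves():
                assert leaf.n >= 25 and leaf.depth <= 10

    def test_at_risk_leaf_counts_match_predictions(self, registry, analytic_cohort):
        # the at-risk leaves partition the tree's predicted-positive support
        sub = analytic_cohort[analytic_cohort["sex"] == "F"]
        X, _ = design_matrix(sub, registry)
        ens = lm.bootstrap_ensemble(sub, registry, n_trees=3, seed=4)
        for tree, idx in zip(ens.trees, ens.bootstrap_indices):
            labels, _ = tree.predict(X[idx])
            leaf_total = sum(r.leaf_n for r in lm.extract_rules(tree))
            assert leaf_total == int((labels == 1).sum())

    def test_per_leaf_contributions_bounded(self, registry, analytic_cohort):
        sub = analytic_cohort[analytic_cohort["sex"] == "M"]
        ens = lm.bootstrap_ensemble(sub, registry, n_trees=5, seed=8)
        for t, tree in enumerate(ens.trees):
            for rule in lm.extract_rules(tree, t):
                assert 0.0 < rule.leaf_ppv <= 1.0


class TestSummaryAndCounts:
    def _rec(self, n_trees):
        return lm.CombinationRecord(conditions=frozenset({"asthma"}), label="x",
                                    n_trees_appearing=n_trees, composite_score=1.0)

    def test_summary_counts(self):
        recs = [self._rec(600), self._rec(400), self._rec(900)]
        s = lm.ensemble_summary(recs, 1000)
        assert s["n_distinct_combinations"] == 3
        assert s["n_in_at_least_half"] == 2
        assert lm.ensemble_summary([], 1000)["n_distinct_combinations"] == 0
        one = lm.ensemble_summary([self._rec(10)], 10)
        assert (one["n_distinct_combinations"], one["n_in_at_least_half"]) == (1, 1)

    def test_count_combinations_domain(self):
        with pytest.raises(ValueError):
            lm.count_combinations(-1, 2)
        with pytest.raises(ValueError):
            lm.count_combinations(53, -2)
        with pytest.raises(ValueError):
            lm.count_combinations(53)
        assert lm.count_combinations(5, 2) == 10
        assert lm.count_combinations(5, max_size=5) == 31
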