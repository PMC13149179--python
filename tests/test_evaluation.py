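"""Evaluation machinery: entropy reduction, hypotheses, metrics."""

import numpy as np
import pandas as pd
import pytest

from conftest import enumerate_joint

from periobn.evaluation import (
    HypothesisSpec,
    classifier_eval,
    entropy_reduction,
    expectation_analysis,
    mean_optimal_threshold,
    node_predictive_performance,
)
from periobn.network import Cpt, DagStructure, DiscreteBayesianNetwork, NodeSpec


def _pair_net(p_y_given_x):
    nodes = (NodeSpec("X", ("0", "1")), NodeSpec("Y", ("0", "1")))
    structure = DagStructure(nodes, (("X", "Y"),))
    states = {n.name: n.states for n in nodes}
    return DiscreteBayesianNetwork(
        structure,
        [
            Cpt("X", states["X"], (), {}, [0.5, 0.5]),
            Cpt("Y", states["Y"], ("X",), states, p_y_given_x),
        ],
    )


class TestEntropyReduction:
    def test_independent_input_gives_zero(self):
        net = _pair_net([[0.7, 0.3], [0.7, 0.3]])
        assert entropy_reduction(net, "Y", "X") == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_copy_gives_full_entropy(self):
        net = _pair_net([[1.0, 0.0], [0.0, 1.0]])
        assert entropy_reduction(net, "Y", "X") == pytest.approx(1.0, abs=1e-12)

    def test_equals_mutual_information_from_joint(self, chain_net):
        """Entropy reduction must equal the mutual information computed by
        joint enumeration, and be symmetric in its arguments."""
        order, joint = enumerate_joint(chain_net)
        ia, ic = order.index("A"), order.index("C")
        pxy = np.zeros((2, 2))
        for config, p in joint.items():
            pxy[config[ia], config[ic]] += p
        px, py = pxy.sum(1), pxy.sum(0)
        mi = sum(
            pxy[i, j] * np.log2(pxy[i, j] / (px[i] * py[j]))
            for i in range(2)
            for j in range(2)
            if pxy[i, j] > 0
        )
        assert entropy_reduction(chain_net, "C", "A") == pytest.approx(mi, abs=1e-10)
        assert entropy_reduction(chain_net, "A", "C") == pytest.approx(mi, abs=1e-10)

    def test_same_node_rejected(self, chain_net):
        with pytest.raises(Exception):
            entropy_reduction(chain_net, "A", "A")

    def test_nats_option(self, chain_net):
        bits = entropy_reduction(chain_net, "C", "A", base=2)
        nats = entropy_reduction(chain_net, "C", "A", base=np.e)
        assert nats == pytest.approx(bits * np.log(2), abs=1e-12)


class TestExpectationAnalysis:
    def test_monotone_ground_truth_age_hypothesis(self, gt_net):
        """The synthetic truth is built with a monotone age effect, so the
        age hypothesis must pass under both inference modes."""
        hyp = HypothesisSpec(
            description="periodontitis probability increases with age",
            target="Periodontitis",
            target_state="True",
            input_node="Age",
            states=("<6m", "2-3y", "6-7y", "10-11y", "13+y"),
        )
        report = expectation_analysis(gt_net, [hyp])
        assert report.passed(hyp.description, "probabilistic")
        assert report.passed(hyp.description, "causal")

    def test_isolated_node_fails_with_no_effect(self):
        nodes = (NodeSpec("X", ("0", "1")), NodeSpec("Y", ("0", "1")))
        structure = DagStructure(nodes, ())
        states = {n.name: n.states for n in nodes}
        net = DiscreteBayesianNetwork(
            structure,
            [
                Cpt("X", states["X"], (), {}, [0.5, 0.5]),
                Cpt("Y", states["Y"], (), {}, [0.6, 0.4]),
            ],
        )
        hyp = HypothesisSpec(
            description="y rises with x", target="Y", target_state="1",
            input_node="X", states=("0", "1"),
        )
        report = expectation_analysis(net, [hyp])
        assert not report.passed(hyp.description, "probabilistic")
        row = report.rows[0]
        assert row.jsd == 0.0 and row.label == "no effect"

    def test_report_shape_one_row_per_pair_and_mode(self, gt_net):
        hyp = HypothesisSpec(
            description="x", target="Periodontitis", target_state="True",
            input_node="Gingivitis", states=("False", "True"),
        )
        report = expectation_analysis(gt_net, [hyp])
        assert len(report.rows) == 2  # one state pair x two modes


class TestClassifierEval:
    def test_toy_confusion_matrix(self):
        scores, labels = (0.9, 0.8, 0.3, 0.1), (1, 1, 0, 0)
        rep = classifier_eval(scores, labels, threshold=0.5)
        d = rep.detail
        assert d["sensitivity"] == 1.0 and d["specificity"] == 1.0
        assert d["roc_auc"] == 1.0
        rep85 = classifier_eval(scores, labels, threshold=0.85)
        assert rep85.detail["sensitivity"] == 0.5

    def test_flipped_scores_auc_zero(self):
        rep = classifier_eval((0.1, 0.2, 0.8, 0.9), (1, 1, 0, 0), 0.5)
        assert rep.detail["roc_auc"] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            classifier_eval((0.1, 0.9), (1, 1), 0.5)

    def test_balanced_accuracy_invariant_to_prevalence(self, rng):
        """Resampling the positives changes prevalence but not per-class
        error rates, so balanced accuracy must not move."""
        n = 4000
        labels = (rng.random(n) < 0.5).astype(int)
        scores = np.clip(
            0.35 * labels + 0.3 + 0.25 * rng.random(n), 0, 1
        )
        base = classifier_eval(scores, labels, 0.5).detail
        pos = np.flatnonzero(labels == 1)
        keep = np.concatenate(
            [np.flatnonzero(labels == 0), rng.choice(pos, size=len(pos) // 4)]
        )
        shifted = classifier_eval(scores[keep], labels[keep], 0.5).detail
        assert shifted["balanced_accuracy"] == pytest.approx(
            base["balanced_accuracy"], abs=0.03
        )


class TestMeanOptimalThreshold:
    def test_identical_datasets(self):
        scores, labels = (0.1, 0.2, 0.8, 0.9), (0, 0, 1, 1)
        t = mean_optimal_threshold([(scores, labels)] * 3)
        assert t == mean_optimal_threshold([(scores, labels)])

    def test_separable_gap_midpoint(self):
        t = mean_optimal_threshold([((0.1, 0.3, 0.7, 0.9), (0, 0, 1, 1))])
        assert t == pytest.approx(0.5)

    def test_constructed_cutoffs_average(self):
        ds1 = ((0.1, 0.19, 0.21, 0.4), (0, 0, 1, 1))  # optimal 0.2
        ds2 = ((0.2, 0.39, 0.41, 0.6), (0, 0, 1, 1))  # optimal 0.4
        assert mean_optimal_threshold([ds1, ds2]) == pytest.approx(0.3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_optimal_threshold([])


class TestNodePredictivePerformance:
    def test_deterministic_ranked_child_is_perfect(self, rng):
        from periobn.params import RankedNodeSpec, ranked_cpt

        spec = RankedNodeSpec(
            node="R", node_states=("Bad", "Medium", "Good"),
            parents=("P",), parent_states={"P": ("Bad", "Medium", "Good")},
            parent_weights={"P": 1.0},
            parent_scores={"P": {"Bad": 0.0, "Medium": 0.5, "Good": 1.0}},
            thresholds=(0.25, 0.75),
        )
        nodes = (
            NodeSpec("P", ("Bad", "Medium", "Good"), "ranked"),
            NodeSpec("R", ("Bad", "Medium", "Good"), "ranked"),
        )
        structure = DagStructure(nodes, (("P", "R"),))
        net = DiscreteBayesianNetwork(
            structure,
            [
                Cpt("P", nodes[0].states, (), {}, [1 / 3] * 3),
                ranked_cpt(spec),
            ],
        )
        p = rng.choice(["Bad", "Medium", "Good"], 300)
        cohort = pd.DataFrame({"P": p, "R": p})
        reports = {
            r.metric: r.value for r in node_predictive_performance(net, cohort)
        }
        assert reports["ordinal_mad"] == 0.0
        assert reports["balanced_accuracy"] == 1.0

    def test_independent_child_auc_near_half(self, rng):
        net = _pair_net([[0.5, 0.5], [0.5, 0.5]])
        cohort = pd.DataFrame(
            {
                "X": rng.choice(["0", "1"], 10_000),
                "Y": rng.choice(["0", "1"], 10_000),
            }
        )
        reports = {
            r.metric: r.value for r in node_predictive_performance(net, cohort)
        }
        assert reports["roc_auc"] == pytest.approx(0.5, abs=0.02)

    def test_perfect_binary_predictor(self):
        net = _pair_net([[0.999, 0.001], [0.001, 0.999]])
        cohort = pd.DataFrame({"X": ["0", "1"] * 50, "Y": ["0", "1"] * 50})
        reports = {
            r.metric: r.value for r in node_predictive_performance(net, cohort)
        }
        assert reports["roc_auc"] == 1.0
        assert reports["balanced_accuracy"] == 1.0

    def test_no_rows_skipped_with_reason(self):
        net = _pair_net([[0.5, 0.5], [0.5, 0.5]])
        cohort = pd.DataFrame({"X": ["", ""], "Y": ["0", "1"]})
        reports = node_predictive_performance(net, cohort)
        assert reports[0].metric == "skipped"
        assert "no complete rows" in reports[0].detail["reason"]
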