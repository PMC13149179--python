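"""Model evaluation: node-level prediction, sensitivity and classification.

Four components mirror how the periodontal network was assessed:

* per-node predictive performance — how well each node's parents predict
  it on held-out records, scored by node class (binary: balanced accuracy
  and ROC AUC; multiclass: balanced accuracy and one-vs-one AUC; ordinal:
  mean absolute distance from the true level);
* outcome certainty — the posterior probability certainty index (PPCI,
  :func:`periobn.inference.ppci`) averaged over a dataset;
* sensitivity — entropy reduction (mutual information between an input and
  the outcome, in bits by default) and expectation analysis against
  predefined monotone hypotheses, with Jensen-Shannon effect sizes;
* overall classifier performance at a probability threshold, including the
  mean-optimal-threshold (Youden's J) selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, roc_auc_score, roc_curve

from .inference import (
    Distribution,
    effect_label,
    jsd,
    query,
    query_probabilistic,
)
from .network import DiscreteBayesianNetwork, MISSING, NetworkError

__all__ = [
    "HypothesisSpec",
    "MetricReport",
    "entropy_reduction",
    "expectation_analysis",
    "node_predictive_performance",
    "classifier_eval",
    "mean_optimal_threshold",
]


@dataclass(frozen=True)
class HypothesisSpec:
    """A predefined domain expectation, e.g. risk should rise with age.

    ``states`` lists the input node's states in the order along which the
    probability of ``target_state`` is expected to move in ``direction``.
    """

    description: str
    target: str
    target_state: str
    input_node: str
    states: tuple[str, ...]
    direction: str = "increase"
    modes: tuple[str, ...] = ("probabilistic", "causal")

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")


@dataclass(frozen=True)
class MetricReport:
    subject: str
    metric: str
    value: float
    support: int = 0
    detail: dict = field(default_factory=dict)


def entropy_reduction(
    net: DiscreteBayesianNetwork, target: str, input_node: str, base: float = 2.0
) -> float:
    """Expected decrease in outcome entropy from observing one input.

    ``H(target) - Σ_x P(x) H(target | x)`` — the mutual information between
    input and target, computed by exact inference. Bits by default.
    """
    if target == input_node:
        raise NetworkError("target and input must differ")
    log = lambda v: np.log(v) / np.log(base)
    ent = lambda p: float(-(p[p > 0] * log(p[p > 0])).sum())
    p_target = np.asarray(query_probabilistic(net, target).probabilities)
    p_input = np.asarray(query_probabilistic(net, input_node).probabilities)
    h = ent(p_target)
    for state, px in zip(net.states(input_node), p_input):
        if px == 0:
            continue
        cond = np.asarray(
            query_probabilistic(net, target, {input_node: state}).probabilities
        )
        h -= px * ent(cond)
    return max(h, 0.0)


@dataclass(frozen=True)
class ExpectationRow:
    hypothesis: str
    mode: str
    state_pair: tuple[str, str]
    p_from: float
    p_to: float
    satisfied: bool
    jsd: float
    label: str


@dataclass(frozen=True)
class ExpectationReport:
    rows: tuple[ExpectationRow, ...]

    @property
    def n_pass(self) -> int:
        by_hm = {}
        for r in self.rows:
            key = (r.hypothesis, r.mode)
            by_hm[key] = by_hm.get(key, True) and r.satisfied
        return sum(by_hm.values())

    def passed(self, hypothesis: str, mode: str) -> bool:
        rows = [
            r for r in self.rows if r.hypothesis == hypothesis and r.mode == mode
        ]
        return bool(rows) and all(r.satisfied for r in rows)


def expectation_analysis(
    net: DiscreteBayesianNetwork, hypotheses: Sequence[HypothesisSpec]
) -> ExpectationReport:
    """Evaluate monotone hypotheses under both inference modes.

    For each hypothesis, mode and consecutive state pair, records whether
    the target-state probability moved in the expected direction and the
    Jensen-Shannon effect size of the comparison.
    """
    rows: list[ExpectationRow] = []
    for hyp in hypotheses:
        for mode in hyp.modes:
            dists: list[Distribution] = [
                query(net, hyp.target, {hyp.input_node: s}, mode=mode)
                for s in hyp.states
            ]
            for (s1, d1), (s2, d2) in zip(
                zip(hyp.states, dists), zip(hyp.states[1:], dists[1:])
            ):
                p1, p2 = d1[hyp.target_state], d2[hyp.target_state]
                ok = p2 > p1 if hyp.direction == "increase" else p2 < p1
                value = jsd(d1, d2)
                rows.append(
                    ExpectationRow(
                        hyp.description, mode, (s1, s2), p1, p2, ok, value,
                        effect_label(value),
                    )
                )
    return ExpectationReport(tuple(rows))


def node_predictive_performance(
    net: DiscreteBayesianNetwork,
    cohort: pd.DataFrame,
    nodes: Sequence[str] | None = None,
) -> list[MetricReport]:
    """Score how well each node's parents predict it on a cohort.

    Only nodes with parents and complete parent-child rows are evaluated;
    prediction is the exact conditional distribution given the observed
    parents. Metrics depend on node class: binary nodes get balanced
    accuracy and ROC AUC, multiclass nodes balanced accuracy and unweighted
    one-vs-one AUC, ordinal (ranked) nodes mean absolute distance between
    predicted and true level.
    """
    reports: list[MetricReport] = []
    targets = nodes if nodes is not None else net.node_names
    for node in targets:
        parents = net.parents(node)
        if not parents:
            continue
        cols = [*parents, node]
        if any(c not in cohort.columns for c in cols):
            reports.append(
                MetricReport(node, "skipped", np.nan,
                             detail={"reason": "columns missing"}))
            continue
        df = cohort[cols].mask(cohort[cols] == MISSING).dropna()
        if len(df) == 0:
            reports.append(
                MetricReport(node, "skipped", np.nan,
                             detail={"reason": "no complete rows"}))
            continue
        cpt = net.cpts[node]
        states = list(net.states(node))
        # conditioning on all parents reduces exact inference to a CPT row
        idx = tuple(
            pd.Categorical(df[p], categories=list(net.states(p))).codes
            for p in cpt.parents
        )
        probs = cpt.values[idx]
        y_true = pd.Categorical(df[node], categories=states).codes
        y_pred = probs.argmax(axis=1)
        klass = net.structure.spec(node).node_class
        n = len(df)
        if klass == "ranked":
            mad = float(np.abs(y_pred - y_true).mean())
            reports.append(MetricReport(node, "ordinal_mad", mad, n))
            reports.append(
                MetricReport(
                    node, "balanced_accuracy",
                    float(balanced_accuracy_score(y_true, y_pred)), n))
            continue
        reports.append(
            MetricReport(
                node, "balanced_accuracy",
                float(balanced_accuracy_score(y_true, y_pred)), n))
        observed = np.unique(y_true)
        if len(observed) < 2:
            reports.append(
                MetricReport(node, "roc_auc", np.nan, n,
                             detail={"reason": "single observed class"}))
            continue
        if klass == "binary" or len(observed) == 2:
            pos = 1 if klass == "binary" else int(observed[1])
            auc = float(roc_auc_score((y_true == pos).astype(int), probs[:, pos]))
        else:
            keep = np.isin(np.arange(len(states)), observed)
            p_obs = probs[:, keep]
            p_obs = p_obs / p_obs.sum(axis=1, keepdims=True)
            remap = {c: i for i, c in enumerate(observed)}
            auc = float(
                roc_auc_score(
                    np.vectorize(remap.get)(y_true), p_obs,
                    multi_class="ovo", average="macro",
                    labels=list(range(len(observed))),
                )
            )
        reports.append(MetricReport(node, "roc_auc", auc, n))
    return reports


def classifier_eval(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
) -> MetricReport:
    """Binary classification metrics at a probability threshold.

    Returns sensitivity, specificity, balanced accuracy, ROC AUC and the
    confusion matrix in ``detail``.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return MetricReport(
        "classifier",
        "summary",
        float((sens + spec) / 2.0),
        support=len(y),
        detail={
            "threshold": float(threshold),
            "sensitivity": float(sens),
            "specificity": float(spec),
            "balanced_accuracy": float((sens + spec) / 2.0),
            "roc_auc": float(roc_auc_score(y, s)),
            "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        },
    )


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Youden-J-maximizing threshold; ties broken at the midpoint.

    Candidates are midpoints between consecutive distinct scores (plus the
    extremes), so a separable dataset yields the centre of the separating
    gap.
    """
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 0.5], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 0.5]]
    )
    pos, neg = labels == 1, labels == 0
    best_j, best_ts = -np.inf, []
    for t in candidates:
        tpr = float((scores[pos] >= t).mean())
        fpr = float((scores[neg] >= t).mean())
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_ts = j, [t]
        elif abs(j - best_j) <= 1e-12:
            best_ts.append(t)
    return float((best_ts[0] + best_ts[-1]) / 2.0)


def mean_optimal_threshold(
    datasets: Sequence[tuple[Sequence[float], Sequence[int]]]
) -> float:
    """Mean over datasets of the per-dataset Youden-optimal threshold."""
    if not datasets:
        raise ValueError("no datasets supplied")
    thresholds = []
    for scores, labels in datasets:
        s = np.asarray(scores, float)
        y = np.asarray(labels, int)
        if len(np.unique(y)) < 2:
            raise ValueError("each dataset needs both classes")
        thresholds.append(_youden_threshold(s, y))
    return float(np.mean(thresholds))
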