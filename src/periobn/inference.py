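"""Exact inference: probabilistic and interventional queries, effect sizes.

Probabilistic queries condition on evidence and run variable elimination
(min-fill ordering; exact, so the ordering only affects speed). Causal
queries implement Pearl's do-operator by truncated factorization: the CPTs
of intervened nodes are removed, their values fixed, and elimination runs on
the mutilated model. Effect sizes between two outcome distributions are
reported as the Jensen-Shannon distance (square root of the natural-log
Jensen-Shannon divergence, bounded by sqrt(ln 2) ~ 0.8326) with qualitative
labels at fixed thresholds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

from .network import DiscreteBayesianNetwork, NetworkError

__all__ = [
    "Distribution",
    "EffectReport",
    "ZeroEvidenceError",
    "query_probabilistic",
    "query_causal",
    "query",
    "jsd",
    "effect_label",
    "effect_report",
    "ppci",
    "JSD_MAX",
]

JSD_MAX = float(np.sqrt(np.log(2.0)))

#: (threshold, label) pairs; a value strictly above the threshold earns the
#: label, zero is "no effect".
EFFECT_THRESHOLDS = (
    (0.2, "very strong"),
    (0.1, "strong"),
    (0.05, "moderate"),
    (0.0, "weak"),
)


class ZeroEvidenceError(NetworkError):
    """The supplied evidence has probability zero under the model."""


@dataclass(frozen=True)
class Distribution:
    """A probability vector over one node's ordered states."""

    node: str
    states: tuple[str, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if len(p) != len(self.states):
            raise NetworkError("probability vector length != state count")
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise NetworkError("invalid probability vector")
        object.__setattr__(self, "probabilities", tuple(float(v) for v in p))

    def __getitem__(self, state: str) -> float:
        return self.probabilities[self.states.index(state)]

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.states, self.probabilities))


@dataclass(frozen=True)
class EffectReport:
    """Pairwise effect size between a baseline and a comparison query."""

    baseline: Distribution
    comparison: Distribution
    jsd: float
    label: str


# ---------------------------------------------------------------------------
# Factors


class _Factor:
    """A non-negative table over a tuple of variables (one axis each)."""

    __slots__ = ("vars", "values")

    def __init__(self, vars: tuple[str, ...], values: np.ndarray) -> None:
        self.vars = vars
        self.values = values

    def restrict(self, var: str, index: int) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            self.vars[:axis] + self.vars[axis + 1 :],
            np.take(self.values, index, axis=axis),
        )

    def sum_out(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            self.vars[:axis] + self.vars[axis + 1 :], self.values.sum(axis=axis)
        )


def _multiply(factors: Sequence[_Factor]) -> _Factor:
    out_vars: list[str] = []
    for f in factors:
        for v in f.vars:
            if v not in out_vars:
                out_vars.append(v)
    out_vars_t = tuple(out_vars)
    result = None
    for f in factors:
        # transpose axes into union order, then insert singleton axes to
        # broadcast over variables this factor does not mention
        order = sorted(range(len(f.vars)), key=lambda i: out_vars_t.index(f.vars[i]))
        vals = np.transpose(f.values, order)
        ordered_vars = [f.vars[i] for i in order]
        shape = [
            vals.shape[ordered_vars.index(v)] if v in f.vars else 1
            for v in out_vars_t
        ]
        vals = vals.reshape(shape)
        result = vals if result is None else result * vals
    return _Factor(out_vars_t, result if result is not None else np.array(1.0))


def _min_fill_order(
    factors: Sequence[_Factor], eliminate: Iterable[str]
) -> list[str]:
    """Greedy min-fill elimination ordering (performance heuristic only)."""
    neighbors: dict[str, set[str]] = {}
    for f in factors:
        for v in f.vars:
            neighbors.setdefault(v, set()).update(set(f.vars) - {v})
    remaining = [v for v in eliminate if v in neighbors]
    order: list[str] = []
    remaining_set = set(remaining)
    while remaining_set:
        best, best_fill = None, None
        for v in sorted(remaining_set):
            nb = neighbors[v] & set(neighbors)
            fill = sum(
                1
                for a, b in itertools.combinations(sorted(nb), 2)
                if b not in neighbors[a]
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        nb = neighbors[best]
        for a in nb:
            neighbors[a].update(nb - {a})
            neighbors[a].discard(best)
        del neighbors[best]
        order.append(best)
        remaining_set.discard(best)
    return order


def _eliminate(
    factors: list[_Factor], hidden: Iterable[str], elimination_order=None
) -> _Factor:
    order = (
        list(elimination_order)
        if elimination_order is not None
        else _min_fill_order(factors, hidden)
    )
    hidden_set = set(hidden)
    assert set(order) <= hidden_set
    # variables appearing in no factor simply drop out
    for var in order:
        involved = [f for f in factors if var in f.vars]
        if not involved:
            continue
        factors = [f for f in factors if var not in f.vars]
        factors.append(_multiply(involved).sum_out(var))
    return _multiply(factors)


# ---------------------------------------------------------------------------
# Queries


def _state_index(net: DiscreteBayesianNetwork, node: str, state: str) -> int:
    states = net.states(node)
    try:
        return states.index(str(state))
    except ValueError:
        raise NetworkError(
            f"{state!r} is not a state of {node!r} (states: {states})"
        ) from None


def _check_query(net, target, given: Mapping[str, str]) -> dict[str, int]:
    if target not in net.node_names:
        raise NetworkError(f"unknown target node {target!r}")
    if target in given:
        raise NetworkError(f"target {target!r} appears in evidence/interventions")
    return {n: _state_index(net, n, s) for n, s in given.items()}


def query_probabilistic(
    net: DiscreteBayesianNetwork,
    target: str,
    evidence: Mapping[str, str] | None = None,
    elimination_order: Sequence[str] | None = None,
) -> Distribution:
    """Exact conditional distribution P(target | evidence)."""
    evidence = dict(evidence or {})
    ev_idx = _check_query(net, target, evidence)
    factors = []
    for name in net.node_names:
        cpt = net.cpts[name]
        f = _Factor(cpt.parents + (name,), cpt.values)
        for var, idx in ev_idx.items():
            if var in f.vars:
                f = f.restrict(var, idx)
        factors.append(f)
    hidden = [
        n for n in net.node_names if n != target and n not in evidence
    ]
    if elimination_order is not None:
        elimination_order = [v for v in elimination_order if v in hidden]
    result = _eliminate(factors, hidden, elimination_order)
    values = result.values
    if result.vars != (target,):
        values = np.transpose(values, [result.vars.index(target)])
    total = float(values.sum())
    if total <= 0.0:
        raise ZeroEvidenceError(
            f"evidence {evidence} has probability zero under the model"
        )
    return Distribution(target, net.states(target), tuple(values / total))


def query_causal(
    net: DiscreteBayesianNetwork,
    target: str,
    interventions: Mapping[str, str],
    elimination_order: Sequence[str] | None = None,
) -> Distribution:
    """P(target | do(interventions)) by truncated factorization.

    Edges into intervened nodes are severed (their CPT factors dropped) and
    their values fixed throughout the remaining factors.
    """
    interventions = dict(interventions)
    iv_idx = _check_query(net, target, interventions)
    factors = []
    for name in net.node_names:
        if name in interventions:
            continue  # mutilation: drop the intervened node's own mechanism
        cpt = net.cpts[name]
        f = _Factor(cpt.parents + (name,), cpt.values)
        for var, idx in iv_idx.items():
            if var in f.vars:
                f = f.restrict(var, idx)
        factors.append(f)
    hidden = [
        n for n in net.node_names if n != target and n not in interventions
    ]
    if elimination_order is not None:
        elimination_order = [v for v in elimination_order if v in hidden]
    result = _eliminate(factors, hidden, elimination_order)
    values = result.values
    total = float(values.sum())
    if total <= 0.0:
        raise ZeroEvidenceError(
            f"interventions {interventions} give a zero-mass truncated model"
        )
    return Distribution(target, net.states(target), tuple(values / total))


def query(
    net: DiscreteBayesianNetwork,
    target: str,
    given: Mapping[str, str] | None = None,
    mode: str = "probabilistic",
) -> Distribution:
    """Dispatch on mode: ``probabilistic`` (evidence) or ``causal`` (do)."""
    if mode == "probabilistic":
        return query_probabilistic(net, target, given)
    if mode == "causal":
        return query_causal(net, target, given or {})
    raise NetworkError(f"unknown query mode {mode!r}")


# ---------------------------------------------------------------------------
# Effect size and certainty


def jsd(p: Distribution | Sequence[float], q: Distribution | Sequence[float]) -> float:
    """Jensen-Shannon distance between two distributions.

    Square root of ``0.5 KL(p||m) + 0.5 KL(q||m)`` with ``m = (p+q)/2``,
    natural logarithm, ``0 log 0 = 0``. Ranges over [0, sqrt(ln 2)].
    """
    pv = np.asarray(p.probabilities if isinstance(p, Distribution) else p, float)
    qv = np.asarray(q.probabilities if isinstance(q, Distribution) else q, float)
    if pv.shape != qv.shape:
        raise NetworkError("jsd: dimension mismatch")
    value = float(jensenshannon(pv, qv))  # scipy default base: natural log
    return 0.0 if np.isnan(value) else value


def effect_label(jsd_value: float) -> str:
    """Qualitative effect-size label for a Jensen-Shannon distance."""
    if jsd_value < 0:
        raise ValueError("negative effect size")
    if jsd_value == 0:
        return "no effect"
    for threshold, label in EFFECT_THRESHOLDS:
        if jsd_value > threshold:
            return label
    return "no effect"  # pragma: no cover - unreachable for positive input


def effect_report(baseline: Distribution, comparison: Distribution) -> EffectReport:
    value = jsd(baseline, comparison)
    return EffectReport(baseline, comparison, value, effect_label(value))


def ppci(posteriors: Sequence[Distribution | Sequence[float]]) -> float:
    """Posterior probability certainty index.

    Per case: ``(max_s P(s) - 1/k) / (1 - 1/k)`` — 0 for a uniform
    posterior, 1 for a point mass. The dataset value is the mean over cases.
    """
    if len(posteriors) == 0:
        raise ValueError("ppci: empty posterior list")
    vals = []
    for p in posteriors:
        v = np.asarray(
            p.probabilities if isinstance(p, Distribution) else p, float
        )
        k = len(v)
        vals.append((float(v.max()) - 1.0 / k) / (1.0 - 1.0 / k))
    return float(np.mean(vals))
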