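"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's inference machinery:
joint distributions are built by explicit enumeration over all state
configurations and conditioned/intervened on by direct summation, so they
can serve as ground truth for variable elimination and do-queries.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from periobn.network import Cpt, DagStructure, DiscreteBayesianNetwork, NodeSpec


# ---------------------------------------------------------------------------
# Brute-force oracles


def enumerate_joint(net: DiscreteBayesianNetwork) -> tuple[list, dict]:
    """Full joint by explicit enumeration: {config tuple: probability}."""
    order = list(net.node_names)
    states = {n: net.states(n) for n in order}
    joint = {}
    for config in itertools.product(*[range(len(states[n])) for n in order]):
        assign = dict(zip(order, config))
        p = 1.0
        for n in order:
            cpt = net.cpts[n]
            idx = tuple(assign[q] for q in cpt.parents) + (assign[n],)
            p *= float(cpt.values[idx])
        joint[config] = p
    return order, joint


def oracle_conditional(net, target, evidence):
    """P(target | evidence) by summing the enumerated joint."""
    order, joint = enumerate_joint(net)
    t = order.index(target)
    ev_idx = {
        order.index(n): net.states(n).index(s) for n, s in evidence.items()
    }
    out = np.zeros(len(net.states(target)))
    for config, p in joint.items():
        if all(config[i] == v for i, v in ev_idx.items()):
            out[config[t]] += p
    total = out.sum()
    return out / total if total > 0 else out


def oracle_do(net, target, interventions):
    """P(target | do(...)) by truncated-factorization enumeration."""
    order = list(net.node_names)
    states = {n: net.states(n) for n in order}
    iv = {n: net.states(n).index(s) for n, s in interventions.items()}
    t = order.index(target)
    out = np.zeros(len(states[target]))
    for config in itertools.product(*[range(len(states[n])) for n in order]):
        assign = dict(zip(order, config))
        if any(assign[n] != v for n, v in iv.items()):
            continue
        p = 1.0
        for n in order:
            if n in iv:
                continue  # intervened mechanisms are removed
            cpt = net.cpts[n]
            idx = tuple(assign[q] for q in cpt.parents) + (assign[n],)
            p *= float(cpt.values[idx])
        out[config[t]] += p
    return out / out.sum()


def oracle_conditional_independent(net, x, y, given, tol=1e-10):
    """Numeric CI check X ⟂ Y | Z on an enumerated joint."""
    order, joint = enumerate_joint(net)
    xi, yi = order.index(x), order.index(y)
    zi = [order.index(z) for z in given]
    cards = [len(net.states(n)) for n in order]
    for zvals in itertools.product(*[range(cards[i]) for i in zi]):
        sel = {i: v for i, v in zip(zi, zvals)}
        table = np.zeros((cards[xi], cards[yi]))
        for config, p in joint.items():
            if all(config[i] == v for i, v in sel.items()):
                table[config[xi], config[yi]] += p
        total = table.sum()
        if total < tol:
            continue
        table /= total
        expected = np.outer(table.sum(1), table.sum(0))
        if np.abs(table - expected).max() > tol:
            return False
    return True


def random_network(
    rng: np.random.Generator, n_nodes: int = 5, edge_prob: float = 0.4,
    max_card: int = 3,
) -> DiscreteBayesianNetwork:
    """A random parameterized DAG (edges respect a random node order)."""
    names = [f"N{i}" for i in range(n_nodes)]
    order = list(rng.permutation(names))
    cards = {n: int(rng.integers(2, max_card + 1)) for n in names}
    edges = [
        (order[i], order[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < edge_prob
    ]
    nodes = tuple(
        NodeSpec(n, tuple(f"s{k}" for k in range(cards[n]))) for n in names
    )
    structure = DagStructure(nodes, tuple(edges))
    states = {n.name: n.states for n in nodes}
    cpts = []
    for n in names:
        parents = structure.parents(n)
        shape = tuple(cards[p] for p in parents) + (cards[n],)
        values = rng.dirichlet(np.ones(cards[n]) * 2.0, size=shape[:-1])
        cpts.append(Cpt(n, states[n], parents, states, values.reshape(shape)))
    return DiscreteBayesianNetwork(structure, cpts)


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def gt_net():
    """Session ground-truth periodontal network (fixed seed)."""
    from periobn.simulate import make_ground_truth

    return make_ground_truth(seed=11)


@pytest.fixture(scope="session")
def gt_cohort_20k(gt_net):
    from periobn.simulate import sample_cohort

    return sample_cohort(gt_net, 20_000, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def chain_net():
    """A -> B -> C with hand-set CPTs (binary)."""
    nodes = (
        NodeSpec("A", ("a0", "a1")),
        NodeSpec("B", ("b0", "b1")),
        NodeSpec("C", ("c0", "c1")),
    )
    structure = DagStructure(nodes, (("A", "B"), ("B", "C")))
    states = {n.name: n.states for n in nodes}
    cpts = [
        Cpt("A", states["A"], (), {}, [0.3, 0.7]),
        Cpt("B", states["B"], ("A",), states, [[0.9, 0.1], [0.2, 0.8]]),
        Cpt("C", states["C"], ("B",), states, [[0.6, 0.4], [0.25, 0.75]]),
    ]
    return DiscreteBayesianNetwork(structure, cpts)


@pytest.fixture()
def confounder_net():
    """C -> X, C -> Y, X -> Y: the smallest back-door situation."""
    nodes = (
        NodeSpec("C", ("c0", "c1")),
        NodeSpec("X", ("x0", "x1")),
        NodeSpec("Y", ("y0", "y1")),
    )
    structure = DagStructure(nodes, (("C", "X"), ("C", "Y"), ("X", "Y")))
    states = {n.name: n.states for n in nodes}
    cpts = [
        Cpt("C", states["C"], (), {}, [0.4, 0.6]),
        Cpt("X", states["X"], ("C",), states, [[0.8, 0.2], [0.3, 0.7]]),
        Cpt(
            "Y", states["Y"], ("C", "X"), states,
            [[[0.9, 0.1], [0.5, 0.5]], [[0.6, 0.4], [0.15, 0.85]]],
        ),
    ]
    return DiscreteBayesianNetwork(structure, cpts)
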