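"""Discrete Bayesian network representation.

A network is a directed acyclic graph over named nodes, each with a fixed,
ordered state space, plus one conditional probability table (CPT) per node.
State order is semantic: ranked (ordinal) nodes declare their states
worst-to-best (e.g. ``Bad < Medium < Good``) and every ordinal encoding and
ranked-node computation relies on that declared order.

CPT rows (one probability vector per full parent-state configuration) are
stored in row-major order of the declared parent list; internally a CPT is an
ndarray with one axis per parent followed by the node axis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "NodeSpec",
    "DagStructure",
    "Cpt",
    "DiscreteBayesianNetwork",
    "build_network",
    "d_separated",
    "implied_independencies",
    "MISSING",
    "NORMALIZATION_TOL",
]

#: Distinguished missing-value token used in cohort tables. Never a state.
MISSING = ""

#: Tolerance for CPT row normalization checks.
NORMALIZATION_TOL = 1e-9

NODE_CLASSES = ("categorical", "binary", "ranked")


class NetworkError(ValueError):
    """Raised for structurally invalid networks or CPTs."""


@dataclass(frozen=True)
class NodeSpec:
    """A node: name, ordered state labels and a class.

    ``node_class`` is one of ``categorical``, ``binary`` or ``ranked``.
    Ranked nodes are ordinal; their state order (worst to best unless
    documented otherwise) is part of the contract.
    """

    name: str
    states: tuple[str, ...]
    node_class: str = "categorical"
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        if len(self.states) < 2:
            raise NetworkError(f"node {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise NetworkError(f"node {self.name!r} has duplicate state labels")
        if self.node_class not in NODE_CLASSES:
            raise NetworkError(f"unknown node class {self.node_class!r}")
        if self.node_class == "binary" and len(self.states) != 2:
            raise NetworkError(f"binary node {self.name!r} must have 2 states")

    @property
    def cardinality(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class DagStructure:
    """A DAG over declared nodes.

    Edges are (parent, child) name pairs. Construction validates that every
    endpoint is declared, there are no duplicate edges or self-loops, and the
    graph is acyclic.
    """

    nodes: tuple[NodeSpec, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(
            self, "edges", tuple((str(p), str(c)) for p, c in self.edges)
        )
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise NetworkError("duplicate node names")
        declared = set(names)
        seen: set[tuple[str, str]] = set()
        for p, c in self.edges:
            if p not in declared or c not in declared:
                raise NetworkError(f"edge ({p}, {c}) references undeclared node")
            if p == c:
                raise NetworkError(f"self-loop on {p}")
            if (p, c) in seen:
                raise NetworkError(f"duplicate edge ({p}, {c})")
            seen.add((p, c))
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise NetworkError("graph contains a cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(n.name for n in self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    def spec(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def parents(self, name: str) -> tuple[str, ...]:
        """Parents of ``name`` in declaration order of the edge list."""
        self.spec(name)
        return tuple(p for p, c in self.edges if c == name)

    def children(self, name: str) -> tuple[str, ...]:
        self.spec(name)
        return tuple(c for p, c in self.edges if p == name)

    def topological_order(self) -> tuple[str, ...]:
        """Deterministic (lexicographic tie-break) topological order."""
        return tuple(nx.lexicographical_topological_sort(self.to_networkx()))

    @property
    def total_states(self) -> int:
        return sum(n.cardinality for n in self.nodes)


class Cpt:
    """Conditional probability table for one node.

    ``values`` has shape ``(*parent_cardinalities, node_cardinality)``; the
    flattened array enumerates parent configurations in row-major order of
    the declared parent list. Every row must be non-negative and sum to 1
    within ``NORMALIZATION_TOL`` unless ``renormalize=True`` is passed (used
    for printed tables carrying rounding slack, e.g. rows summing to 1.001);
    renormalized rows are recorded in :attr:`adjusted_rows`.
    """

    def __init__(
        self,
        node: str,
        node_states: Sequence[str],
        parents: Sequence[str],
        parent_states: Mapping[str, Sequence[str]],
        values: np.ndarray | Sequence,
        renormalize: bool = False,
    ) -> None:
        self.node = str(node)
        self.node_states = tuple(str(s) for s in node_states)
        self.parents = tuple(str(p) for p in parents)
        self.parent_states = {
            p: tuple(str(s) for s in parent_states[p]) for p in self.parents
        }
        shape = tuple(len(self.parent_states[p]) for p in self.parents) + (
            len(self.node_states),
        )
        arr = np.asarray(values, dtype=float)
        if arr.size != int(np.prod(shape)):
            raise NetworkError(
                f"CPT for {self.node!r}: got {arr.size} values, expected "
                f"{int(np.prod(shape))}"
            )
        arr = arr.reshape(shape)
        if np.any(arr < 0):
            raise NetworkError(f"CPT for {self.node!r} has negative entries")
        sums = arr.sum(axis=-1)
        off = np.abs(sums - 1.0) > NORMALIZATION_TOL
        self.adjusted_rows: list[tuple[str, ...]] = []
        if off.any():
            if not renormalize:
                raise NetworkError(
                    f"CPT for {self.node!r}: {int(off.sum())} row(s) not "
                    f"normalized (max |sum-1| = {np.abs(sums - 1).max():.3g})"
                )
            if np.any(sums <= 0):
                raise NetworkError(f"CPT for {self.node!r}: zero-mass row")
            for idx in np.argwhere(off):
                self.adjusted_rows.append(
                    tuple(
                        self.parent_states[p][i]
                        for p, i in zip(self.parents, idx)
                    )
                )
            arr = arr / sums[..., None]
        self.values = arr

    @property
    def n_parameters(self) -> int:
        return self.values.size

    def parent_configurations(self) -> Iterable[tuple[str, ...]]:
        """All parent configurations in row-major order."""
        pools = [self.parent_states[p] for p in self.parents]
        return itertools.product(*pools)

    def _config_index(self, config: Mapping[str, str]) -> tuple[int, ...]:
        try:
            return tuple(
                self.parent_states[p].index(str(config[p])) for p in self.parents
            )
        except (KeyError, ValueError) as exc:
            raise NetworkError(
                f"bad parent configuration for {self.node!r}: {config}"
            ) from exc

    def row(self, config: Mapping[str, str] | None = None) -> np.ndarray:
        """Probability vector over the node's states for one configuration."""
        if not self.parents:
            return self.values.reshape(-1).copy()
        assert config is not None, "parent configuration required"
        return self.values[self._config_index(config)].copy()

    def flat(self) -> np.ndarray:
        """Row-major flattened probabilities (serialization order)."""
        return self.values.reshape(-1).copy()

    def signature(self) -> tuple:
        return (
            self.node,
            self.node_states,
            self.parents,
            tuple(self.parent_states[p] for p in self.parents),
        )

    def copy_with(self, values: np.ndarray, renormalize: bool = False) -> "Cpt":
        return Cpt(
            self.node,
            self.node_states,
            self.parents,
            self.parent_states,
            values,
            renormalize=renormalize,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Cpt({self.node!r}, parents={list(self.parents)}, "
            f"shape={self.values.shape})"
        )


class DiscreteBayesianNetwork:
    """A fully parameterized discrete Bayesian network."""

    def __init__(self, structure: DagStructure, cpts: Iterable[Cpt]) -> None:
        self.structure = structure
        self.cpts: dict[str, Cpt] = {}
        for cpt in cpts:
            if cpt.node in self.cpts:
                raise NetworkError(f"duplicate CPT for {cpt.node!r}")
            self.cpts[cpt.node] = cpt
        missing = set(structure.node_names) - set(self.cpts)
        if missing:
            raise NetworkError(f"missing CPTs for {sorted(missing)}")
        extra = set(self.cpts) - set(structure.node_names)
        if extra:
            raise NetworkError(f"CPTs for undeclared nodes {sorted(extra)}")
        for name in structure.node_names:
            cpt = self.cpts[name]
            spec = structure.spec(name)
            if cpt.node_states != spec.states:
                raise NetworkError(f"CPT state labels mismatch for {name!r}")
            if tuple(sorted(cpt.parents)) != tuple(
                sorted(structure.parents(name))
            ):
                raise NetworkError(
                    f"CPT parents {cpt.parents} != graph parents "
                    f"{structure.parents(name)} for {name!r}"
                )
            for p in cpt.parents:
                if cpt.parent_states[p] != structure.spec(p).states:
                    raise NetworkError(
                        f"CPT parent-state mismatch for {name!r} / {p!r}"
                    )

    @property
    def node_names(self) -> tuple[str, ...]:
        return self.structure.node_names

    def states(self, name: str) -> tuple[str, ...]:
        return self.structure.spec(name).states

    def parents(self, name: str) -> tuple[str, ...]:
        return self.structure.parents(name)

    @property
    def n_parameters(self) -> int:
        """Total conditional probabilities: sum over nodes of |states| x
        product of parent state counts."""
        return sum(c.n_parameters for c in self.cpts.values())

    def topological_order(self) -> tuple[str, ...]:
        return self.structure.topological_order()


def build_network(
    structure: DagStructure, cpts: Iterable[Cpt]
) -> DiscreteBayesianNetwork:
    """Assemble and validate a network from a structure and one CPT per node."""
    return DiscreteBayesianNetwork(structure, cpts)


def d_separated(
    net: DiscreteBayesianNetwork | DagStructure,
    x: str,
    y: str,
    given: Iterable[str] = (),
) -> bool:
    """Standard d-separation of ``x`` and ``y`` given a conditioning set."""
    structure = net.structure if isinstance(net, DiscreteBayesianNetwork) else net
    given = set(given)
    for name in {x, y} | given:
        structure.spec(name)  # raises KeyError on unknown node
    return nx.is_d_separator(structure.to_networkx(), {x}, {y}, given)


def implied_independencies(
    net: DiscreteBayesianNetwork | DagStructure,
) -> list[tuple[str, str, frozenset[str]]]:
    """A testable basis of conditional independencies implied by the DAG.

    For each non-adjacent pair, with ``y`` the later node in a deterministic
    topological order, returns ``(x, y, parents(y))``: since ``x`` is a
    non-descendant of ``y``, the local Markov property guarantees
    ``x ⟂ y | parents(y)``. Output order is deterministic (by topological
    index of ``y``, then of ``x``).
    """
    structure = net.structure if isinstance(net, DiscreteBayesianNetwork) else net
    order = structure.topological_order()
    rank = {n: i for i, n in enumerate(order)}
    adjacent = {frozenset(e) for e in structure.edges}
    out: list[tuple[str, str, frozenset[str]]] = []
    for j, y in enumerate(order):
        pa_y = frozenset(structure.parents(y))
        for x in order[:j]:
            if frozenset((x, y)) in adjacent or x in pa_y:
                continue
            out.append((x, y, pa_y))
    out.sort(key=lambda t: (rank[t[1]], rank[t[0]]))
    return out
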