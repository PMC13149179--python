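"""Hybrid CPT construction: priors, expert tables, data counts and fusion.

Each node's posterior CPT is assembled from up to three ingredients:

* a prior — uniform, expert-elicited, a data marginal, or a weighted
  composite of several of these;
* observed counts — possibly fused from several datasets with per-dataset
  weights, or corrected for known observation bias through an
  expert-supplied misclassification matrix;
* a prior-to-data weight ratio governing a Dirichlet-style pseudo-count
  update.

The "prior : dataset" ratio is scale-free: the prior contributes pseudo-mass
equal to ``ratio * (observed row total)`` in every parent-configuration row,
so a "1:10" ratio means the prior carries one eleventh of each row's
effective evidence regardless of how much data that row saw. Rows with no
observations fall back to the prior unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import Cpt, NetworkError

__all__ = [
    "WeightConfig",
    "CountTable",
    "RankedNodeSpec",
    "parse_ratio",
    "uniform_prior",
    "combine_expert_tables",
    "expand_coarse_cpt",
    "composite_prior",
    "fuse_dataset_counts",
    "posterior_cpt",
    "marginal_data_prior",
    "bias_resample",
    "ranked_cpt",
    "fit_network_from_cohort",
    "count_table_from_cohort",
]


def parse_ratio(text: str) -> tuple[float, ...]:
    """Parse a ratio string like ``"1:20"`` or ``"1.5:1"`` or ``"15:1:2"``."""
    parts = tuple(float(p) for p in str(text).split(":"))
    if len(parts) < 2 or any(p < 0 for p in parts) or sum(parts) == 0:
        raise ValueError(f"bad ratio {text!r}")
    return parts


@dataclass(frozen=True)
class WeightConfig:
    """Per-node weighting ratios for the three fusion stages.

    ``prior_components`` weights the components of a composite prior,
    ``datasets`` weights the datasets being fused, and ``prior_to_data``
    weights the (composite) prior against the (fused) data.
    """

    node: str
    prior_components: tuple[float, ...] | None = None
    datasets: tuple[float, ...] | None = None
    prior_to_data: tuple[float, float] | None = None

    @classmethod
    def from_strings(
        cls,
        node: str,
        prior_components: str | None = None,
        datasets: str | None = None,
        prior_to_data: str | None = None,
    ) -> "WeightConfig":
        ptd = None
        if prior_to_data:
            parts = parse_ratio(prior_to_data)
            if len(parts) != 2:
                raise ValueError("prior:data ratio must have two terms")
            ptd = (parts[0], parts[1])
        return cls(
            node=node,
            prior_components=parse_ratio(prior_components)
            if prior_components
            else None,
            datasets=parse_ratio(datasets) if datasets else None,
            prior_to_data=ptd,
        )


class CountTable:
    """Observed counts on the same configuration space as a target CPT."""

    def __init__(
        self,
        node: str,
        node_states: Sequence[str],
        parents: Sequence[str],
        parent_states: Mapping[str, Sequence[str]],
        counts: np.ndarray | Sequence,
        provenance: str = "",
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
        arr = np.asarray(counts, dtype=float).reshape(shape)
        if np.any(arr < 0):
            raise ValueError(f"negative counts for {self.node!r}")
        self.counts = arr
        self.provenance = provenance

    def signature(self) -> tuple:
        return (
            self.node,
            self.node_states,
            self.parents,
            tuple(self.parent_states[p] for p in self.parents),
        )

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class RankedNodeSpec:
    """Ranked-node synthesis: weighted parent scores cut at thresholds.

    ``thresholds`` are strictly ascending interior cut points partitioning
    the weighted-score range into as many intervals as the node has states
    (declared order). A score landing exactly on a threshold is assigned to
    the higher interval.
    """

    node: str
    node_states: tuple[str, ...]
    parents: tuple[str, ...]
    parent_states: Mapping[str, tuple[str, ...]]
    parent_weights: Mapping[str, float]
    parent_scores: Mapping[str, Mapping[str, float]]
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.node_states) - 1:
            raise ValueError(
                "need exactly one threshold between consecutive levels"
            )
        if any(
            b <= a for a, b in zip(self.thresholds, self.thresholds[1:])
        ):
            raise ValueError("thresholds must be strictly ascending")
        if any(self.parent_weights[p] < 0 for p in self.parents):
            raise ValueError("parent weights must be non-negative")


def _check_signatures(tables: Sequence) -> None:
    sig = tables[0].signature()
    for t in tables[1:]:
        if t.signature() != sig:
            raise NetworkError(
                f"signature mismatch: {t.signature()} vs {sig}"
            )


def uniform_prior(
    node: str,
    node_states: Sequence[str],
    parents: Sequence[str] = (),
    parent_states: Mapping[str, Sequence[str]] | None = None,
) -> Cpt:
    """Non-informative prior: every row is 1/k over the node's k states."""
    parent_states = parent_states or {}
    shape = tuple(len(parent_states[p]) for p in parents) + (len(node_states),)
    values = np.full(shape, 1.0 / len(node_states))
    return Cpt(node, node_states, parents, parent_states, values)


def combine_expert_tables(tables: Sequence[Cpt]) -> Cpt:
    """Element-wise mean of independent expert tables, rows renormalized."""
    if not tables:
        raise ValueError("no expert tables supplied")
    _check_signatures(tables)
    mean = np.mean([t.values for t in tables], axis=0)
    return tables[0].copy_with(mean, renormalize=True)


def composite_prior(components: Sequence[tuple[Cpt, float]]) -> Cpt:
    """Row-wise convex combination of prior components."""
    if not components:
        raise ValueError("no components supplied")
    tables = [c for c, _ in components]
    weights = np.asarray([w for _, w in components], float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("composite weights must be positive")
    _check_signatures(tables)
    weights = weights / weights.sum()
    values = sum(w * t.values for t, w in zip(tables, weights))
    return tables[0].copy_with(values, renormalize=True)


def expand_coarse_cpt(
    coarse: Cpt,
    fine_parent_states: Mapping[str, Sequence[str]],
    state_maps: Mapping[str, Mapping[str, str]],
    interpolate: Sequence[str] = (),
) -> Cpt:
    """Expand a CPT elicited on simplified parent categories to full states.

    ``state_maps[parent]`` sends each fine parent state to the coarse
    category used at elicitation (e.g. each breed to its low/expected/high
    risk group, each fine age bin to a life stage). By default each fine row
    inherits the row of its coarse category tuple (piecewise-constant).
    Parents listed in ``interpolate`` are treated as ordinal: each coarse
    category is placed at the mean index of its fine states and fine rows
    are linearly interpolated between the flanking category rows.
    """
    fine_parents = coarse.parents
    fine_states = {p: tuple(fine_parent_states[p]) for p in fine_parents}
    # per parent: for each fine state, (lower coarse idx, upper idx, weight)
    plans: dict[str, list[tuple[int, int, float]]] = {}
    for p in fine_parents:
        coarse_states = coarse.parent_states[p]
        mapping = state_maps.get(p)
        if mapping is None:
            if fine_states[p] != coarse_states:
                raise NetworkError(f"parent {p!r} needs a state map")
            plans[p] = [(i, i, 0.0) for i in range(len(coarse_states))]
            continue
        coarse_idx = []
        for s in fine_states[p]:
            if s not in mapping:
                raise NetworkError(f"fine state {s!r} of {p!r} unmapped")
            if mapping[s] not in coarse_states:
                raise NetworkError(
                    f"unknown coarse category {mapping[s]!r} for {p!r}"
                )
            coarse_idx.append(coarse_states.index(mapping[s]))
        if p not in interpolate:
            plans[p] = [(c, c, 0.0) for c in coarse_idx]
            continue
        # ordinal interpolation between coarse category centres
        centres = {}
        for c in set(coarse_idx):
            positions = [i for i, ci in enumerate(coarse_idx) if ci == c]
            centres[c] = float(np.mean(positions))
        anchor = sorted(centres.items(), key=lambda kv: kv[1])
        plan = []
        for i, _ in enumerate(fine_states[p]):
            lo = hi = None
            for c, pos in anchor:
                if pos <= i:
                    lo = (c, pos)
                if pos >= i and hi is None:
                    hi = (c, pos)
            if lo is None:
                plan.append((hi[0], hi[0], 0.0))
            elif hi is None:
                plan.append((lo[0], lo[0], 0.0))
            elif lo[0] == hi[0]:
                plan.append((lo[0], lo[0], 0.0))
            else:
                w = (i - lo[1]) / (hi[1] - lo[1])
                plan.append((lo[0], hi[0], float(w)))
        plans[p] = plan

    shape = tuple(len(fine_states[p]) for p in fine_parents) + (
        len(coarse.node_states),
    )
    values = np.zeros(shape)
    for idx in np.ndindex(shape[:-1]):
        # multilinear combination over per-parent (lo, hi, w) plans
        row = np.zeros(len(coarse.node_states))
        corners = [(1.0, ())]
        for p, i in zip(fine_parents, idx):
            lo, hi, w = plans[p][i]
            new = []
            for weight, coords in corners:
                if w == 0.0 or lo == hi:
                    new.append((weight, coords + (lo,)))
                else:
                    new.append((weight * (1 - w), coords + (lo,)))
                    new.append((weight * w, coords + (hi,)))
            corners = new
        for weight, coords in corners:
            row += weight * coarse.values[coords]
        values[idx] = row
    return Cpt(
        coarse.node, coarse.node_states, fine_parents, fine_states, values,
        renormalize=True,
    )


def fuse_dataset_counts(
    count_tables: Sequence[tuple[CountTable, float]]
) -> CountTable:
    """Weighted fusion of datasets on a shared configuration space.

    Each dataset is rescaled to carry a share of the combined total mass
    proportional to its weight: with normalized weights ``w_i`` and combined
    raw total ``T``, dataset ``i`` contributes ``w_i * T * p_i(cell)``.
    """
    if not count_tables:
        raise ValueError("no count tables supplied")
    tables = [t for t, _ in count_tables]
    weights = np.asarray([w for _, w in count_tables], float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("dataset weights must be positive")
    _check_signatures(tables)
    weights = weights / weights.sum()
    total = sum(t.total for t in tables)
    out = np.zeros_like(tables[0].counts)
    for t, w in zip(tables, weights):
        if t.total > 0:
            out += w * total * t.counts / t.total
    return CountTable(
        tables[0].node,
        tables[0].node_states,
        tables[0].parents,
        tables[0].parent_states,
        out,
        provenance="+".join(t.provenance for t in tables if t.provenance),
    )


def posterior_cpt(
    prior: Cpt,
    counts: CountTable,
    prior_to_data: tuple[float, float] = (1.0, 1.0),
) -> Cpt:
    """Dirichlet pseudo-count update of a prior with observed counts.

    Per parent-configuration row the prior is given total pseudo-mass
    ``(w_prior / w_data) * row_count_total`` and added to the observed
    counts; rows with no observations return the prior row unchanged. A
    zero data weight returns the prior for every row.
    """
    if prior.signature() != counts.signature():
        raise NetworkError("prior/counts signature mismatch")
    wp, wd = float(prior_to_data[0]), float(prior_to_data[1])
    if wp < 0 or wd < 0 or (wp == 0 and wd == 0):
        raise ValueError("prior:data weights must be non-negative, not both 0")
    if wd == 0:
        return prior.copy_with(prior.values.copy())
    row_totals = counts.counts.sum(axis=-1, keepdims=True)
    pseudo = prior.values * (wp / wd) * row_totals
    post = pseudo + counts.counts
    post_sums = post.sum(axis=-1, keepdims=True)
    empty = row_totals == 0
    values = np.where(
        empty, prior.values, post / np.where(post_sums == 0, 1.0, post_sums)
    )
    return prior.copy_with(values)


def marginal_data_prior(
    counts: CountTable,
    full_parents: Sequence[str],
    full_parent_states: Mapping[str, Sequence[str]],
) -> Cpt:
    """Broadcast counts observed on a parent subset over the full signature.

    Each full parent configuration's row is the normalized counts of its
    projection onto the observed subset; projected rows with no data fall
    back to uniform.
    """
    observed = set(counts.parents)
    if not observed <= set(full_parents):
        raise NetworkError("observed parents must be a subset of full parents")
    k = len(counts.node_states)
    full_parents = tuple(full_parents)
    full_states = {p: tuple(full_parent_states[p]) for p in full_parents}
    for p in counts.parents:
        if full_states[p] != counts.parent_states[p]:
            raise NetworkError(f"parent-state mismatch for {p!r}")
    shape = tuple(len(full_states[p]) for p in full_parents) + (k,)
    values = np.empty(shape)
    for idx in np.ndindex(shape[:-1]):
        config = dict(zip(full_parents, idx))
        sub = tuple(config[p] for p in counts.parents)
        row = counts.counts[sub] if counts.parents else counts.counts
        total = row.sum()
        values[idx] = row / total if total > 0 else np.full(k, 1.0 / k)
    return Cpt(counts.node, counts.node_states, full_parents, full_states, values)


def bias_resample(
    observed_counts: CountTable, inverse_conditional: Cpt
) -> CountTable:
    """Correct counts observed through a known misclassification process.

    ``inverse_conditional`` gives ``P(observed state | true state)`` for the
    node (a square misclassification matrix, rows indexed by true state).
    Per parent-configuration row the true counts solve ``M x = observed``
    where ``M[o, t] = P(o | t)``; negative solutions are clipped at zero and
    the row rescaled to its original total. Clip events are recorded on the
    returned table as ``clip_events`` (list of parent-index tuples).
    """
    if inverse_conditional.parents != (observed_counts.node,):
        raise NetworkError(
            "inverse conditional must condition on the true node state"
        )
    if inverse_conditional.node_states != observed_counts.node_states:
        raise NetworkError("misclassification state-space mismatch")
    m = inverse_conditional.values.T  # M[observed, true]
    if abs(np.linalg.det(m)) < 1e-12:
        raise np.linalg.LinAlgError("singular misclassification matrix")
    obs = observed_counts.counts
    flat = obs.reshape(-1, obs.shape[-1])
    corrected = np.empty_like(flat)
    clip_events: list[tuple[int, ...]] = []
    shape = obs.shape[:-1]
    for i, row in enumerate(flat):
        total = row.sum()
        if total == 0:
            corrected[i] = 0.0
            continue
        x = np.linalg.solve(m, row)
        if np.any(x < -1e-9):
            clip_events.append(tuple(np.unravel_index(i, shape)) if shape else ())
        x = np.clip(x, 0.0, None)
        s = x.sum()
        corrected[i] = x * (total / s) if s > 0 else row
    out = CountTable(
        observed_counts.node,
        observed_counts.node_states,
        observed_counts.parents,
        observed_counts.parent_states,
        corrected.reshape(obs.shape),
        provenance=observed_counts.provenance,
    )
    out.clip_events = clip_events
    return out


def ranked_cpt(spec: RankedNodeSpec, temperature: float | None = None) -> Cpt:
    """Synthesize an ordinal CPT from weighted parent scores.

    Each parent configuration's weighted score is mapped to the ordinal
    level whose interval contains it (boundary scores go to the higher
    level), giving a point-mass row. ``temperature > 0`` optionally softens
    the rows with weights ``exp(-|score - centre_level| / temperature)``
    over interval centres; the default is the hard categorization.
    """
    k = len(spec.node_states)
    cards = [len(spec.parent_states[p]) for p in spec.parents]
    # interval bounds from min/max attainable scores
    lo = sum(
        spec.parent_weights[p] * min(spec.parent_scores[p].values())
        for p in spec.parents
    )
    hi = sum(
        spec.parent_weights[p] * max(spec.parent_scores[p].values())
        for p in spec.parents
    )
    bounds = (lo,) + spec.thresholds + (hi,)
    if spec.thresholds and (spec.thresholds[0] < lo or spec.thresholds[-1] > hi):
        raise ValueError("thresholds fall outside the attainable score range")
    centres = [(bounds[i] + bounds[i + 1]) / 2 for i in range(k)]
    shape = tuple(cards) + (k,)
    values = np.zeros(shape)
    for idx in np.ndindex(*cards):
        score = sum(
            spec.parent_weights[p]
            * spec.parent_scores[p][spec.parent_states[p][i]]
            for p, i in zip(spec.parents, idx)
        )
        if score < lo - 1e-12 or score > hi + 1e-12:
            raise ValueError(f"score {score} outside [{lo}, {hi}]")
        # boundary scores (== threshold) assign to the higher level
        level = int(np.searchsorted(np.asarray(spec.thresholds), score, "right"))
        level = min(level, k - 1)
        if temperature and temperature > 0:
            w = np.exp(-np.abs(score - np.asarray(centres)) / temperature)
            values[idx] = w / w.sum()
        else:
            values[idx][level] = 1.0
    return Cpt(
        spec.node, spec.node_states, spec.parents, spec.parent_states, values
    )


def fit_network_from_cohort(
    structure,
    cohort,
    prior_to_data: tuple[float, float] = (1.0, 10.0),
    priors: Mapping[str, Cpt] | None = None,
    provenance: str = "",
):
    """Estimate every CPT of a structure from a complete-case cohort.

    Each node's counts are cross-tabulated from the cohort and combined
    with its prior (uniform unless supplied) through the pseudo-count
    update at the given prior:data ratio. Parent configurations never seen
    in the data keep the prior row.
    """
    from .network import DiscreteBayesianNetwork

    states = {n.name: n.states for n in structure.nodes}
    cpts = []
    for node in structure.node_names:
        parents = structure.parents(node)
        pstates = {p: states[p] for p in parents}
        prior = (
            priors[node]
            if priors and node in priors
            else uniform_prior(node, states[node], parents, pstates)
        )
        counts = count_table_from_cohort(
            cohort, node, states[node], parents, pstates, provenance
        )
        cpts.append(posterior_cpt(prior, counts, prior_to_data))
    return DiscreteBayesianNetwork(structure, cpts)


def count_table_from_cohort(
    cohort,
    node: str,
    node_states: Sequence[str],
    parents: Sequence[str],
    parent_states: Mapping[str, Sequence[str]],
    provenance: str = "",
) -> CountTable:
    """Cross-tabulate complete cases of a cohort table into a CountTable.

    ``cohort`` is a pandas DataFrame with one column per node; missing cells
    (NaN or the empty-string token) are dropped per family (complete-case).
    """
    import pandas as pd

    cols = list(parents) + [node]
    df = cohort[cols].mask(cohort[cols] == "").dropna()
    shape = tuple(len(parent_states[p]) for p in parents) + (len(node_states),)
    counts = np.zeros(shape)
    if len(df):
        codes = []
        for p in parents:
            cat = pd.Categorical(df[p], categories=list(parent_states[p]))
            codes.append(cat.codes)
        cat = pd.Categorical(df[node], categories=list(node_states))
        codes.append(cat.codes)
        codes = np.stack(codes, axis=1)
        if np.any(codes < 0):
            bad = df.iloc[int(np.argwhere(codes < 0)[0][0])]
            raise ValueError(f"unseen state in cohort for {cols}: {dict(bad)}")
        np.add.at(counts, tuple(codes.T), 1.0)
    return CountTable(
        node, node_states, parents, parent_states, counts, provenance
    )
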