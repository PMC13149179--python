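"""Synthetic cohorts with the statistical structure the method assumes.

Real periodontal cohorts (primary-care EHRs, owner questionnaires) are not
distributable, so every pipeline stage is exercised against cohorts sampled
from a documented ground-truth parameterization of the bundled 19-node
structure, then passed through an explicit observation process:

* EHR-style: the latent disease state is visible only through the
  exam-conditional diagnosis nodes (underdiagnosis), hygiene and bad-breath
  recording is sparse with a negative default, and morphology fields have a
  few percent missingness (head shape 8.23%, breed size 5.50% by default —
  the rates reported for the emulated records);
* questionnaire-style: self-reported fields carry symmetric flip noise and
  morphology is missing far more often (mixed breeds preclude assignment).

The ground truth is constructed, not fitted: effects are monotone by design
(risk rises with age; bad conformation, biofilm and gingivitis raise it),
the age-risk trajectory follows the published probabilistic estimates
(0.008 at under six months rising to about 0.48 at 13+), and the latent
prevalence is calibrated by intercept bisection to a configurable target
(default 12.4%, the model's no-evidence prior). Every CPT is strictly
positive so that conditional-independence tests see non-degenerate data;
ranked nodes use a softening temperature rather than hard point masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .inference import _eliminate, _Factor
from .network import Cpt, DiscreteBayesianNetwork, MISSING
from .params import ranked_cpt
from .perio import (
    AGE_BIN_LABELS,
    BREED_RISK_GROUPS,
    BREEDS,
    HEAD_SHAPE_LOOKUP,
    HEAD_SHAPES,
    PARENTS,
    RANKED_LEVELS,
    SIZE_LABELS,
    BREED_MEAN_WEIGHT_KG,
    assign_breed_size,
    build_periodontal_dag,
    default_ranked_spec,
    load_owner_awareness_cpt,
)
from .params import expand_coarse_cpt

__all__ = [
    "GroundTruthConfig",
    "ObservationSpec",
    "EHR_OBSERVATION",
    "QUESTIONNAIRE_OBSERVATION",
    "make_ground_truth",
    "sample_cohort",
    "apply_observation",
]


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return float(np.log(p / (1.0 - p)))


#: Published probabilistic periodontitis estimates at the anchor ages
#: (months) used to shape the ground truth's age effect.
_AGE_ANCHORS_MONTHS = (3.0, 36.0, 84.0, 132.0, 160.0)
_AGE_ANCHORS_P = (0.008, 0.115, 0.277, 0.419, 0.477)


def _age_bin_midpoints_months() -> np.ndarray:
    from .perio import AGE_BIN_EDGES_MONTHS

    edges = list(AGE_BIN_EDGES_MONTHS) + [168.0]
    return np.array([(a + b) / 2 for a, b in zip(edges[:-1], edges[1:])])


@dataclass(frozen=True)
class GroundTruthConfig:
    """Tunable knobs of the synthetic ground truth."""

    latent_prevalence: float = 0.124
    gingivitis_effect: float = 2.8  # log-odds for gingivitis present
    biofilm_effect: float = 1.0
    conformation_effect: float = 0.8  # per unit of badness (good=0, bad=1)
    breed_effect_sd: float = 0.5  # log-odds spread of per-breed risk
    coe_sensitivity: float = 0.60  # P(DX | disease, conscious exam)
    ga_sensitivity: float = 0.95  # P(DX | disease, GA exam)
    dx_false_positive: float = 0.01
    ranked_temperature: float = 0.12
    deterministic_dx_or: bool = True


@dataclass(frozen=True)
class ObservationSpec:
    """Observation process mapping latent records to recorded ones.

    ``missing_rates``: cell replaced by the missing token at this rate.
    ``sparsity``: node -> (rate, default state); with probability ``rate``
    the true state is simply not recorded and the dataset's default value
    appears instead (EHR flags default to their negative state).
    ``flip_rates``: node -> rate of replacing the cell by a uniformly drawn
    *other* state (self-report noise).
    ``diagnosis_pathway``: drop the latent outcome column so the disease is
    visible only through the exam-conditional diagnosis nodes.
    """

    missing_rates: Mapping[str, float] = field(default_factory=dict)
    sparsity: Mapping[str, tuple[float, str]] = field(default_factory=dict)
    flip_rates: Mapping[str, float] = field(default_factory=dict)
    diagnosis_pathway: bool = False
    provenance: str = "ideal"

    def __post_init__(self) -> None:
        rates = list(self.missing_rates.values()) + list(
            self.flip_rates.values()
        ) + [r for r, _ in self.sparsity.values()]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all observation rates must lie in [0, 1]")


EHR_OBSERVATION = ObservationSpec(
    missing_rates={"Head shape": 0.0823, "Breed size": 0.0550},
    sparsity={
        "Bad breath": (0.97, "False"),
        "Dental hygiene": (0.60, "Bad"),
    },
    diagnosis_pathway=True,
    provenance="ehr-like",
)

QUESTIONNAIRE_OBSERVATION = ObservationSpec(
    missing_rates={"Head shape": 0.3836, "Breed size": 0.3665},
    flip_rates={"Bad breath": 0.05, "Bleeding gums": 0.02, "Clinical signs": 0.08},
    diagnosis_pathway=True,
    provenance="questionnaire-like",
)


def _breed_marginal(rng: np.random.Generator) -> np.ndarray:
    """Popularity distribution: named common breeds dominate, long tail."""
    named = {
        "Other": 0.157, "American Staffordshire Terrier": 0.093,
        "Chihuahua": 0.0815, "Labrador Retriever": 0.080,
        "Mixed Breed": 0.067, "Yorkshire Terrier": 0.0517,
        "Shih Tzu": 0.0504, "German Shepherd": 0.0494, "Poodle": 0.0483,
        "Maltese": 0.0326,
    }
    rest = [b for b in BREEDS if b not in named]
    tail = rng.gamma(2.0, 1.0, size=len(rest))
    tail = tail / tail.sum() * (1.0 - sum(named.values()))
    p = np.array([named.get(b, 0.0) for b in BREEDS])
    p[[BREEDS.index(b) for b in rest]] = tail
    return p / p.sum()


def _spread_around(k: int, centre: int, mass: float = 0.85) -> np.ndarray:
    """Concentrated-but-positive distribution around one category."""
    p = np.full(k, (1.0 - mass) / max(k - 1, 1) * 0.4)
    if centre > 0:
        p[centre - 1] += (1.0 - mass) * 0.3
    if centre < k - 1:
        p[centre + 1] += (1.0 - mass) * 0.3
    p[centre] += mass
    return p / p.sum()


def make_ground_truth(
    config: GroundTruthConfig = GroundTruthConfig(), seed: int = 0
) -> DiscreteBayesianNetwork:
    """Parameterize the bundled structure with documented monotone effects."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x67]))
    dag = build_periodontal_dag()
    states = {n: dag.spec(n).states for n in dag.node_names}
    pstates = lambda node: {p: states[p] for p in PARENTS[node]}
    cpts: list[Cpt] = []
    add = lambda node, values: cpts.append(
        Cpt(node, states[node], PARENTS[node], pstates(node), values)
    )

    n_age = len(AGE_BIN_LABELS)
    age_mid = _age_bin_midpoints_months()
    size_score = {s: 1.0 - i / 5.0 for i, s in enumerate(SIZE_LABELS)}  # Toy=1
    head_score = {"Brachycephalic": 1.0, "Mesocephalic": 0.0, "Dolichocephalic": 0.4}
    risk_score = {"Low": 0.0, "Expected": 0.5, "High": 1.0}
    nominal_size = {
        b: SIZE_LABELS.index(assign_breed_size(BREED_MEAN_WEIGHT_KG[b]))
        for b in BREEDS
    }

    # Breed (root): popularity marginal
    add("Breed", _breed_marginal(rng))

    # Breed size | Breed: concentrated on the nominal class
    add(
        "Breed size",
        np.stack([_spread_around(6, nominal_size[b]) for b in BREEDS]),
    )

    # Head shape | Breed, Breed size: lookup shape dominates; unknown breeds
    # lean brachycephalic when small, mesocephalic otherwise
    hs = np.zeros((len(BREEDS), 6, 3))
    for i, b in enumerate(BREEDS):
        shape = HEAD_SHAPE_LOOKUP.get(b, "Mesocephalic")
        for j in range(6):
            if shape is None:
                brachy = 0.35 - 0.04 * j
                hs[i, j] = np.array([brachy, 0.95 - brachy, 0.05])
            else:
                hs[i, j] = _spread_around(3, HEAD_SHAPES.index(shape), 0.9)
    add("Head shape", hs / hs.sum(-1, keepdims=True))

    # Age | Breed, Breed size: puppy-heavy base, small breeds skew older
    base_age = np.exp(-np.arange(n_age) / 4.0)
    base_age[:2] *= (2.2, 1.4)
    age = np.zeros((len(BREEDS), 6, n_age))
    for j in range(6):
        tilt = np.exp((size_score[SIZE_LABELS[j]] - 0.5) * 0.12 * np.arange(n_age))
        age[:, j, :] = base_age * tilt
    add("Age", age / age.sum(-1, keepdims=True))

    # Pet compliance | Breed
    comp = 0.45 + 0.35 * rng.beta(4, 4, size=len(BREEDS))
    add("Pet compliance", np.stack([1 - comp, comp], axis=-1))

    # Dental conformation | Breed, Breed size, Head shape (softened ranked)
    conf = np.zeros((len(BREEDS), 6, 3, 3))
    for i, b in enumerate(BREEDS):
        for j, s in enumerate(SIZE_LABELS):
            for h, hd in enumerate(HEAD_SHAPES):
                r = (
                    0.45 * size_score[s]
                    + 0.35 * head_score[hd]
                    + 0.20 * risk_score[BREED_RISK_GROUPS[b]]
                )
                p_bad = 0.01 + 0.22 * r
                p_med = 0.03 + 0.20 * r
                conf[i, j, h] = (p_bad, p_med, 1.0 - p_bad - p_med)
    add("Dental conformation", conf)

    # Dental hygiene | Age: mostly bad, care improves with age
    hyg = np.zeros((n_age, 3))
    for a in range(n_age):
        p_good = 0.08 + 0.022 * a
        p_med = 0.02 + 0.004 * a
        hyg[a] = (1.0 - p_good - p_med, p_med, p_good)
    add("Dental hygiene", hyg)

    # Biofilm | Dental conformation, Dental hygiene, Age
    conf_bad = {"Bad": 1.0, "Medium": 0.5, "Good": 0.0}
    bio = np.zeros((3, 3, n_age, 2))
    for c, cs in enumerate(RANKED_LEVELS):
        for y, ys in enumerate(RANKED_LEVELS):
            for a in range(n_age):
                z = (
                    -2.6
                    + 0.55 * min(a, 8)
                    + 1.0 * conf_bad[cs]
                    + 0.8 * conf_bad[ys]
                )
                p = _logistic(z)
                bio[c, y, a] = (1 - p, p)
    add("Biofilm", bio)

    # Bad breath | Biofilm
    add("Bad breath", np.array([[0.98, 0.02], [0.65, 0.35]]))

    # Gingivitis | Age, Biofilm, Dental hygiene
    ging = np.zeros((n_age, 2, 3, 2))
    for a in range(n_age):
        for b in range(2):
            for y, ys in enumerate(RANKED_LEVELS):
                z = -4.2 + 2.9 * b + 0.10 * a + 0.6 * conf_bad[ys]
                p = _logistic(z)
                ging[a, b, y] = (1 - p, p)
    add("Gingivitis", ging)

    # Periodontitis | Breed, Age, Dental conformation, Biofilm, Gingivitis
    breed_delta = rng.normal(0.0, config.breed_effect_sd, size=len(BREEDS))
    breed_delta -= breed_delta.mean()
    # high-risk groups shifted up, low-risk down, on top of the jitter
    breed_delta += np.array(
        [(risk_score[BREED_RISK_GROUPS[b]] - 0.5) * 1.2 for b in BREEDS]
    )
    age_curve = np.interp(age_mid, _AGE_ANCHORS_MONTHS, _AGE_ANCHORS_P)
    age_base = np.array([_logit(p) for p in age_curve])

    def perio_values(intercept_shift: float) -> np.ndarray:
        z = (
            age_base[None, :, None, None, None]
            + breed_delta[:, None, None, None, None]
            + config.conformation_effect
            * np.array([1.0, 0.5, 0.0])[None, None, :, None, None]
            + config.biofilm_effect * np.array([0.0, 1.0])[None, None, None, :, None]
            + config.gingivitis_effect
            * np.array([0.0, 1.0])[None, None, None, None, :]
            - 1.4  # centre: covariate effects otherwise inflate the curve
            + intercept_shift
        )
        p = _logistic(z)
        return np.stack([1 - p, p], axis=-1)

    add("Periodontitis", perio_values(0.0))

    # Bleeding gums | Gingivitis, Periodontitis
    bleed = np.array(
        [[[0.995, 0.005], [0.92, 0.08]], [[0.80, 0.20], [0.65, 0.35]]]
    )
    add("Bleeding gums", bleed)

    # Clinical signs | Periodontitis, Gingivitis, Bleeding gums, Age
    # (softened ranked node; high score = healthy)
    clin_spec = default_ranked_spec(
        "Clinical signs",
        PARENTS["Clinical signs"],
        {p: states[p] for p in PARENTS["Clinical signs"]},
        parent_scores={
            "Periodontitis": {"False": 1.0, "True": 0.0},
            "Gingivitis": {"False": 1.0, "True": 0.0},
            "Bleeding gums": {"False": 1.0, "True": 0.0},
            "Age": {
                s: 1.0 - i / (n_age - 1) for i, s in enumerate(AGE_BIN_LABELS)
            },
        },
        weights={
            "Periodontitis": 0.45,
            "Gingivitis": 0.25,
            "Bleeding gums": 0.15,
            "Age": 0.15,
        },
    )
    cpts.append(ranked_cpt(clin_spec, temperature=config.ranked_temperature))

    # Owner awareness: the elicited coarse table expanded over breeds
    oa = expand_coarse_cpt(
        load_owner_awareness_cpt(),
        {
            "Bad breath": states["Bad breath"],
            "Bleeding gums": states["Bleeding gums"],
            "Breed risk group": BREEDS,
            "Clinical signs": states["Clinical signs"],
        },
        state_maps={"Breed risk group": BREED_RISK_GROUPS},
    )
    oa = Cpt(
        "Owner awareness",
        states["Owner awareness"],
        ("Bad breath", "Bleeding gums", "Breed", "Clinical signs"),
        {p: states[p] for p in PARENTS["Owner awareness"]},
        oa.values,
    )
    cpts.append(oa)

    # Conscious exam | Age, Breed, Owner awareness, Pet compliance
    coe = np.zeros((n_age, len(BREEDS), 2, 2, 2))
    breed_jitter = rng.normal(0, 0.05, size=len(BREEDS))
    for a in range(n_age):
        p = 0.55 + 0.012 * a + breed_jitter[None, :]
        for aw in range(2):
            for cp in range(2):
                q = np.clip(p + 0.12 * aw + 0.10 * cp, 0.05, 0.97)
                coe[a, :, aw, cp, 1] = q
                coe[a, :, aw, cp, 0] = 1 - q
    add("Conscious exam", coe)

    # GA exam | Age, Breed, Owner awareness
    ga = np.zeros((n_age, len(BREEDS), 2, 2))
    for a in range(n_age):
        p = np.clip(0.03 + 0.022 * a + breed_jitter, 0.005, 0.9)
        for aw in range(2):
            q = np.clip(p + 0.10 * aw, 0.005, 0.95)
            ga[a, :, aw, 1] = q
            ga[a, :, aw, 0] = 1 - q
    add("GA exam", ga)

    # Diagnosis nodes: disease visible only through an exam
    fp = config.dx_false_positive
    dx_coe = np.array(
        [
            [[1.0, 0.0], [1.0 - fp, fp]],  # no disease: (no exam, exam)
            [[1.0, 0.0], [1.0 - config.coe_sensitivity, config.coe_sensitivity]],
        ]
    )
    add("Periodontitis DX under COE", dx_coe)
    dx_ga = np.array(
        [
            [[1.0, 0.0], [1.0 - fp, fp]],
            [[1.0, 0.0], [1.0 - config.ga_sensitivity, config.ga_sensitivity]],
        ]
    )
    add("Periodontitis DX under GA", dx_ga)

    if config.deterministic_dx_or:
        dx = np.array([[[1, 0], [0, 1]], [[0, 1], [0, 1]]], dtype=float)
    else:
        dx = np.array([[[0.99, 0.01], [0.02, 0.98]], [[0.02, 0.98], [0.01, 0.99]]])
    add("Periodontitis DX", dx)

    net = DiscreteBayesianNetwork(dag, cpts)

    # Calibrate the latent prevalence by bisecting the outcome intercept
    # against the exact parent-joint (deterministic given the seed).
    parent_joint = _parent_joint(net, "Periodontitis")
    target = config.latent_prevalence
    lo, hi = -4.0, 4.0
    for _ in range(40):
        mid = (lo + hi) / 2
        p = float((parent_joint * perio_values(mid)[..., 1]).sum())
        if p < target:
            lo = mid
        else:
            hi = mid
    cpts = [c for c in cpts if c.node != "Periodontitis"]
    cpts.append(
        Cpt(
            "Periodontitis",
            states["Periodontitis"],
            PARENTS["Periodontitis"],
            pstates("Periodontitis"),
            perio_values((lo + hi) / 2),
        )
    )
    return DiscreteBayesianNetwork(dag, cpts)


def _parent_joint(net: DiscreteBayesianNetwork, node: str) -> np.ndarray:
    """Exact joint distribution over a node's parents, axes in parent order."""
    parents = net.parents(node)
    factors = [
        _Factor(c.parents + (c.node,), c.values) for c in net.cpts.values()
    ]
    hidden = [n for n in net.node_names if n not in parents]
    result = _eliminate(factors, hidden)
    order = [result.vars.index(p) for p in parents]
    values = np.transpose(result.values, order)
    return values / values.sum()


# ---------------------------------------------------------------------------
# Sampling and observation


def sample_cohort(
    net: DiscreteBayesianNetwork, n: int, seed: int = 0
) -> pd.DataFrame:
    """Ancestral (forward) sampling of ``n`` i.i.d. records.

    Returns a DataFrame with one string column per node;
    ``df.attrs["provenance"]`` is ``"ideal"`` (no observation noise).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A]))
    codes: dict[str, np.ndarray] = {}
    for node in net.topological_order():
        cpt = net.cpts[node]
        if cpt.parents:
            idx = tuple(codes[p] for p in cpt.parents)
            probs = cpt.values[idx]  # (n, k)
        else:
            probs = np.broadcast_to(cpt.values, (n, cpt.values.shape[-1]))
        u = rng.random(n)[:, None]
        codes[node] = (probs.cumsum(axis=1) < u).sum(axis=1).astype(np.int64)
    data = {
        node: pd.Categorical.from_codes(
            codes[node], categories=list(net.states(node))
        ).astype(str)
        for node in net.node_names
    }
    df = pd.DataFrame(data)
    df.attrs["provenance"] = "ideal"
    return df


def apply_observation(
    cohort: pd.DataFrame, spec: ObservationSpec, seed: int = 0
) -> pd.DataFrame:
    """Apply an observation process to an ideal cohort.

    Order per column: self-report flips, recording sparsity (unrecorded
    cells take the dataset default), then missingness masking. With the
    diagnosis pathway on, the latent outcome column is dropped entirely.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0B5]))
    df = cohort.copy()
    n = len(df)
    for node, rate in spec.flip_rates.items():
        if node not in df.columns or rate == 0:
            continue
        mask = rng.random(n) < rate
        if mask.any():
            observed = df[node].to_numpy(copy=True)
            states = sorted(set(observed[observed != MISSING]))
            if len(states) > 1:
                for i in np.flatnonzero(mask):
                    others = [s for s in states if s != observed[i]]
                    observed[i] = others[rng.integers(len(others))]
                df[node] = observed
    for node, (rate, default) in spec.sparsity.items():
        if node not in df.columns or rate == 0:
            continue
        mask = rng.random(n) < rate
        col = df[node].to_numpy(copy=True)
        col[mask] = default
        df[node] = col
    for node, rate in spec.missing_rates.items():
        if node not in df.columns or rate == 0:
            continue
        mask = rng.random(n) < rate
        col = df[node].to_numpy(dtype=object, copy=True)
        col[mask] = MISSING
        df[node] = col
    if spec.diagnosis_pathway and "Periodontitis" in df.columns:
        df = df.drop(columns=["Periodontitis"])
    df.attrs["provenance"] = spec.provenance
    return df
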