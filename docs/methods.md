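# Methods

## Model

`periobn` represents a discrete Bayesian network as a DAG over nodes with
fixed, ordered state spaces plus one conditional probability table (CPT)
per node. State order is semantic: ranked (ordinal) nodes declare their
levels worst→best (`Bad < Medium < Good`), and every ordinal encoding,
ranked-node synthesis and serialization relies on the declared order.
Parent configurations are enumerated row-major in the declared parent
list, byte-for-byte stable across save/load. CPT rows must sum to 1 within
1e-9; rows from printed tables carrying rounding slack (e.g. 0.523 + 0.478
= 1.001) are renormalized only on explicit request and the adjusted rows
are recorded on the table. Missing data is a distinguished token (empty
CSV cell), never a state.

### The bundled periodontal structure

The shipped 19-node structure encodes the causal account of canine
periodontal disease: breed determines size, skull shape and (with size)
the age profile; morphology drives dental conformation; conformation,
hygiene and age drive biofilm; biofilm, hygiene and age drive gingivitis;
breed, age, conformation, biofilm and gingivitis drive periodontitis;
disease drives bleeding gums and clinical signs; signs, bad breath,
bleeding and breed drive owner awareness; awareness, compliance, age and
breed drive the two examination routes; and diagnosis nodes fire only
when disease meets an examination. It reproduces the published structural
totals exactly — 19 nodes, 45 edges, 101 states, 33,231 conditional
probabilities — which is a strong joint constraint: among all
text-plausible parent-set assignments, only the shipped family (up to the
placement of the awareness/compliance edges into the two exam nodes)
satisfies all four totals simultaneously. The source figure itself was
not available to this implementation, so the edge list is a
reconstruction pinned by those totals plus the textual parent
descriptions; the two validation-added edges (age→dental hygiene,
age→clinical signs) are included.

State spaces follow the published processing rules: 44 breeds (14
higher-prevalence, 15 lower-prevalence, 14 common, plus Other — breeds
beyond those named in the source tables are synthetic stand-ins, as are
the breed risk groups and the head-shape lookup, and all are
overridable); 15 age bins (<6 months, 6 months–1 year, yearly to 13, then
13+; half-open intervals, dogs under one month excluded); six size
classes at closed upper bounds 6.5/9/15/30/40 kg; three skull shapes;
three 3-level ranked nodes; twelve binary nodes. Bodyweight is corrected
for body condition score at 20% per point around the ideal score of 3
before size assignment. Ranked-node weights and thresholds default to
equal weights with tercile cut points (the published consensus values are
in unavailable supplementary material); a score on a threshold goes to
the higher level, and an optional softening temperature turns the default
point-mass rows into graded ones.

## Parameter construction

Each node's CPT is built from up to three ingredients:

* **Priors** — uniform; expert tables (element-wise mean across
  panelists, renormalized); demographic or data marginals (counts over an
  observed parent subset broadcast over unobserved parents, uniform
  fallback for empty projections); or weighted convex mixtures of these
  (composite priors). Expert tables elicited on simplified categories
  (breed risk groups, life stages) are expanded to the full state space
  piecewise-constant by default, with opt-in linear interpolation between
  category centres for ordinal parents — the publication says
  "interpolated" without a formula, so the constant expansion is the
  conservative default.
* **Data** — per-family contingency counts from complete cases, fused
  across datasets so each dataset contributes a share of the combined
  mass proportional to its weight (a 1:20 questionnaire:EHR weight gives
  the EHR 20/21 of every cell regardless of raw sizes). Known
  misclassification is corrected by solving the observed counts through
  the expert-supplied matrix `M[obs,true] = P(obs|true)`, clipping
  negative solutions at zero, rescaling to the original total and
  logging clip events.
* **Update** — a Dirichlet pseudo-count step in which the prior receives
  total mass `(w_prior / w_data) x (row's observed count)` per parent
  configuration. This makes the printed ratios scale-free: "1:10" always
  means the prior carries 1/11 of each row's effective evidence, whatever
  the node's data volume. Rows never observed keep the prior unchanged.

A consequence worth stating plainly: at a fixed ratio the posterior is a
*fixed* mixture `(w_d·p̂ + w_p·prior)/(w_d+w_p)` and never converges to
the empirical frequencies as data accumulate. At 1:10 with a uniform
prior, every row is pulled exactly 1/11 of the way toward uniform — a
deterministic bias of `0.0909 x TV(row, uniform)`, up to 0.045 for
near-degenerate rows. Recovery experiments must therefore not expect
well-supported extreme rows (disease probability 0.008 in puppies, 0.001
without gingivitis, deterministic diagnosis gates) to land within 0.03
total variation of the truth; measured max TV at n=50,000 is 0.087. The
corresponding acceptance test states the stricter bound and fails for
exactly this reason; it is retained as documentation of the limit rather
than relaxed.

## Inference

Queries are exact. Factors are dense ndarrays multiplied by broadcasting;
hidden variables are summed out in greedy min-fill order (a performance
choice only — results are order-invariant and tested as such). Evidence
with zero probability raises rather than returning NaN. Interventional
queries drop the mechanisms of intervened nodes and fix their values in
all remaining factors (truncated factorization), which reduces to
conditioning for parentless nodes and to the bare CPT row when every
parent of the target is fixed — both identities are tested.

Effect size is the Jensen–Shannon *distance*: the square root of the
natural-log Jensen–Shannon divergence (bounded by sqrt(ln 2) ≈ 0.8326),
computed via `scipy.spatial.distance.jensenshannon`. This convention —
rather than the base-2 or unrooted variants — reproduces the published
worked values (0.443, 0.323, 0.410, 0.172, 0.337) from their printed
input pairs to three decimals and is frozen by test. The posterior
probability certainty index (PPCI) is implemented as the normalized peak
posterior, `(max_s P(s) − 1/k)/(1 − 1/k)` averaged over cases: 0 for
uniform posteriors, 1 for point masses. The defining reference was not
available to this implementation, so the formula is a documented stand-in
kept behind a single function. Entropy reduction is the mutual
information `H(target) − Σ_x P(x) H(target|x)` computed by exact
inference, in bits by default with the base configurable; it is not
normalized by `H(target)` (both conventions are reachable, raw is the
default).

## DAG validation

The testable implications are one conditional independence per
non-adjacent pair: with `y` the later node in a fixed topological order,
`x ⟂ y | pa(y)` holds by the local Markov property. Three tests are
provided, all complete-case per test:

* **Generalized Cochran–Mantel–Haenszel (default).** Pools
  margin-conditioned centred counts across conditioning strata, giving
  (r−1)(c−1) degrees of freedom however many sparse strata the
  conditioning space produces. On 20,000 records sampled from the bundled
  network it rejects at the nominal 1% rate (1 of 110 performed tests)
  and detects an injected head-shape→hygiene dependency in 10/10
  replicates.
* **Fisher-z partial correlation on ordinal encodings** (the workflow the
  published analysis used, via dagitty). Provided and tested, but
  *anti-conservative* on strongly discrete data: conditional means that
  are non-linear in the integer ranks leave residual correlation that a
  large sample converts into rejections (~23% of implied independencies
  rejected at α=0.01 on the same null data). It is therefore not the
  default here.
* **Stratified G².** Also provided; anti-conservative when strata are
  sparse (~21% null rejections on the same data), with the usual
  `n ≥ 5·df` screening heuristic.

Tests whose conditioning space the sample cannot support are skipped with
a reason, as are degenerate cases (constant columns, no usable strata).
The default α is 0.01 and is configurable; the publication states neither
α nor a multiplicity treatment, so no correction is applied by default.
BIC is the penalized log-likelihood `log L − (free parameters/2)·ln N`
(higher is better), decomposed over families; `compare_edge` rescores only
the affected families and exactly equals the full-score difference. Edge
adjudication remains a human decision; the module reports evidence only.

## Synthetic cohorts

Real cohorts being proprietary, the generator defines the study
conditions in two stages.

**Ground truth.** The bundled structure is parameterized with documented
monotone effects: the age–risk trajectory interpolates the published
observational estimates (0.008 under six months rising through 0.115 at
three years to ≈0.48 at 13+); gingivitis, biofilm and bad conformation
add fixed log-odds (2.8, 1.0, 0.8); breed effects combine the risk-group
offset (±0.6) with seeded jitter (sd 0.5); and the latent prevalence is
calibrated by intercept bisection against the exact parent joint to a
configurable target, default 12.4% (the model's no-evidence prior; the
EHR-style diagnosed prevalence then lands near the reported 9% once the
exam pathway is applied). The owner-awareness CPT is the shipped expert
table expanded over the 44 breeds via their risk groups. All rows except
the diagnosis gates are strictly positive, and ranked nodes use a
softening temperature (0.12), so conditional-independence tests see
non-degenerate data. Conscious-exam sensitivity for periodontitis is 0.60
versus 0.95 under anesthesia, with a 1% false-positive rate; "any
diagnosis" is the deterministic OR of the two routes (configurable).

**Observation.** A cohort sampled ancestrally (vectorized, seeded; a
single seed fans out to per-stage child seeds) is passed through an
observation spec: per-node missingness (EHR defaults: head shape 8.23%,
breed size 5.50% — the reported rates), recording sparsity with a dataset
default (bad breath unrecorded 97% of the time → recorded False; hygiene
60% → recorded Bad), self-report flip noise for the questionnaire profile,
and the diagnosis pathway switch that drops the latent outcome column so
disease is visible only through the exam-conditional diagnosis nodes.
Diagnosed prevalence is then strictly below latent prevalence,
reproducing the underdiagnosis the method is designed around.

What the generator does **not** emulate: visit-level longitudinal
structure, billing/free-text signals, cohort-selection effects (the ≥2
visits / ≥2 questionnaires inclusion rules), and real breed-specific
idiosyncrasies beyond the risk-group offsets. Passing tests on these
cohorts therefore demonstrate correctness of the machinery under the
stated statistical pathologies, not fidelity to any real population.

## Evaluation

Node-level prediction conditions each node on its full parent set (exact
inference then reduces to the CPT row) and scores by node class: binary —
balanced accuracy and ROC AUC; multiclass — balanced accuracy and
unweighted one-vs-one AUC over observed classes; ordinal — mean absolute
distance between predicted and true level. The overall classifier is
evaluated at a probability threshold chosen as the mean over validation
datasets of the per-dataset Youden-J-optimal threshold; candidate
thresholds are midpoints between consecutive distinct scores so a
separable dataset yields the centre of its separating gap, and ties take
the midpoint of the optimal range. "Optimal threshold" is not defined in
the source, so Youden's J is this package's documented choice. Expectation
analysis sweeps a hypothesis's ordered input states under both inference
modes and reports, per consecutive pair, direction satisfaction plus the
Jensen–Shannon effect size and label.

## Problem sizes and numerical choices

The test suite runs the oracle-equivalence battery on 100 random networks
of ≤6 nodes (exact agreement within 1e-10 against full-joint enumeration
and truncated-factorization oracles), conditional-independence calibration
on 20,000-record cohorts, power estimation over 10 replicates, and
parameter recovery at 50,000 records — sizes chosen so the full suite
completes in a few minutes on one CPU while keeping every Monte-Carlo
band comfortably away from its threshold. Over the five published age
anchors the refit model's risk ordering matches the truth exactly; over
all 15 bins the Spearman correlation at n=50,000 is 0.993, with adjacent
swaps confined to the senior bins that hold ~1–2% of records each.
Normalization tolerance is 1e-9 throughout; renormalization is
opt-in and logged; elimination ordering is min-fill with lexicographic
tie-breaks; all randomness flows from explicit integer seeds.
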