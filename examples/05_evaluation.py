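"""Evaluate the network: sensitivity, node prediction, classification.

Ranks inputs by entropy reduction on the outcome, tests a monotone age
hypothesis under both inference modes, scores per-node prediction on a
fresh cohort, and evaluates periodontitis classification at a
Youden-selected threshold.
"""

import numpy as np

from periobn import (
    HypothesisSpec,
    classifier_eval,
    entropy_reduction,
    expectation_analysis,
    make_ground_truth,
    mean_optimal_threshold,
    node_predictive_performance,
    ppci,
    query_probabilistic,
    sample_cohort,
)

net = make_ground_truth(seed=0)

print("entropy reduction on periodontitis (bits):")
for node in ("Gingivitis", "Clinical signs", "Age", "Biofilm", "Head shape"):
    print(f"  {node:18s} {entropy_reduction(net, 'Periodontitis', node):.3f}")

hyp = HypothesisSpec(
    description="risk increases with age",
    target="Periodontitis", target_state="True", input_node="Age",
    states=("<6m", "3-4y", "7-8y", "11-12y", "13+y"),
)
report = expectation_analysis(net, [hyp])
print(f"age hypothesis: probabilistic "
      f"{'pass' if report.passed(hyp.description, 'probabilistic') else 'fail'}, "
      f"causal {'pass' if report.passed(hyp.description, 'causal') else 'fail'}")

cohort = sample_cohort(net, 10_000, seed=3)
for rep in node_predictive_performance(net, cohort, nodes=("Gingivitis",)):
    print(f"gingivitis from parents: {rep.metric}={rep.value:.3f}")

# classify the latent outcome from the five parent observations
parents = list(net.parents("Periodontitis"))
scores = np.empty(len(cohort))
for config, sub in cohort.groupby(parents, observed=True):
    d = query_probabilistic(net, "Periodontitis", dict(zip(parents, config)))
    scores[sub.index] = d["True"]
labels = (cohort["Periodontitis"] == "True").astype(int).to_numpy()
threshold = mean_optimal_threshold([(scores, labels)])
rep = classifier_eval(scores, labels, threshold)
d = rep.detail
print(f"threshold {threshold:.3f}: AUC={d['roc_auc']:.3f}, "
      f"sens={d['sensitivity']:.3f}, spec={d['specificity']:.3f}, "
      f"balanced acc={d['balanced_accuracy']:.3f}")
print(f"mean posterior certainty (PPCI): "
      f"{ppci([(s, 1 - s) for s in scores]):.3f}")
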