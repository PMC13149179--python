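"""Build the bundled periodontal network and ask it basic risk questions.

Constructs the 19-node ground-truth parameterization (latent periodontitis
prevalence calibrated to 12.4%), then queries the probability of
periodontitis with no evidence and with progressively more clinical
evidence for one dog.
"""

from periobn import make_ground_truth, query_probabilistic

net = make_ground_truth(seed=0)
print(f"network: {len(net.node_names)} nodes, "
      f"{len(net.structure.edges)} edges, {net.n_parameters} parameters")

baseline = query_probabilistic(net, "Periodontitis")
print(f"P(periodontitis), no evidence: {baseline['True']:.3f}")

scenarios = [
    {"Breed": "Shih Tzu"},
    {"Breed": "Shih Tzu", "Age": "12-13y"},
    {"Breed": "Shih Tzu", "Age": "12-13y", "Gingivitis": "True"},
]
for ev in scenarios:
    d = query_probabilistic(net, "Periodontitis", ev)
    print(f"P(periodontitis | {ev}): {d['True']:.3f}")

# Each added observation moves the risk estimate; the jump with gingivitis
# reflects its proximity to the outcome in the causal chain.
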