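"""Observing a variable versus setting it: the do-operator.

Dental hygiene is confounded with periodontitis through age (older dogs
both receive more dental care and carry more disease), so the observed
association and the effect of intervening differ. The Jensen-Shannon
distance quantifies each contrast, with the qualitative labels used for
effect sizes (>0.2 very strong, >0.1 strong, >0.05 moderate, >0 weak).
"""

from periobn import (
    effect_report,
    make_ground_truth,
    query_causal,
    query_probabilistic,
)

net = make_ground_truth(seed=0)

for state in ("Good", "Bad"):
    obs = query_probabilistic(net, "Periodontitis", {"Dental hygiene": state})
    do = query_causal(net, "Periodontitis", {"Dental hygiene": state})
    print(f"hygiene={state}: observed P={obs['True']:.3f}, "
          f"do() P={do['True']:.3f}")

base = query_probabilistic(net, "Periodontitis")
ging = query_probabilistic(net, "Periodontitis", {"Gingivitis": "True"})
rep = effect_report(base, ging)
print(f"gingivitis evidence: JSD={rep.jsd:.3f} ({rep.label})")

# Observing poor hygiene mostly flags *young* dogs (hygiene starts bad and
# improves with age), so the observed association can even invert the
# causal direction — the classic reason to separate the two queries.
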