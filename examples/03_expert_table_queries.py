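"""Query the expert-elicited owner-awareness table.

The package ships the consensus conditional probability table for owner
awareness of oral disease given bad breath, bleeding gums, the breed's
risk group and clinical signs, as averaged across a veterinary expert
panel. With every parent observed, exact inference returns the elicited
row itself.
"""

from periobn import load_owner_awareness_cpt, owner_awareness_subnetwork
from periobn import query_probabilistic

cpt = load_owner_awareness_cpt()
print(f"table: parents {list(cpt.parents)}, "
      f"{cpt.values.size // 2} parent configurations")
print(f"rows renormalized on load (printed rounding slack): "
      f"{len(cpt.adjusted_rows)}")

net = owner_awareness_subnetwork()
quiet = query_probabilistic(
    net, "Owner awareness",
    {"Bad breath": "False", "Bleeding gums": "False",
     "Breed risk group": "Low", "Clinical signs": "Bad"},
)
alarmed = query_probabilistic(
    net, "Owner awareness",
    {"Bad breath": "True", "Bleeding gums": "True",
     "Breed risk group": "High", "Clinical signs": "Bad"},
)
print(f"low-risk breed, no visible signs beyond demeanour: "
      f"P(aware)={quiet['True']:.3f}")
print(f"high-risk breed, bad breath and bleeding gums:     "
      f"P(aware)={alarmed['True']:.3f}")

# Partial evidence marginalizes over the unobserved parents:
partial = query_probabilistic(net, "Owner awareness", {"Bad breath": "True"})
print(f"bad breath only: P(aware)={partial['True']:.3f}")
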