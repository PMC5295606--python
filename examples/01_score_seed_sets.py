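"""Score seed sets on a synthetic functional network.

Generates a small world with module-coherent and random-control seed sets,
evaluates every seed set by leave-one-out ROC AUC, and compares the two
groups: coherent partner sets cluster in the network (AUC near 1), control
sets do not (AUC near 0.5).
"""

import numpy as np

from netgi import WorldSpec, evaluate_seed_set, generate_world

world = generate_world(WorldSpec(rng_seed=42))
results = [evaluate_seed_set(world.network, ss) for ss in world.seed_sets]

by_group = {"coherent": [], "control": []}
for r in results:
    by_group[world.truth["seeds"][r.seed_set.seed]].append(r.auc)

for group, aucs in by_group.items():
    print(f"{group:8s}  n={len(aucs):2d}  mean AUC={np.mean(aucs):.3f}  "
          f"frac >= 0.9: {np.mean(np.array(aucs) >= 0.9):.2f}")
print("\nAUC >= 0.9 marks a seed set as highly predictive: its known "
      "partners sit in one functional module, so the remaining module "
      "members are credible novel interaction partners.")
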