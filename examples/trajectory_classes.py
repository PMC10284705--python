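"""Cluster immune trajectories into classes and link them to outcome.

Each tumour's trajectory is its per-day (T-cell abundance, core
infiltration ratio) pair.  Ward clustering with automatic class-count
selection recovers the three canonical classes: I — rising abundance but
persistently excluded; II — excluded early, inflamed late; III — early
inflamed with high infiltration, enriched for rejection.
"""

import numpy as np

from stamparray import cluster_trajectories, default_immunocompetent, simulate_cohort

truth = simulate_cohort(default_immunocompetent(seed=9), 300)
A = np.vstack([t.abundance_seq for t in truth.tumours])
R = np.vstack([t.core_ratio_seq for t in truth.tumours])

model = cluster_trajectories(A, R)
print(f"classes selected       : k = {model.k} "
      f"(variance-ratio scores {dict((k, round(v)) for k, v in model.score_by_k.items())})")

names = np.array([t.archetype_class for t in truth.tumours])
for c in range(1, model.k + 1):
    sel = model.labels == c
    rej = np.mean([truth.tumours[i].rejection_day is not None for i in np.flatnonzero(sel)])
    ratio_end = model.median_ratio[c - 1, -5:].mean()
    print(f"class {c}: n={sel.sum():3d}, median late infiltration ratio {ratio_end:.2f}, "
          f"rejection fraction {rej:.2f}, dominant truth class "
          f"{max(set(names[sel]), key=list(names[sel]).count)}")
print("only the early-inflamed class shows strong enrichment in rejection — "
      "a tumour's immune history predicts its outcome")
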