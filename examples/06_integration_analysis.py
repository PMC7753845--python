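"""Methylation-expression correlation screen and miRNA-target network.

The screen flags genes whose promoter methylation is strongly negatively
correlated with expression (Pearson r < -0.5, p < 1e-4) — candidates for
epigenetic silencing.  The network builder intersects two predicted
target lists per miRNA (score-filtered) with the differential-gene set.
"""

import numpy as np
import pandas as pd

import omisurv as om

rng = np.random.default_rng(0)
n = 200
idx = [f"s{i}" for i in range(n)]
genes = [f"g{j}" for j in range(30)]
beta = rng.uniform(0.1, 0.9, (n, 30))
expr = pd.DataFrame(rng.normal(5, 1, (n, 30)), index=idx, columns=genes)
# plant epigenetic silencing in the first five genes
expr.iloc[:, :5] = 8 - 5 * beta[:, :5] + rng.normal(0, 0.4, (n, 5))
meth = pd.DataFrame(beta, index=idx, columns=genes)

table = om.methylation_expression_screen(expr, meth)
hits = table.index[table["pass"]].tolist()
print(f"screen: {len(hits)} of {len(genes)} genes pass (r<-0.5, p<1e-4): {hits}")

targets_a = pd.DataFrame({   # e.g. prediction scores on a 0-100 scale
    "mirna": ["mirX"] * 4, "gene": ["g0", "g1", "g5", "g6"], "score": [95, 88, 40, 91],
})
targets_b = pd.DataFrame({   # e.g. conservation probabilities on a 0-1 scale
    "mirna": ["mirX"] * 4, "gene": ["g0", "g1", "g6", "g9"], "score": [0.9, 0.95, 0.7, 0.85],
})
edges = om.build_mirna_target_network(
    differential_mirnas=["mirX"], differential_genes=hits,
    targets_a=targets_a, targets_b=targets_b,
)
print("miRNA-target edges (filtered A ∩ B ∩ differential genes):")
print(edges.to_string(index=False))
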