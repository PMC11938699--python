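"""Generate and preprocess a random molecule library.

Draws 200 seed-deterministic valence-valid random molecules, applies the
standard preprocessing filter (connected, at least four carbons, heavy
degree at most four), and featurizes the survivors into a shared-schema
matrix ready for regression.
"""

from invqspr import GenConfig, featurize_dataset, preprocess_filter
from invqspr.datagen import random_chemgraphs

graphs = random_chemgraphs(GenConfig(n_graphs=200, seed=5))
kept, rejected = preprocess_filter(graphs)
print(f"generated {len(graphs)} molecules; kept {len(kept)}, rejected {len(rejected)}")
for g, reason in rejected[:5]:
    print(f"  rejected {g.id}: {reason}")

X, schema = featurize_dataset(kept, rho=2)
print(f"feature matrix: {X.shape[0]} rows x {X.shape[1]} descriptors")
print(f"first columns: {schema[:6]}")
print(f"mean heavy-atom count: {X['n_heavy'].mean():.2f}")
print(f"distinct fringe configurations observed: "
      f"{sum(1 for s in schema if s.startswith('fc:'))}")
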