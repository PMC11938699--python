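"""Inverse design: infer a molecule whose predicted logS hits a target.

Loads the packaged toy topological specification (a two-vertex seed whose
typical edge may stretch into a path of length up to 4, with a small
catalog of terminal fringe trees) and a linear solubility model, then asks
the MILP for any admissible molecule with predicted logS in [-2.0, -1.5].
The decoded graph is independently re-featurized and verified before being
returned.
"""

import json
from importlib import resources

from invqspr import LinearModel, infer, spec_from_json
from invqspr.descriptors import featurize

data = resources.files("invqspr.data")
spec = spec_from_json(json.loads((data / "toy_spec.json").read_text()))
model = LinearModel.from_json(json.loads((data / "toy_model.json").read_text()))

print(f"target predicted logS range: {spec.target_range}")
result = infer(spec, model)
print(f"status: {result.status}  (variables={result.n_vars}, "
      f"constraints={result.n_cons}, branches={result.n_branches}, "
      f"{result.seconds:.2f}s)")
g = result.graph
print(f"inferred molecule: {g.n_heavy()} heavy atoms, formula counts "
      f"{dict(g.formula_counts())}")
print(f"predicted logS = {result.predicted:.4f}")
vec = featurize(g, spec.rho)
print(f"re-verified prediction = {model.predict_vector(vec):.4f} (exactness check)")
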