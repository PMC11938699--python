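# invqspr

Predicting aqueous solubility (logS) of small molecules from deterministic
graph-theoretic descriptors — and running the prediction backwards:
inferring a novel, chemically valid molecular graph whose *predicted*
solubility lands inside a user-chosen range, under a prescribed structural
template, by mixed-integer linear programming.

The package is aimed at cheminformatics practitioners who want an inverse
QSPR workflow whose every step is exact and auditable: no fingerprints, no
3D descriptors, no neural networks — only counts on a labeled graph, a
linear model, and an MILP whose feasible points correspond one-to-one with
admissible molecules.

## The model in brief

A compound is a *chemical graph* ℂ = (H, α, β): a simple connected graph
with element labels α, bond multiplicities β ∈ {1,2,3}, and per-vertex
hydrogen counts.  For a height parameter ρ (default 2), the graph splits
into an **exterior** — the pendant fragments of height < ρ, i.e. terminal
functional groups, each forming a rooted *ρ-fringe tree* — and an
**interior**, everything else.  The descriptor vector f(ℂ) collects:

- heavy-atom count n, rank (cyclomatic number) r, interior size,
  average scaled atomic mass over all atoms including hydrogens;
- interior vertex counts by degree d ∈ {1..4}, in the full
  hydrogen-suppressed graph and in the interior-induced subgraph;
- interior double/triple bond counts;
- element frequencies in interior and exterior;
- *edge-configurations* (a d, b d′, m) over interior edges,
  *fringe-configurations* (canonical strings of the ρ-fringe trees), and
  *adjacency-configurations* (a, b, m) over leaf edges.

A prediction function η(f(ℂ)) = b₀ + Σ w·f(ℂ) is fit by ordinary least
squares after greedy forward stepwise selection (FSP) scored by
cross-validated R²; leave-one-out and repeated 5-fold protocols are
provided, along with LASSO-based selection (`LLR-LLR`) and the named
strategy bundles (`MLR`, `MLR-LOO`, `FSP-MLR`, `FSP-MLR-LOO`,
`FSP-LOO-MLR`, `LLR-LLR`).

For the inverse direction, a *topological specification* gives a seed
graph (some edges "typical", replaceable by paths of bounded length), a
catalog F of chemical rooted fringe trees, and count bounds.  The MILP
chooses path lengths, one fringe tree per interior vertex, and bond
multiplicities, with every selected descriptor linked to those choices by
exact linear constraints and the target constraint
y* ≤ η(f(ℂ)) ≤ ȳ*.  Decoded solutions are re-featurized and verified —
the formulation is feasible iff an admissible molecule exists.  The solver
is HiGHS (via `scipy.optimize.milp`).

## Worked example

The running example throughout the package is
3-(3-ethylcyclopentyl)propanoic acid (C10H18O2, PubChem CID 20849290),
available both as `invqspr.worked_compound()` and as a packaged SDF
fixture.

```python
>>> from invqspr import worked_compound, featurize
>>> v = featurize(worked_compound(), rho=2)
>>> v["n_heavy"], v["rank"], v["n_interior"], round(v["average_mass"], 3)
(12, 1, 7, 56.667)
>>> {k: v[k] for k in v if k.startswith("elt_ext:")}
{'elt_ext:C': 3, 'elt_ext:O': 2}
>>> {k: v[k] for k in v if k.startswith("ec:")}
{'ec:C2C3_1': 5, 'ec:C2C2_1': 2}
```

Twelve heavy atoms, one ring; the interior (7 vertices) is the
cyclopentane ring plus the first two chain carbons, and the exterior is
the carboxyl group and the ethyl tail — 3 carbons and 2 oxygens spread
over four distinct fringe-tree shapes.  The average mass is
(10·120 + 18·10 + 2·160)/30 = 56.667 in scaled units (10× atomic mass).

Inverse design, end to end (`examples/infer_molecule.py`):

```text
target predicted logS range: (-2.0, -1.5)
status: FEASIBLE  (variables=8, constraints=11, branches=4, 0.00s)
inferred molecule: 6 heavy atoms, formula counts {'C': 6, 'H': 14}
predicted logS = -1.5200
re-verified prediction = -1.5200 (exactness check)
```

The `examples/` directory holds one short script per capability
(featurization, strategy comparison, dataset generation, inverse design),
and the `invqspr` console command exposes the same steps as subcommands
(`featurize`, `preprocess`, `select`, `train`, `eval`, `infer`,
`gendata`).

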