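# Methods

## Chemical-graph model

Molecules are hydrogen-suppressed labeled graphs: vertices carry an
element symbol and an explicit hydrogen count, edges a bond multiplicity
in {1, 2, 3}.  Validity requires simplicity, connectivity, and at every
vertex Σ(incident multiplicities) + hcount ≤ valence(element), with the
fixed valence table C:4, N:3, O:2, P:5, S:6, halogens:1, H:1.  Sulfur is
admitted at its maximal valence; aromatic perception, charges, stereo-
chemistry and isotopes are out of scope.  Masses are scaled integers,
round(10 × standard atomic weight) (C → 120, H → 10, O → 160, …); the
average-mass descriptor divides the summed scaled mass of *all* atoms,
hydrogens included, by the total atom count.  This is the unique simple
convention under which the reference compound C10H18O2 averages
(10·120 + 18·10 + 2·160)/30 = 56.667.

SDF (V2000) input and output go through RDKit with sanitization disabled;
explicit hydrogen atoms are folded into the per-vertex counts on read and
expanded again on write.  A one-graph-per-file plain-text edge-list format
(`n m` header, vertex lines, edge lines) is provided for fixtures.

## Two-layer decomposition

For height parameter ρ ≥ 1 (default 2, matching the fringe-tree height
used throughout), a vertex is **exterior** iff it is removed within ρ
rounds of iterative leaf pruning of the hydrogen-suppressed graph —
equivalently, iff the pendant subtree hanging at it has height < ρ.  The
remaining **interior** is connected whenever the molecule is; each
exterior vertex hangs from a unique interior root, giving one rooted
ρ-fringe tree per interior vertex (possibly just the root and its
hydrogens).  The pruning formulation handles cyclic and acyclic molecules
uniformly: for a simple ring nothing is pruned, for a path of 2ρ+1 heavy
atoms only the middle vertex survives.  Molecules small enough that
everything prunes away have an empty interior; all interior-indexed
descriptors are then zero and no fringe trees exist.

Fringe trees are encoded canonically in AHU style: preorder tokens
`<mark><element><depth>` where the mark records a double (`=`) or triple
(`#`) bond to the parent; heavy children are ordered by element rank
(C < N < O < P < S < F < Cl < Br < I), then by canonical substring, and
hydrogen leaves sort last.  Two rooted labeled trees receive equal strings
iff they are isomorphic (tested against a graph-isomorphism oracle).

## Descriptors

The 14 scalar descriptors are: heavy-atom count, rank |E|−|V|+1, interior
size, average mass, four interior-vertex counts by hydrogen-suppressed
degree 1–4, four by degree within the interior-induced subgraph, and the
interior double- and triple-bond counts.  The degree-1..4 bins
deliberately count **interior** vertices only: that is the reading which
reproduces the reference compound's published values ((0,5,2,0) rather
than the (3,5,3,1) an all-vertex count would give).  A degree-0 vertex (a
singleton interior) falls outside the 1–4 bins by construction.

The keyed families — interior/exterior element frequencies,
edge-configurations (endpoint (element, degree) pairs ordered by element
rank then degree, plus multiplicity) over interior edges,
fringe-configurations (canonical strings), and adjacency-configurations
over leaf edges — are stored sparsely.  Dataset schemas list the scalars
first and then each family sorted by key string, so feature matrices are
bit-for-bit reproducible; the schema of a dataset is the union of keys
observed in it, and matrices fill unobserved keys with zero.

## Learning

MLR is ordinary least squares (scikit-learn `LinearRegression`, SVD-based
with minimum-norm coefficients on rank-deficient designs).  R² is the
standard 1 − SSres/SStot; zero-variance targets are rejected, and hugely
negative values (unregularized wide designs under LOOV) are legal outputs.
LOOV pools the n held-out predictions into a single R² and is
seed-independent; repeated k-fold (default 10×5) reports the **median** of
the per-test-fold R² values, folds drawn with seed base+repeat.

Forward stepwise selection starts empty and, per iteration, scores every
unselected descriptor by the evaluation protocol applied to MLR on the
augmented set — the same protocol object, hence identical folds across
candidates within an iteration, for comparability.  Ties break toward the
earlier schema column.  It stops at `max_k` additions or when the best
one-step improvement is below `tol` (default 1e-4), returning the best
trajectory prefix.  LASSO selection standardizes columns and keeps
descriptors with nonzero coefficients, choosing the penalty by a 5-fold
CV grid when not supplied.  Note that the LASSO-predicting strategy
(`LLR-LLR`) cannot reach R² = 1 even on noiseless data: shrinkage bias
keeps it marginally below, which the tests account for.

LOOV-based strategies refuse datasets above 150 samples by default
(overridable), reflecting their intended use on small collections.

## Synthetic data

The random-molecule generator grows a uniformly random spanning tree
under valence and heavy-degree-≤4 caps over a C/O/N/S palette
(probabilities 0.75/0.12/0.10/0.03), optionally closes one ring
(probability 0.4), upgrades bonds to double/triple where spare valence
allows (probability 0.15), and fills every remaining valence slot with
hydrogen.  Molecule sizes are uniform on 6–18 heavy atoms.  These defaults
produce small drug-like-ish organics; the generator does **not** emulate
aromatic systems, charge states, realistic functional-group frequencies,
or the property distribution of any curated solubility collection — so
passing recovery tests demonstrates correctness of the machinery on
linear ground truth, not predictive accuracy on real measurements.
Dataset ground truth is y = b₀ + Σ w·descriptor + N(0, σ) over
user-chosen descriptor names; a plain numeric planted-regression
generator (iid standard-normal design) exercises the selection machinery
at exactly controlled sparsity.  All generators are pure functions of
their seeds.

## Inverse design

A topological specification prescribes: a connected seed graph whose
vertices become interior vertices (optionally element-fixed, optionally
with restricted fringe choices); fixed and *typical* edges, the latter
replaceable by a path of length ℓ ∈ [ℓLB, ℓUB] whose internal vertices
also take catalog fringes; per-edge admissible multiplicities; a finite
catalog F of rooted fringe trees with explicit hydrogen counts at every
node (root included); global heavy-atom bounds, per-descriptor bounds,
and the target range [y*, ȳ*].

Catalog trees carry their root hydrogen count explicitly rather than
deriving it from valence slack at decode: slack-derived root hydrogens
would make a fringe tree's configuration depend on the root's interior
degree, destroying the linearity of the fringe-configuration link.  A
helper fills non-root hydrogens to full valence, matching the usual
convention of drawing only root hydrogens.

One MILP is built per assignment of typical-edge path lengths (their
product is expected to be small; specifications are templates, not open
searches).  Within a branch the interior topology is fixed, so interior
size, rank, and interior-degree counts are constants, and the remaining
choices — one fringe tree per site, one multiplicity per edge — are
one-hot binaries.  Degree-dependent descriptors use per-edge oriented
configuration binaries y[e, (class_u, class_v, m)] tied to the endpoint
choices and the multiplicity by ≤-constraints plus a one-hot row; since
the endpoint class indicators are themselves one-hot sums, exactly one
configuration per edge can be active, making every edge- and
adjacency-configuration count an exact linear expression.  Valence rows
couple interior multiplicities with each chosen root's bond sum and
hydrogen count.  When the model uses average mass, the total atom count
is additionally fixed per sub-branch (one MILP per candidate total),
keeping the mass ratio linear — the branch count is bounded by the spread
of catalog atom counts and refused beyond 500.

Interior vertices that are leaves of the interior pendant forest are
restricted to fringe trees of height exactly ρ.  This is the condition
under which re-decomposing the decoded molecule reproduces the prescribed
interior: a pendant interior vertex survives leaf pruning for ρ rounds
iff the subtree hanging below it has height ≥ ρ, and by induction a
height-ρ fringe at every pendant leaf gives every pendant interior vertex
hanging height ≥ ρ, while every fringe vertex at depth δ has hanging
height ≤ ρ − δ < ρ and is pruned.  Cyclic-core vertices are never pruned.
Consequently a vertex of interior degree 1 always ends with full degree
≥ 2, so leaf edges occur only inside fringe trees.

Solving uses HiGHS through `scipy.optimize.milp`; branches are solved in
order (first feasible wins for feasibility queries; all branches for
max/min objectives).  Decoding instantiates paths, elements,
multiplicities and grafted fringe trees, with hydrogen counts taken from
the catalog entries; the decoded graph must pass full chemical-graph
validation.  Verification then re-featurizes the decoded molecule with
the ordinary descriptor pipeline and requires every model descriptor to
equal its MILP linear expression (exactly for counts, 1e-6 for average
mass) and the recomputed prediction to lie in the target range; `infer`
never returns an unverified graph.  A brute-force enumerator over the
same choice space, computing predictions through the full featurization
pipeline rather than the MILP algebra, serves as the independent
feasibility oracle in the tests.

Numerical choices: solution integrality tolerance 1e-6 at decode;
zero-width and even flipped target ranges are rejected at specification
validation; a zero time limit returns a TIME_LIMIT status rather than
crashing.

## Problem sizes used in the shipped checks

The enumeration-agreement checks use three specifications whose search
spaces hold between a handful and a few hundred candidate molecules, with
20 random target ranges each (widths 0.05–1.05 log units, including the
narrow 0.05-unit windows).  Stepwise-recovery checks use n = 200 samples
over 60 descriptors with a planted 3-descriptor model at noise σ = 0.1,
across 10 seeded replicates.  These sizes were chosen so the full suite
re-runs in well under a minute of MILP time while still exercising every
constraint family.

## Known limitations

- The specification class covers seed-graph + path-expansion + catalog
  fringe trees; constructions that change the rank beyond the seed graph
  (e.g. growing new rings) are not expressible, and models selecting
  `rank` are handled by constant substitution per branch.
- Interior structure is prescribed, not searched: two specifications are
  needed to compare two interior shapes (though typical edges give
  bounded families in one call).
- Fringe-configuration strings follow this package's canonical grammar;
  catalogs built elsewhere must be re-canonicalized through
  `invqspr.twolayer.canonical_string`.
- No aromatic bond model: aromatic rings must be written in a Kekulé
  form.
- Path-length and atom-count branching enumerate products of choices;
  specifications with many simultaneous wide typical edges will multiply
  branches and are better split by the caller.
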