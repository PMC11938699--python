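"""Graph-theoretic descriptors of chemical graphs under the two-layer model.

The descriptor vector of a molecule consists of 14 scalar descriptors —
heavy-atom count, rank (cyclomatic number), interior size, average atomic
mass, interior-vertex degree counts taken in the full hydrogen-suppressed
graph and in the interior-induced subgraph, and interior double/triple bond
counts — followed by sparse keyed families: element frequencies in the
interior and exterior, edge-configurations over interior edges,
fringe-configurations over the rho-fringe trees, and adjacency-
configurations over leaf edges.

Note on the degree descriptors: the four "degree d" counts are computed
over *interior* vertices using their degree in the full hydrogen-suppressed
graph (this is the reading consistent with the worked reference values),
and the next four over the interior-induced subgraph.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .chemgraph import ELEMENT_RANK, MASS10, ChemicalGraph, rank
from .twolayer import TwoLayerDecomposition, decompose, fringe_config_counts

__all__ = [
    "SCALAR_NAMES",
    "FAMILY_PREFIXES",
    "average_mass",
    "degree_counts",
    "interior_bond_counts",
    "element_frequencies",
    "edge_config_counts",
    "adjacency_config_counts",
    "featurize",
    "featurize_dataset",
    "schema_sort_key",
]

SCALAR_NAMES: tuple[str, ...] = (
    "n_heavy",
    "rank",
    "n_interior",
    "average_mass",
    "n_deg1", "n_deg2", "n_deg3", "n_deg4",
    "n_int_deg1", "n_int_deg2", "n_int_deg3", "n_int_deg4",
    "n_double_int", "n_triple_int",
)

#: Keyed-family prefixes in schema order.
FAMILY_PREFIXES: tuple[str, ...] = ("elt_int:", "elt_ext:", "ec:", "fc:", "ac:")


def average_mass(g: ChemicalGraph) -> float:
    """Mean scaled atomic mass over all atoms, hydrogens included."""
    total = sum(MASS10[s] for s in g.element.values()) + 10 * sum(g.hcount.values())
    return total / g.n_atoms()


def degree_counts(
    g: ChemicalGraph, d: TwoLayerDecomposition
) -> tuple[tuple[int, int, int, int], tuple[int, int, int, int]]:
    """(interior vertices by full-graph degree 1..4,
    interior vertices by interior-subgraph degree 1..4)."""
    full = Counter(g.degree(v) for v in d.interior)
    int_edges = d.interior_edges(g)
    ideg = Counter()
    for u, v in int_edges:
        ideg[u] += 1
        ideg[v] += 1
    induced = Counter(ideg[v] for v in d.interior)
    return (
        tuple(full.get(k, 0) for k in (1, 2, 3, 4)),
        tuple(induced.get(k, 0) for k in (1, 2, 3, 4)),
    )


def interior_bond_counts(g: ChemicalGraph, d: TwoLayerDecomposition) -> tuple[int, int]:
    """(double, triple) bond counts over interior-interior edges."""
    doubles = triples = 0
    for e in d.interior_edges(g):
        m = g.bond[e]
        if m == 2:
            doubles += 1
        elif m == 3:
            triples += 1
    return doubles, triples


def element_frequencies(
    g: ChemicalGraph, d: TwoLayerDecomposition
) -> tuple[Counter, Counter]:
    """(interior element counts, exterior element counts)."""
    return (
        Counter(g.element[v] for v in d.interior),
        Counter(g.element[v] for v in d.exterior),
    )


def _end_key(elem: str, deg: int) -> tuple[int, int]:
    return (ELEMENT_RANK.get(elem, 50), deg)


def edge_config_key(a: str, da: int, b: str, db: int, m: int) -> str:
    """Canonical edge-configuration key with (element, degree) endpoints
    ordered by element rank then degree."""
    if _end_key(a, da) > _end_key(b, db):
        a, da, b, db = b, db, a, da
    return f"{a}{da}{b}{db}_{m}"


def adjacency_config_key(a: str, b: str, m: int) -> str:
    if ELEMENT_RANK.get(a, 50) > ELEMENT_RANK.get(b, 50):
        a, b = b, a
    return f"{a}{b}_{m}"


def edge_config_counts(g: ChemicalGraph, d: TwoLayerDecomposition) -> Counter:
    """Configurations (a d, b d', m) over interior-interior edges; degrees
    are taken in the full hydrogen-suppressed graph."""
    out: Counter = Counter()
    for u, v in d.interior_edges(g):
        out[edge_config_key(g.element[u], g.degree(u), g.element[v], g.degree(v), g.bond[(u, v) if u < v else (v, u)])] += 1
    return out


def adjacency_config_counts(g: ChemicalGraph) -> Counter:
    """Configurations (a, b, m) over leaf edges — edges with a degree-1
    endpoint in the hydrogen-suppressed graph."""
    out: Counter = Counter()
    for (u, v), m in g.bond.items():
        if g.degree(u) == 1 or g.degree(v) == 1:
            out[adjacency_config_key(g.element[u], g.element[v], m)] += 1
    return out


def featurize(g: ChemicalGraph, rho: int = 2) -> dict[str, float]:
    """Full descriptor vector of one molecule (sparse: only observed
    configuration keys appear)."""
    g.validate()
    d = decompose(g, rho)
    (f1, f2, f3, f4), (i1, i2, i3, i4) = degree_counts(g, d)
    dbl, trp = interior_bond_counts(g, d)
    elt_int, elt_ext = element_frequencies(g, d)
    vec: dict[str, float] = {
        "n_heavy": g.n_heavy(),
        "rank": rank(g),
        "n_interior": len(d.interior),
        "average_mass": average_mass(g),
        "n_deg1": f1, "n_deg2": f2, "n_deg3": f3, "n_deg4": f4,
        "n_int_deg1": i1, "n_int_deg2": i2, "n_int_deg3": i3, "n_int_deg4": i4,
        "n_double_int": dbl, "n_triple_int": trp,
    }
    for sym, c in elt_int.items():
        vec[f"elt_int:{sym}"] = c
    for sym, c in elt_ext.items():
        vec[f"elt_ext:{sym}"] = c
    for key, c in edge_config_counts(g, d).items():
        vec[f"ec:{key}"] = c
    for key, c in fringe_config_counts(d).items():
        vec[f"fc:{key}"] = c
    for key, c in adjacency_config_counts(g).items():
        vec[f"ac:{key}"] = c
    return vec


def schema_sort_key(name: str) -> tuple[int, str]:
    """Stable schema order: scalars first (fixed order), then each keyed
    family sorted by key string."""
    if name in SCALAR_NAMES:
        return (SCALAR_NAMES.index(name), "")
    for i, prefix in enumerate(FAMILY_PREFIXES):
        if name.startswith(prefix):
            return (len(SCALAR_NAMES) + i, name)
    raise KeyError(f"unknown descriptor name {name!r}")


def featurize_dataset(
    graphs, rho: int = 2
) -> tuple[pd.DataFrame, list[str]]:
    """Featurize a list of molecules under a shared schema.

    Returns the feature matrix (row order = input order; unobserved keys
    filled with 0) and the ordered schema.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("cannot featurize an empty dataset")
    rows = [featurize(g, rho) for g in graphs]
    names = set()
    for r in rows:
        names.update(r)
    schema = sorted(names, key=schema_sort_key)
    frame = pd.DataFrame(
        [[r.get(n, 0) for n in schema] for r in rows],
        columns=schema,
        index=[g.id if g.id is not None else i for i, g in enumerate(graphs)],
    )
    return frame, schema
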