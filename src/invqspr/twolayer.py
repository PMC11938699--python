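"""Two-layer (interior/exterior) decomposition and rho-fringe trees.

For a height parameter ``rho`` the exterior of a molecule consists of the
pendant fragments of height < rho — chemically, the terminal functional
groups — and the interior is everything else.  Each interior vertex roots a
*rho-fringe tree*: itself plus the exterior subtree (and hydrogens) hanging
from it, of height at most rho counting heavy atoms only.

Operationally a vertex is exterior iff it is removed within ``rho`` rounds
of iterative leaf pruning of the hydrogen-suppressed graph; this is
equivalent to its pendant height being < rho and handles cyclic and acyclic
molecules uniformly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .chemgraph import ELEMENT_RANK, ChemicalGraph

__all__ = [
    "FringeNode",
    "TwoLayerDecomposition",
    "pendant_height",
    "decompose",
    "fringe_config_counts",
    "canonical_string",
    "psi",
    "tree_height",
]

_BOND_MARK = {1: "", 2: "=", 3: "#"}


@dataclass
class FringeNode:
    """Node of a rooted fringe tree: element, attached hydrogens, and heavy
    children each with the multiplicity of the bond connecting them."""

    element: str
    hcount: int = 0
    children: list[tuple[int, "FringeNode"]] = field(default_factory=list)


def psi(element: str, hcount: int = 0, children: list[tuple[int, FringeNode]] | None = None) -> FringeNode:
    """Terse constructor for catalog fringe trees."""
    return FringeNode(element, hcount, list(children or []))


def tree_height(node: FringeNode) -> int:
    """Height counting heavy atoms only (a bare root has height 0)."""
    if not node.children:
        return 0
    return 1 + max(tree_height(c) for _, c in node.children)


def canonical_string(node: FringeNode, depth: int = 0, mult: int = 1) -> str:
    """AHU-style canonical encoding of a rooted labeled fringe tree.

    Tokens are ``<mark><element><depth>`` in preorder, where ``mark`` is
    ``=``/``#`` for double/triple bonds to the parent.  Heavy children are
    ordered by (element rank, canonical substring); hydrogens sort last.
    Two rooted trees are isomorphic iff their canonical strings are equal.
    """
    mark = "" if depth == 0 else _BOND_MARK[mult]
    token = f"{mark}{node.element}{depth}"
    subs = sorted(
        (canonical_string(c, depth + 1, m) for m, c in node.children),
        key=lambda s: (ELEMENT_RANK.get(s.lstrip("=#")[0:2].rstrip("0123456789"), 50), s),
    )
    h = [f"H{depth + 1}"] * node.hcount
    parts = [token, *subs, *h]
    return " ".join(parts)


@dataclass
class TwoLayerDecomposition:
    rho: int
    interior: set[int]
    exterior: set[int]
    fringe_tree: dict[int, FringeNode]

    def interior_edges(self, g: ChemicalGraph) -> list[tuple[int, int]]:
        return [e for e in g.bond if e[0] in self.interior and e[1] in self.interior]

    def interior_degree(self, g: ChemicalGraph, v: int) -> int:
        """Degree of interior vertex v in the interior-induced subgraph."""
        return sum(1 for e in self.interior_edges(g) if v in e)


def _prune_rounds(g: ChemicalGraph) -> dict[int, int]:
    """Round (1-based) at which each vertex is removed by iterative leaf
    pruning; vertices never removed (the cyclic core) are absent."""
    adj = {v: set(ns) for v, ns in g.adjacency().items()}
    rounds: dict[int, int] = {}
    r = 0
    while adj:
        r += 1
        leaves = [v for v, ns in adj.items() if len(ns) <= 1]
        if not leaves:
            break  # cyclic core reached
        for v in leaves:
            rounds[v] = r
        for v in leaves:
            for u in adj.pop(v):
                adj.get(u, set()).discard(v)
    return rounds


def pendant_height(g: ChemicalGraph, v: int) -> int:
    """Height of the maximal pendant subtree rooted at v, hydrogens excluded.

    Undefined (raises) for vertices of the cyclic core.
    """
    rounds = _prune_rounds(g)
    if v not in rounds:
        raise ValueError(f"vertex {v} lies on the cyclic core; pendant height undefined")
    return rounds[v] - 1


def decompose(g: ChemicalGraph, rho: int) -> TwoLayerDecomposition:
    """Partition ``g`` into interior and exterior and extract fringe trees."""
    if rho < 1:
        raise ValueError("rho must be a positive integer")
    g.validate()
    rounds = _prune_rounds(g)
    exterior = {v for v, r in rounds.items() if r <= rho}
    interior = set(g.element) - exterior

    fringe: dict[int, FringeNode] = {}
    if interior:
        adj = g.adjacency()

        def build(v: int, parent: int) -> FringeNode:
            node = FringeNode(g.element[v], g.hcount.get(v, 0))
            kids = [u for u in adj[v] if u != parent and u in exterior]
            # exterior children are strictly shallower (larger is impossible):
            # a pruned child of v was removed before v could become a leaf.
            for u in sorted(kids):
                node.children.append((g.multiplicity(v, u), build(u, v)))
            return node

        for root in sorted(interior):
            node = FringeNode(g.element[root], g.hcount.get(root, 0))
            for u in sorted(adj[root]):
                if u in exterior and _parent_of(u, root, rounds, adj):
                    node.children.append((g.multiplicity(root, u), build(u, root)))
            fringe[root] = node
    return TwoLayerDecomposition(rho, interior, exterior, fringe)


def _parent_of(u: int, root: int, rounds: dict[int, int], adj: dict[int, list[int]]) -> bool:
    """True iff exterior vertex u hangs from ``root`` (its unique neighbor
    surviving longer than u)."""
    ru = rounds[u]
    survivors = [w for w in adj[u] if rounds.get(w, 10**9) > ru]
    return survivors == [root]


def fringe_config_counts(d: TwoLayerDecomposition) -> Counter:
    """Multiset of canonical fringe-tree strings, one per interior vertex."""
    return Counter(canonical_string(t) for t in d.fringe_tree.values())
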