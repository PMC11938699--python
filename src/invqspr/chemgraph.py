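"""Chemical graphs: hydrogen-suppressed labeled graphs with explicit H counts.

A molecule is modeled as a simple connected undirected graph whose vertices
carry a chemical element label and a count of attached hydrogens, and whose
edges carry a bond multiplicity in {1, 2, 3}.  All structural computations
(degrees, cycles, decompositions) are performed on the hydrogen-suppressed
graph; hydrogens enter only through the per-vertex ``hcount`` and the
average-mass descriptor.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "VALENCE",
    "MASS10",
    "ELEMENT_RANK",
    "ChemicalGraph",
    "ValidationError",
    "ParseError",
    "rank",
    "preprocess_filter",
    "read_sdf",
    "write_sdf",
    "read_edgelist",
    "write_edgelist",
]

#: Maximum valence per element.  S is treated at its maximum (6); halogens
#: and hydrogen are monovalent.
VALENCE: dict[str, int] = {
    "H": 1,
    "C": 4,
    "N": 3,
    "O": 2,
    "P": 5,
    "S": 6,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
}

#: Scaled integer atomic masses: round(10 x standard atomic weight).
MASS10: dict[str, int] = {
    "H": 10,
    "C": 120,
    "N": 140,
    "O": 160,
    "F": 190,
    "P": 310,
    "S": 321,
    "Cl": 355,
    "Br": 799,
    "I": 1269,
}

#: Canonical element order used for all configuration keys; hydrogen last.
ELEMENT_RANK: dict[str, int] = {
    "C": 0, "N": 1, "O": 2, "P": 3, "S": 4,
    "F": 5, "Cl": 6, "Br": 7, "I": 8, "H": 99,
}


class ValidationError(ValueError):
    """A graph violates the chemical-graph invariants."""


class ParseError(ValueError):
    """A structure file could not be parsed."""


def _ekey(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u <= v else (v, u)


@dataclass
class ChemicalGraph:
    """Hydrogen-suppressed molecular graph.

    Parameters
    ----------
    element:
        Map vertex id -> element symbol (no ``"H"`` entries).
    hcount:
        Map vertex id -> number of attached hydrogens.
    bond:
        Map (u, v) with u < v -> bond multiplicity in {1, 2, 3}.
    id:
        Optional molecule identifier (SDF title line).
    """

    element: dict[int, str]
    hcount: dict[int, int]
    bond: dict[tuple[int, int], int]
    id: str | None = None

    def __post_init__(self) -> None:
        self.bond = {_ekey(*e): m for e, m in self.bond.items()}

    # -- basic accessors -------------------------------------------------
    @property
    def vertices(self) -> list[int]:
        return list(self.element)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return list(self.bond)

    def n_heavy(self) -> int:
        return len(self.element)

    def n_atoms(self) -> int:
        """Total atom count including hydrogens."""
        return len(self.element) + sum(self.hcount.values())

    def neighbors(self, v: int) -> list[int]:
        return [u if w == v else w for (u, w) in self.bond if v in (u, w)]

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {v: [] for v in self.element}
        for u, v in self.bond:
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def degree(self, v: int) -> int:
        """Degree in the hydrogen-suppressed graph."""
        return sum(1 for e in self.bond if v in e)

    def bond_sum(self, v: int) -> int:
        """Sum of incident bond multiplicities (hydrogens excluded)."""
        return sum(m for e, m in self.bond.items() if v in e)

    def multiplicity(self, u: int, v: int) -> int:
        return self.bond[_ekey(u, v)]

    def is_connected(self) -> bool:
        if not self.element:
            return False
        adj = self.adjacency()
        seen = {next(iter(self.element))}
        queue = deque(seen)
        while queue:
            for w in adj[queue.popleft()]:
                if w not in seen:
                    seen.add(w)
                    queue.append(w)
        return len(seen) == len(self.element)

    def formula_counts(self) -> Counter:
        """Atom counts by element, hydrogens included."""
        counts = Counter(self.element.values())
        counts["H"] = sum(self.hcount.values())
        if counts["H"] == 0:
            del counts["H"]
        return counts

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        for v, sym in self.element.items():
            if sym == "H" or sym not in VALENCE:
                raise ValidationError(f"vertex {v}: element {sym!r} not in valence table")
            if self.hcount.get(v, 0) < 0:
                raise ValidationError(f"vertex {v}: negative hydrogen count")
        for (u, v), m in self.bond.items():
            if u == v:
                raise ValidationError(f"self-loop at vertex {u}")
            if u not in self.element or v not in self.element:
                raise ValidationError(f"edge ({u},{v}) references unknown vertex")
            if m not in (1, 2, 3):
                raise ValidationError(f"edge ({u},{v}): bad multiplicity {m}")
        for v in self.element:
            used = self.bond_sum(v) + self.hcount.get(v, 0)
            cap = VALENCE[self.element[v]]
            if used > cap:
                raise ValidationError(
                    f"vertex {v} ({self.element[v]}): valence {used} exceeds {cap}"
                )
        if not self.is_connected():
            raise ValidationError("graph is not connected")

    def copy(self) -> "ChemicalGraph":
        return ChemicalGraph(dict(self.element), dict(self.hcount), dict(self.bond), self.id)

    def relabel(self, mapping: dict[int, int]) -> "ChemicalGraph":
        """Return an isomorphic copy with vertex ids renamed by ``mapping``."""
        return ChemicalGraph(
            {mapping[v]: s for v, s in self.element.items()},
            {mapping[v]: h for v, h in self.hcount.items()},
            {_ekey(mapping[u], mapping[v]): m for (u, v), m in self.bond.items()},
            self.id,
        )


def rank(g: ChemicalGraph) -> int:
    """Cyclomatic number |E| - |V| + 1 of the hydrogen-suppressed graph."""
    if not g.is_connected():
        raise ValidationError("rank is defined for connected graphs only")
    return len(g.bond) - len(g.element) + 1


def preprocess_filter(
    graphs: Iterable[ChemicalGraph],
) -> tuple[list[ChemicalGraph], list[tuple[ChemicalGraph, str]]]:
    """Keep compounds that are connected, have >= 4 carbons, and whose atoms
    all have at most 4 non-hydrogen neighbors; return (kept, rejected+reason)."""
    kept: list[ChemicalGraph] = []
    rejected: list[tuple[ChemicalGraph, str]] = []
    for g in graphs:
        if not g.is_connected():
            rejected.append((g, "graph not connected"))
            continue
        n_carbon = sum(1 for s in g.element.values() if s == "C")
        if n_carbon < 4:
            rejected.append((g, "carbon count < 4"))
            continue
        if any(g.degree(v) > 4 for v in g.element):
            rejected.append((g, "atom with more than 4 non-hydrogen neighbors"))
            continue
        kept.append(g)
    return kept, rejected


# ---------------------------------------------------------------------------
# SDF V2000 I/O (via RDKit)
# ---------------------------------------------------------------------------

def _to_rdkit(g: ChemicalGraph):
    from rdkit import Chem

    mol = Chem.RWMol()
    idx: dict[int, int] = {}
    for v in sorted(g.element):
        a = Chem.Atom(g.element[v])
        a.SetNoImplicit(True)
        idx[v] = mol.AddAtom(a)
    order = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for (u, v), m in g.bond.items():
        mol.AddBond(idx[u], idx[v], order[m])
    for v in sorted(g.element):
        for _ in range(g.hcount.get(v, 0)):
            h = Chem.Atom("H")
            h.SetNoImplicit(True)
            hi = mol.AddAtom(h)
            mol.AddBond(idx[v], hi, Chem.BondType.SINGLE)
    out = mol.GetMol()
    if g.id is not None:
        out.SetProp("_Name", str(g.id))
    return out


def _from_rdkit(mol, record: int) -> ChemicalGraph:
    from rdkit import Chem

    element: dict[int, str] = {}
    hcount: dict[int, int] = {}
    bond: dict[tuple[int, int], int] = {}
    vid: dict[int, int] = {}
    nxt = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "H":
            continue
        if sym not in VALENCE:
            raise ValidationError(
                f"record {record}: element {sym!r} not in valence table"
            )
        vid[atom.GetIdx()] = nxt
        element[nxt] = sym
        hcount[nxt] = atom.GetNumExplicitHs()
        nxt += 1
    for b in mol.GetBonds():
        ai, bi = b.GetBeginAtom(), b.GetEndAtom()
        m = b.GetBondTypeAsDouble()
        if ai.GetSymbol() == "H" and bi.GetSymbol() == "H":
            raise ParseError(f"record {record}: H-H bond unsupported")
        if ai.GetSymbol() == "H" or bi.GetSymbol() == "H":
            heavy = bi if ai.GetSymbol() == "H" else ai
            hcount[vid[heavy.GetIdx()]] += 1
            continue
        if m not in (1.0, 2.0, 3.0):
            raise ParseError(
                f"record {record}: unsupported bond order {m} (aromatic perception is out of scope)"
            )
        bond[_ekey(vid[ai.GetIdx()], vid[bi.GetIdx()])] = int(m)
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
    g = ChemicalGraph(element, hcount, bond, id=name or None)
    g.validate()
    return g


def read_sdf(path) -> list[ChemicalGraph]:
    """Read a V2000 SDF; explicit hydrogens are folded into ``hcount``."""
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    with open(path) as fh:
        if not fh.read().strip():
            return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    graphs: list[ChemicalGraph] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"malformed SDF record {i} in {path}")
        graphs.append(_from_rdkit(mol, i))
    return graphs


def write_sdf(graphs: Sequence[ChemicalGraph], path) -> None:
    """Write V2000 records with hydrogens made explicit."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for g in graphs:
        writer.write(_to_rdkit(g))
    writer.close()


# ---------------------------------------------------------------------------
# Auxiliary edge-list text format (fixtures)
# ---------------------------------------------------------------------------

def read_edgelist(path) -> ChemicalGraph:
    """Read the plain-text fixture format: header ``n m``, then ``id element
    hcount`` lines, then ``u v multiplicity`` lines."""
    with open(path) as fh:
        lines = [ln.split("#")[0].strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    try:
        n, m = map(int, lines[0].split())
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: bad header line") from exc
    if len(lines) != 1 + n + m:
        raise ParseError(f"{path}: expected {1 + n + m} lines, found {len(lines)}")
    element: dict[int, str] = {}
    hcount: dict[int, int] = {}
    for ln in lines[1 : 1 + n]:
        vid, sym, hc = ln.split()
        element[int(vid)] = sym
        hcount[int(vid)] = int(hc)
    bond: dict[tuple[int, int], int] = {}
    for ln in lines[1 + n :]:
        u, v, mult = map(int, ln.split())
        bond[_ekey(u, v)] = mult
    g = ChemicalGraph(element, hcount, bond)
    g.validate()
    return g


def write_edgelist(g: ChemicalGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(g.element)} {len(g.bond)}\n")
        for v in sorted(g.element):
            fh.write(f"{v} {g.element[v]} {g.hcount.get(v, 0)}\n")
        for (u, v), m in sorted(g.bond.items()):
            fh.write(f"{u} {v} {m}\n")
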