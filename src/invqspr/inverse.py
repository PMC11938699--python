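"""MILP-based inference of chemical graphs with a prescribed structure and
a predicted property value inside a target range.

A *topological specification* prescribes the interior of the target
molecule as a seed graph whose *typical* edges may be replaced by paths of
bounded length, together with a finite catalog of rooted fringe trees, one
of which is attached at every interior vertex, and global count bounds.
Given a linear prediction function over the two-layer descriptors, the
builder emits mixed-integer linear programs whose feasible points are in
one-to-one correspondence with the admissible chemical graphs: every
selected descriptor is linked to the decision variables by exact linear
constraints, so a decoded solution always re-featurizes to the same
descriptor values and its recomputed prediction lies in the target range
(decode-and-verify exactness).

Path-length choices (and, when the average-mass descriptor is used, the
total atom count) are handled by enumerating one MILP per choice, which
keeps every descriptor exactly linear.  Interior vertices that are leaves
of the interior pendant forest are restricted to fringe trees of height
exactly rho; this guarantees that re-decomposing the decoded graph
reproduces the prescribed interior.

The solver backend is HiGHS via :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import itertools
import time
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint
from scipy.optimize import milp as _scipy_milp

from .chemgraph import VALENCE, MASS10, ChemicalGraph, ValidationError
from .descriptors import (
    SCALAR_NAMES,
    adjacency_config_key,
    edge_config_key,
    featurize,
)
from .learn import LinearModel
from .twolayer import FringeNode, canonical_string, decompose, tree_height, psi

__all__ = [
    "SeedEdge",
    "TopologicalSpec",
    "InferenceResult",
    "MILP",
    "UnsupportedDescriptorError",
    "ExactnessError",
    "build_milp",
    "build_milps",
    "solve",
    "decode",
    "verify",
    "infer",
    "enumerate_candidates",
    "brute_force_infer",
    "fill_hydrogens",
]

FEASIBLE = "FEASIBLE"
INFEASIBLE = "INFEASIBLE"
TIME_LIMIT = "TIME_LIMIT"


class UnsupportedDescriptorError(ValueError):
    """The prediction function uses a descriptor the specification cannot
    express as a linear function of the decision variables."""


class ExactnessError(RuntimeError):
    """A decoded solution disagreed with its MILP descriptor variables."""


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

def fill_hydrogens(node: FringeNode, is_root: bool = False, parent_mult: int = 1) -> FringeNode:
    """Complete every non-root node of a catalog tree to full valence with
    hydrogens (the usual drawing convention omits them); the root hydrogen
    count is left as given, since the root also carries interior bonds."""
    used = parent_mult * (0 if is_root else 1) + sum(m for m, _ in node.children)
    hc = node.hcount if is_root else VALENCE[node.element] - used
    if hc < 0:
        raise ValidationError(f"fringe node {node.element}: bonds exceed valence")
    return FringeNode(node.element, hc, [(m, fill_hydrogens(c, False, m)) for m, c in node.children])


@dataclass(frozen=True)
class _FringeStats:
    """Per-catalog-entry constants used by the linear linking."""

    index: int
    element: str
    height: int
    heavy: int
    atoms: int
    mass: int
    root_bond: int
    root_hc: int
    ext_elements: tuple[tuple[str, int], ...]
    leaf_adj: tuple[tuple[str, int], ...]
    config: str


def _validate_fringe(node: FringeNode, is_root: bool = True, parent_mult: int = 0) -> None:
    used = parent_mult + sum(m for m, _ in node.children) + node.hcount
    cap = VALENCE[node.element]
    if used > cap:
        raise ValidationError(
            f"catalog fringe node {node.element}: valence {used} exceeds {cap}"
        )
    for m, c in node.children:
        _validate_fringe(c, False, m)


def _fringe_stats(i: int, t: FringeNode) -> _FringeStats:
    _validate_fringe(t)
    heavy = atoms = mass = 0
    ext: Counter = Counter()
    adj: Counter = Counter()

    def walk(node: FringeNode, is_root: bool) -> None:
        nonlocal heavy, atoms, mass
        heavy += 1
        atoms += 1 + node.hcount
        mass += MASS10[node.element] + 10 * node.hcount
        if not is_root:
            ext[node.element] += 1
        for m, c in node.children:
            if not c.children:  # heavy leaf => leaf edge of the full graph
                adj[adjacency_config_key(node.element, c.element, m)] += 1
            walk(c, False)

    walk(t, True)
    return _FringeStats(
        index=i,
        element=t.element,
        height=tree_height(t),
        heavy=heavy,
        atoms=atoms,
        mass=mass,
        root_bond=sum(m for m, _ in t.children),
        root_hc=t.hcount,
        ext_elements=tuple(sorted(ext.items())),
        leaf_adj=tuple(sorted(adj.items())),
        config=canonical_string(t),
    )


@dataclass
class SeedEdge:
    """Seed-graph edge.  ``kind='typical'`` edges are replaced by a path of
    length in ``lengths`` (length 1 keeps the edge); internal path vertices
    draw their fringe tree from ``path_fringes`` (catalog indices, default
    all)."""

    u: int
    v: int
    kind: str = "fixed"
    lengths: tuple[int, int] = (1, 1)
    mults: tuple[int, ...] = (1,)
    path_fringes: list[int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "typical"):
            raise ValueError(f"edge kind {self.kind!r}")
        if self.kind == "fixed":
            self.lengths = (1, 1)
        if self.lengths[0] < 1 or self.lengths[0] > self.lengths[1]:
            raise ValueError("path length bounds must satisfy 1 <= lLB <= lUB")
        if any(m not in (1, 2, 3) for m in self.mults):
            raise ValueError("bond multiplicities must lie in {1,2,3}")


@dataclass
class TopologicalSpec:
    """Seed graph + typical edges + fringe catalog + bounds + target range."""

    seed_vertices: list[int]
    seed_edges: list[SeedEdge]
    catalog: list[FringeNode]
    target_range: tuple[float, float]
    rho: int = 2
    element_fix: dict[int, str] = field(default_factory=dict)
    site_fringes: dict[int, list[int]] = field(default_factory=dict)
    n_range: tuple[int, int] | None = None
    descriptor_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.seed_vertices) < 2:
            raise ValueError("seed graph needs at least 2 vertices")
        if not self.catalog:
            raise ValueError("fringe-tree catalog must be non-empty")
        if self.target_range[0] > self.target_range[1]:
            raise ValueError("target range is empty (lower bound above upper)")
        if self.rho < 1:
            raise ValueError("rho must be >= 1")
        vs = set(self.seed_vertices)
        adj: dict[int, set[int]] = {v: set() for v in vs}
        for e in self.seed_edges:
            if e.u not in vs or e.v not in vs or e.u == e.v:
                raise ValueError(f"bad seed edge ({e.u},{e.v})")
            adj[e.u].add(e.v)
            adj[e.v].add(e.u)
        seen = {self.seed_vertices[0]}
        stack = [self.seed_vertices[0]]
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if seen != vs:
            raise ValueError("seed graph is not connected")
        for t in self.catalog:
            _validate_fringe(t)
            if tree_height(t) > self.rho:
                raise ValueError("catalog fringe tree taller than rho")

    def stats(self) -> list[_FringeStats]:
        return [_fringe_stats(i, t) for i, t in enumerate(self.catalog)]


# ---------------------------------------------------------------------------
# Interior topologies (one per assignment of typical-edge path lengths)
# ---------------------------------------------------------------------------

@dataclass
class _Topology:
    vertices: list[int]
    edges: list[tuple[int, int, tuple[int, ...]]]  # (u, v, allowed multiplicities)
    site_allowed: dict[int, list[int]]             # vertex -> catalog indices
    lengths: dict[int, int]                        # typical-edge index -> chosen length

    def intdeg(self, v: int) -> int:
        return sum(1 for (a, b, _) in self.edges if v in (a, b))

    @property
    def rank(self) -> int:
        return len(self.edges) - len(self.vertices) + 1


def _topologies(spec: TopologicalSpec, stats: list[_FringeStats]):
    """Yield one interior topology per combination of path lengths, with
    per-site allowed fringe subsets already filtered."""
    typical = [i for i, e in enumerate(spec.seed_edges) if e.kind == "typical"]
    ranges = [range(spec.seed_edges[i].lengths[0], spec.seed_edges[i].lengths[1] + 1) for i in typical]
    next_id = max(spec.seed_vertices) + 1

    for combo in itertools.product(*ranges) if typical else [()]:
        vid = next_id
        vertices = list(spec.seed_vertices)
        edges: list[tuple[int, int, tuple[int, ...]]] = []
        site_allowed: dict[int, list[int]] = {}
        lengths = dict(zip(typical, combo))
        for idx, e in enumerate(spec.seed_edges):
            if e.kind == "fixed" or lengths.get(idx, 1) == 1:
                edges.append((e.u, e.v, e.mults))
                continue
            path = [e.u]
            for _ in range(lengths[idx] - 1):
                vertices.append(vid)
                site_allowed[vid] = list(e.path_fringes if e.path_fringes is not None else range(len(stats)))
                path.append(vid)
                vid += 1
            path.append(e.v)
            for a, b in zip(path, path[1:]):
                edges.append((a, b, e.mults))
        topo = _Topology(vertices, edges, site_allowed, lengths)
        for v in spec.seed_vertices:
            allowed = list(spec.site_fringes.get(v, range(len(stats))))
            if v in spec.element_fix:
                allowed = [i for i in allowed if stats[i].element == spec.element_fix[v]]
            topo.site_allowed[v] = allowed
        # interior pendant leaves must carry height-rho fringes so that the
        # decoded graph re-decomposes to exactly this interior
        for v in topo.vertices:
            if topo.intdeg(v) <= 1:
                topo.site_allowed[v] = [
                    i for i in topo.site_allowed[v] if stats[i].height == spec.rho
                ]
            if not topo.site_allowed[v]:
                break
        else:
            yield topo


# ---------------------------------------------------------------------------
# MILP construction
# ---------------------------------------------------------------------------

@dataclass
class MILP:
    spec: TopologicalSpec
    topology: _Topology
    stats: list[_FringeStats]
    c: np.ndarray
    rows: np.ndarray
    row_lb: np.ndarray
    row_ub: np.ndarray
    var_names: list[str]
    x_index: dict[tuple[int, int], int]
    b_index: dict[tuple[int, int], int]
    expr_cache: dict[str, tuple[np.ndarray, float]]
    atom_total: int | None = None

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    @property
    def n_cons(self) -> int:
        return len(self.rows)

    def expression_value(self, name: str, solution: np.ndarray) -> float:
        coef, const = self.expr_cache[name]
        return float(coef @ solution + const)


def _interior_degree_counts(topo: _Topology) -> tuple[int, int, int, int]:
    c = Counter(topo.intdeg(v) for v in topo.vertices)
    return tuple(c.get(k, 0) for k in (1, 2, 3, 4))


class _Builder:
    def __init__(self, spec: TopologicalSpec, topo: _Topology, stats: list[_FringeStats],
                 model: LinearModel, atom_total: int | None):
        self.spec, self.topo, self.stats, self.model = spec, topo, stats, model
        self.atom_total = atom_total
        self.var_names: list[str] = []
        self.x_index: dict[tuple[int, int], int] = {}
        self.b_index: dict[tuple[int, int], int] = {}
        self.y_index: dict[tuple[int, tuple], int] = {}
        self.rows: list[np.ndarray] = []
        self.row_lb: list[float] = []
        self.row_ub: list[float] = []

    def _new_var(self, name: str) -> int:
        self.var_names.append(name)
        return len(self.var_names) - 1

    # -- endpoint (element, full-degree) classes -------------------------
    def _classes(self, v: int) -> dict[tuple[str, int], list[int]]:
        out: dict[tuple[str, int], list[int]] = {}
        dv = self.topo.intdeg(v)
        for i in self.topo.site_allowed[v]:
            s = self.stats[i]
            out.setdefault((s.element, dv + s.root_bond), []).append(i)
        return out

    def build(self) -> MILP:
        topo, stats = self.topo, self.stats
        for v in topo.vertices:
            if not topo.site_allowed[v]:
                raise ValueError(f"no admissible fringe tree at interior vertex {v}")
            for i in topo.site_allowed[v]:
                self.x_index[(v, i)] = self._new_var(f"x[{v},{i}]")
        for e_idx, (u, v, mults) in enumerate(topo.edges):
            for m in mults:
                self.b_index[(e_idx, m)] = self._new_var(f"b[{e_idx},{m}]")
        # oriented edge-configuration choice variables
        self.edge_combos: dict[int, list[tuple]] = {}
        for e_idx, (u, v, mults) in enumerate(topo.edges):
            combos = []
            for pu in self._classes(u):
                for pv in self._classes(v):
                    for m in mults:
                        combos.append((pu, pv, m))
            self.edge_combos[e_idx] = combos
            for cmb in combos:
                self.y_index[(e_idx, cmb)] = self._new_var(f"y[{e_idx},{cmb}]")

        nv = len(self.var_names)
        self._nv = nv

        # one-hot choices
        for v in topo.vertices:
            row = np.zeros(nv)
            for i in topo.site_allowed[v]:
                row[self.x_index[(v, i)]] = 1
            self._add(row, 1, 1)
        for e_idx, (_, _, mults) in enumerate(topo.edges):
            row = np.zeros(nv)
            for m in mults:
                row[self.b_index[(e_idx, m)]] = 1
            self._add(row, 1, 1)

        # valence coupling at interior vertices
        for v in topo.vertices:
            row = np.zeros(nv)
            for e_idx, (a, b, mults) in enumerate(topo.edges):
                if v in (a, b):
                    for m in mults:
                        row[self.b_index[(e_idx, m)]] += m
            for i in topo.site_allowed[v]:
                s = stats[i]
                row[self.x_index[(v, i)]] += s.root_bond + s.root_hc - VALENCE[s.element]
            self._add(row, -np.inf, 0)

        # edge-configuration linking: one-hot + consistency with endpoints
        for e_idx, (u, v, mults) in enumerate(topo.edges):
            row = np.zeros(nv)
            for cmb in self.edge_combos[e_idx]:
                row[self.y_index[(e_idx, cmb)]] = 1
            self._add(row, 1, 1)
            cls_u, cls_v = self._classes(u), self._classes(v)
            for cmb in self.edge_combos[e_idx]:
                pu, pv, m = cmb
                yj = self.y_index[(e_idx, cmb)]
                for (vertex, cls, p) in ((u, cls_u, pu), (v, cls_v, pv)):
                    row = np.zeros(nv)
                    row[yj] = 1
                    for i in cls[p]:
                        row[self.x_index[(vertex, i)]] -= 1
                    self._add(row, -np.inf, 0)
                row = np.zeros(nv)
                row[yj] = 1
                row[self.b_index[(e_idx, m)]] -= 1
                self._add(row, -np.inf, 0)

        # fixed total atom count (average-mass branch)
        if self.atom_total is not None:
            coef = np.zeros(nv)
            for (v, i), j in self.x_index.items():
                coef[j] = stats[i].atoms
            self._add(coef, self.atom_total, self.atom_total)

        # descriptor expression cache for the model + bounds
        self.expr_cache: dict[str, tuple[np.ndarray, float]] = {}
        needed = set(self.model.weights) | set(self.spec.descriptor_bounds)
        if self.spec.n_range is not None:
            needed.add("n_heavy")
        for name in sorted(needed):
            self.expr_cache[name] = self._expression(name)

        # global bounds
        if self.spec.n_range is not None:
            coef, const = self.expr_cache["n_heavy"]
            self._add(coef, self.spec.n_range[0] - const, self.spec.n_range[1] - const)
        for name, (lb, ub) in self.spec.descriptor_bounds.items():
            coef, const = self.expr_cache[name]
            self._add(coef, lb - const, ub - const)

        # prediction constraint: y* <= eta(f(C)) <= y-bar*
        pred_coef = np.zeros(nv)
        pred_const = self.model.intercept
        for name, w in self.model.weights.items():
            coef, const = self.expr_cache[name]
            pred_coef += w * coef
            pred_const += w * const
        lo, hi = self.spec.target_range
        self._add(pred_coef, lo - pred_const, hi - pred_const)
        self.expr_cache["__prediction__"] = (pred_coef, pred_const)

        return MILP(
            spec=self.spec, topology=topo, stats=stats,
            c=np.zeros(nv),
            rows=np.array(self.rows) if self.rows else np.zeros((0, nv)),
            row_lb=np.array(self.row_lb), row_ub=np.array(self.row_ub),
            var_names=self.var_names,
            x_index=self.x_index, b_index=self.b_index,
            expr_cache=self.expr_cache,
            atom_total=self.atom_total,
        )

    def _add(self, row: np.ndarray, lb: float, ub: float) -> None:
        self.rows.append(row)
        self.row_lb.append(lb)
        self.row_ub.append(ub)

    # -- linear expression of each supported descriptor ------------------
    def _expression(self, name: str) -> tuple[np.ndarray, float]:
        topo, stats, nv = self.topo, self.stats, self._nv
        coef = np.zeros(nv)
        const = 0.0
        if name == "n_interior":
            return coef, float(len(topo.vertices))
        if name == "rank":
            return coef, float(topo.rank)
        if name.startswith("n_int_deg"):
            d = int(name[-1])
            return coef, float(_interior_degree_counts(topo)[d - 1])
        if name == "n_heavy":
            const = len(topo.vertices)
            for (v, i), j in self.x_index.items():
                coef[j] = stats[i].heavy - 1
            return coef, float(const)
        if name.startswith("n_deg"):
            d = int(name[-1])
            for v in topo.vertices:
                for (elem, deg), idxs in self._classes(v).items():
                    if deg == d:
                        for i in idxs:
                            coef[self.x_index[(v, i)]] += 1
            return coef, 0.0
        if name == "n_double_int" or name == "n_triple_int":
            m = 2 if name == "n_double_int" else 3
            for (e_idx, mm), j in self.b_index.items():
                if mm == m:
                    coef[j] = 1
            return coef, 0.0
        if name.startswith("elt_int:"):
            sym = name.split(":", 1)[1]
            for (v, i), j in self.x_index.items():
                if stats[i].element == sym:
                    coef[j] = 1
            return coef, 0.0
        if name.startswith("elt_ext:"):
            sym = name.split(":", 1)[1]
            for (v, i), j in self.x_index.items():
                coef[j] = dict(stats[i].ext_elements).get(sym, 0)
            return coef, 0.0
        if name.startswith("fc:"):
            key = name.split(":", 1)[1]
            for (v, i), j in self.x_index.items():
                if stats[i].config == key:
                    coef[j] = 1
            return coef, 0.0
        if name.startswith("ec:"):
            key = name.split(":", 1)[1]
            for (e_idx, cmb), j in self.y_index.items():
                (a, da), (b, db), m = cmb
                if edge_config_key(a, da, b, db, m) == key:
                    coef[j] = 1
            return coef, 0.0
        if name.startswith("ac:"):
            key = name.split(":", 1)[1]
            for (v, i), j in self.x_index.items():
                coef[j] = dict(stats[i].leaf_adj).get(key, 0)
            for (e_idx, cmb), j in self.y_index.items():
                (a, da), (b, db), m = cmb
                if (da == 1 or db == 1) and adjacency_config_key(a, b, m) == key:
                    coef[j] += 1
            return coef, 0.0
        if name == "average_mass":
            if self.atom_total is None:
                raise UnsupportedDescriptorError(
                    "average_mass requires atom-count branching (internal error)"
                )
            for (v, i), j in self.x_index.items():
                coef[j] = stats[i].mass / self.atom_total
            return coef, 0.0
        raise UnsupportedDescriptorError(
            f"descriptor {name!r} cannot be linked under this specification"
        )


def _atom_total_range(topo: _Topology, stats: list[_FringeStats]) -> tuple[int, int]:
    lo = sum(min(stats[i].atoms for i in topo.site_allowed[v]) for v in topo.vertices)
    hi = sum(max(stats[i].atoms for i in topo.site_allowed[v]) for v in topo.vertices)
    return lo, hi


def build_milps(spec: TopologicalSpec, model: LinearModel, schema=None) -> list[MILP]:
    """All MILP branches for the specification: one per typical-edge
    path-length assignment (times one per total atom count when the model
    uses average mass)."""
    spec.validate()
    if schema is not None:
        missing = [n for n in model.weights if n not in schema]
        if missing:
            raise UnsupportedDescriptorError(f"model descriptors absent from schema: {missing}")
    stats = spec.stats()
    uses_mass = "average_mass" in model.weights or "average_mass" in spec.descriptor_bounds
    out: list[MILP] = []
    for topo in _topologies(spec, stats):
        if uses_mass:
            lo, hi = _atom_total_range(topo, stats)
            if hi - lo > 500:
                raise UnsupportedDescriptorError(
                    "average_mass branching range too large for this specification"
                )
            totals: list[int | None] = list(range(lo, hi + 1))
        else:
            totals = [None]
        for t in totals:
            out.append(_Builder(spec, topo, stats, model, t).build())
    if not out:
        raise ValueError("specification admits no interior topology "
                         "(no admissible fringe trees at some interior leaf)")
    return out


def build_milp(spec: TopologicalSpec, model: LinearModel, schema=None) -> MILP:
    """First MILP branch (convenience; see :func:`build_milps`)."""
    return build_milps(spec, model, schema)[0]


# ---------------------------------------------------------------------------
# Solve / decode / verify / infer
# ---------------------------------------------------------------------------

@dataclass
class SolveOutcome:
    status: str
    values: np.ndarray | None
    objective: float | None
    seconds: float


def solve(milp: MILP, time_limit: float = 300.0, objective: str = "feasible") -> SolveOutcome:
    """Solve one branch with HiGHS.  ``objective`` is 'feasible', 'max' or
    'min' (of the predicted property)."""
    c = np.zeros(milp.n_vars)
    if objective in ("max", "min"):
        coef, _ = milp.expr_cache["__prediction__"]
        c = -coef if objective == "max" else coef.copy()
    elif objective != "feasible":
        raise ValueError(f"unknown objective {objective!r}")
    t0 = time.perf_counter()
    res = _scipy_milp(
        c=c,
        constraints=[LinearConstraint(milp.rows, milp.row_lb, milp.row_ub)],
        integrality=np.ones(milp.n_vars),
        bounds=Bounds(0, 1),
        options={"time_limit": max(time_limit, 0.0), "presolve": True},
    )
    dt = time.perf_counter() - t0
    if res.status == 0:
        return SolveOutcome(FEASIBLE, np.asarray(res.x), float(res.fun), dt)
    if res.status == 2:
        return SolveOutcome(INFEASIBLE, None, None, dt)
    if res.status == 1:
        return SolveOutcome(TIME_LIMIT, None, None, dt)
    return SolveOutcome(TIME_LIMIT if "time" in (res.message or "").lower() else INFEASIBLE,
                        None, None, dt)


def decode(values: np.ndarray, milp: MILP) -> ChemicalGraph:
    """Instantiate the chemical graph encoded by a feasible solution."""
    tol = 1e-6
    if np.any(np.abs(values - np.round(values)) > tol):
        raise ExactnessError("non-integral solution values beyond tolerance")
    values = np.round(values)
    topo, stats, cat = milp.topology, milp.stats, milp.spec.catalog

    chosen_fringe: dict[int, int] = {}
    for (v, i), j in milp.x_index.items():
        if values[j] == 1:
            chosen_fringe[v] = i
    chosen_mult: dict[int, int] = {}
    for (e_idx, m), j in milp.b_index.items():
        if values[j] == 1:
            chosen_mult[e_idx] = m
    if set(chosen_fringe) != set(topo.vertices) or set(chosen_mult) != set(range(len(topo.edges))):
        raise ExactnessError("solution does not encode a complete choice")

    element: dict[int, str] = {}
    hcount: dict[int, int] = {}
    bond: dict[tuple[int, int], int] = {}
    for v in topo.vertices:
        t = cat[chosen_fringe[v]]
        element[v] = t.element
        hcount[v] = t.hcount
    for e_idx, (u, v, _) in enumerate(topo.edges):
        bond[(u, v) if u < v else (v, u)] = chosen_mult[e_idx]

    next_id = max(topo.vertices) + 1

    def graft(parent_id: int, node: FringeNode) -> None:
        nonlocal next_id
        for m, child in node.children:
            cid = next_id
            next_id += 1
            element[cid] = child.element
            hcount[cid] = child.hcount
            bond[(parent_id, cid) if parent_id < cid else (cid, parent_id)] = m
            graft(cid, child)

    for v in topo.vertices:
        graft(v, cat[chosen_fringe[v]])

    g = ChemicalGraph(element, hcount, bond, id="inferred")
    g.validate()
    return g


@dataclass
class InferenceResult:
    status: str
    graph: ChemicalGraph | None = None
    predicted: float | None = None
    n_vars: int = 0
    n_cons: int = 0
    seconds: float = 0.0
    n_branches: int = 0
    solver: str = "highs"


def verify(result: InferenceResult, spec: TopologicalSpec, model: LinearModel,
           milp: MILP | None = None, values: np.ndarray | None = None) -> dict:
    """Independently featurize the decoded graph and check exactness.

    Every descriptor selected by the model must equal its MILP linear
    expression exactly (counts) or to 1e-6 (average mass), and the
    recomputed prediction must lie in the target range.  Raises
    :class:`ExactnessError` on any violation.
    """
    if result.status != FEASIBLE or result.graph is None:
        raise ValueError("verify requires a FEASIBLE result with a decoded graph")
    vec = featurize(result.graph, spec.rho)
    report: dict[str, tuple[float, float]] = {}
    if milp is not None and values is not None:
        for name in model.weights:
            milp_val = milp.expression_value(name, values)
            true_val = float(vec.get(name, 0.0))
            report[name] = (true_val, milp_val)
            tol = 1e-6 if name == "average_mass" else 1e-9
            if abs(true_val - milp_val) > tol:
                raise ExactnessError(
                    f"descriptor {name!r}: featurized {true_val} != MILP {milp_val}"
                )
    pred = model.predict_vector(vec)
    lo, hi = spec.target_range
    if not (lo - 1e-6 <= pred <= hi + 1e-6):
        raise ExactnessError(f"recomputed prediction {pred} outside [{lo}, {hi}]")
    if result.predicted is not None and abs(pred - result.predicted) > 1e-6:
        raise ExactnessError("recomputed prediction disagrees with MILP objective value")
    report["__prediction__"] = (pred, result.predicted if result.predicted is not None else pred)
    return report


def infer(spec: TopologicalSpec, model: LinearModel, schema=None,
          time_limit: float = 300.0, objective: str = "feasible") -> InferenceResult:
    """build -> solve -> decode -> verify; never returns an unverified graph.

    Branches (path lengths, atom totals) are solved in order; with
    ``objective='feasible'`` the first feasible branch wins, otherwise all
    branches are solved and the best objective value is returned.
    """
    milps = build_milps(spec, model, schema)
    total_time = 0.0
    hit_limit = False
    best: tuple[float, MILP, SolveOutcome] | None = None
    nv = nc = 0
    for m in milps:
        out = solve(m, time_limit=time_limit, objective=objective)
        total_time += out.seconds
        nv, nc = max(nv, m.n_vars), max(nc, m.n_cons)
        if out.status == TIME_LIMIT:
            hit_limit = True
            continue
        if out.status != FEASIBLE:
            continue
        pred = m.expression_value("__prediction__", out.values)
        if objective == "feasible":
            best = (pred, m, out)
            break
        keyed = -pred if objective == "max" else pred
        if best is None or keyed < (-best[0] if objective == "max" else best[0]):
            best = (pred, m, out)
    if best is None:
        status = TIME_LIMIT if hit_limit else INFEASIBLE
        return InferenceResult(status, n_vars=nv, n_cons=nc,
                               seconds=total_time, n_branches=len(milps))
    pred, m, out = best
    graph = decode(out.values, m)
    result = InferenceResult(
        FEASIBLE, graph=graph, predicted=pred,
        n_vars=m.n_vars, n_cons=m.n_cons,
        seconds=total_time, n_branches=len(milps),
    )
    verify(result, spec, model, m, out.values)
    return result


# ---------------------------------------------------------------------------
# Spec (de)serialization for config files
# ---------------------------------------------------------------------------

def fringe_to_json(node: FringeNode) -> dict:
    return {
        "element": node.element,
        "hcount": node.hcount,
        "children": [[m, fringe_to_json(c)] for m, c in node.children],
    }


def fringe_from_json(obj: dict) -> FringeNode:
    return FringeNode(
        obj["element"], int(obj.get("hcount", 0)),
        [(int(m), fringe_from_json(c)) for m, c in obj.get("children", [])],
    )


def spec_to_json(spec: TopologicalSpec) -> dict:
    return {
        "seed_vertices": spec.seed_vertices,
        "seed_edges": [
            {"u": e.u, "v": e.v, "kind": e.kind, "lengths": list(e.lengths),
             "mults": list(e.mults), "path_fringes": e.path_fringes}
            for e in spec.seed_edges
        ],
        "catalog": [fringe_to_json(t) for t in spec.catalog],
        "target_range": list(spec.target_range),
        "rho": spec.rho,
        "element_fix": {str(k): v for k, v in spec.element_fix.items()},
        "site_fringes": {str(k): v for k, v in spec.site_fringes.items()},
        "n_range": list(spec.n_range) if spec.n_range else None,
        "descriptor_bounds": {k: list(v) for k, v in spec.descriptor_bounds.items()},
    }


def spec_from_json(obj: dict) -> TopologicalSpec:
    spec = TopologicalSpec(
        seed_vertices=[int(v) for v in obj["seed_vertices"]],
        seed_edges=[
            SeedEdge(int(e["u"]), int(e["v"]), e.get("kind", "fixed"),
                     tuple(e.get("lengths", (1, 1))), tuple(e.get("mults", (1,))),
                     e.get("path_fringes"))
            for e in obj["seed_edges"]
        ],
        catalog=[fringe_from_json(t) for t in obj["catalog"]],
        target_range=tuple(obj["target_range"]),
        rho=int(obj.get("rho", 2)),
        element_fix={int(k): v for k, v in obj.get("element_fix", {}).items()},
        site_fringes={int(k): list(v) for k, v in obj.get("site_fringes", {}).items()},
        n_range=tuple(obj["n_range"]) if obj.get("n_range") else None,
        descriptor_bounds={k: tuple(v) for k, v in obj.get("descriptor_bounds", {}).items()},
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_candidates(spec: TopologicalSpec):
    """Yield every chemical graph admitted by the specification's
    combinatorial choices (before bounds / target filtering), with its
    descriptor vector.  Intended for small search spaces."""
    spec.validate()
    stats = spec.stats()
    cat = spec.catalog
    for topo in _topologies(spec, stats):
        sites = topo.vertices
        edge_mults = [mults for (_, _, mults) in topo.edges]
        for fringe_choice in itertools.product(*(topo.site_allowed[v] for v in sites)):
            for mult_choice in itertools.product(*edge_mults):
                element = {}
                hcount = {}
                bond = {}
                ok = True
                for v, i in zip(sites, fringe_choice):
                    element[v] = cat[i].element
                    hcount[v] = cat[i].hcount
                for (u, v, _), m in zip(topo.edges, mult_choice):
                    bond[(u, v) if u < v else (v, u)] = m
                next_id = max(sites) + 1

                def graft(parent: int, node: FringeNode) -> None:
                    nonlocal next_id
                    for m, child in node.children:
                        cid = next_id
                        next_id += 1
                        element[cid] = child.element
                        hcount[cid] = child.hcount
                        bond[(parent, cid) if parent < cid else (cid, parent)] = m
                        graft(cid, child)

                for v, i in zip(sites, fringe_choice):
                    graft(v, cat[i])
                g = ChemicalGraph(element, hcount, bond)
                try:
                    g.validate()
                except ValidationError:
                    continue
                d = decompose(g, spec.rho)
                if d.interior != set(sites):
                    # should not happen under the height-rho leaf rule
                    continue
                yield g, featurize(g, spec.rho)


def brute_force_infer(spec: TopologicalSpec, model: LinearModel):
    """All admissible graphs whose bounds hold and whose prediction lies in
    the target range, as (graph, prediction) pairs — the enumeration oracle
    for MILP feasibility."""
    lo, hi = spec.target_range
    out = []
    for g, vec in enumerate_candidates(spec):
        if spec.n_range is not None and not (spec.n_range[0] <= vec["n_heavy"] <= spec.n_range[1]):
            continue
        bounds_ok = True
        for name, (blo, bhi) in spec.descriptor_bounds.items():
            val = vec.get(name, 0.0)
            if not (blo <= val <= bhi):
                bounds_ok = False
                break
        if not bounds_ok:
            continue
        pred = model.predict_vector(vec)
        if lo <= pred <= hi:
            out.append((g, pred))
    return out
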