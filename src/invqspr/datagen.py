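"""Synthetic molecule and dataset generation.

Provides seed-deterministic generators for valence-valid random chemical
graphs, linear-ground-truth solubility datasets built on the package's own
descriptors, plain numeric planted-regression problems for exercising the
selection machinery, and the hand-encoded reference compound
3-(3-ethylcyclopentyl)propanoic acid (PubChem CID 20849290).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemgraph import VALENCE, ChemicalGraph
from .descriptors import featurize_dataset

__all__ = [
    "GenConfig",
    "SyntheticDatasetSpec",
    "worked_compound",
    "random_chemgraph",
    "synthetic_dataset",
    "planted_regression",
]


def worked_compound() -> ChemicalGraph:
    """3-(3-ethylcyclopentyl)propanoic acid, C10H18O2, 12 heavy atoms.

    Vertices 0-4: cyclopentane ring (0 carries the propanoic-acid chain,
    2 the ethyl group); 5-7: chain CH2-CH2-C(=O)OH with carboxyl carbon 7;
    8 (=O) and 9 (OH) the carboxyl oxygens; 10-11 the ethyl CH2-CH3.
    """
    element = {v: "C" for v in range(8)} | {8: "O", 9: "O", 10: "C", 11: "C"}
    hcount = {0: 1, 1: 2, 2: 1, 3: 2, 4: 2, 5: 2, 6: 2, 7: 0, 8: 0, 9: 1, 10: 2, 11: 3}
    bond = {
        (0, 1): 1, (1, 2): 1, (2, 3): 1, (3, 4): 1, (0, 4): 1,  # ring
        (0, 5): 1, (5, 6): 1, (6, 7): 1, (7, 8): 2, (7, 9): 1,  # acid chain
        (2, 10): 1, (10, 11): 1,                                 # ethyl
    }
    g = ChemicalGraph(element, hcount, bond, id="CID20849290")
    g.validate()
    return g


@dataclass
class GenConfig:
    """Parameters of the random-molecule generator."""

    n_graphs: int = 100
    heavy_range: tuple[int, int] = (6, 18)
    elements: dict[str, float] = field(
        default_factory=lambda: {"C": 0.75, "O": 0.12, "N": 0.10, "S": 0.03}
    )
    ring_prob: float = 0.4
    multi_bond_prob: float = 0.15
    triple_frac: float = 0.2  # fraction of upgraded bonds tried as triple
    seed: int = 0
    max_retries: int = 200

    def validate(self) -> None:
        total = sum(self.elements.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"element probabilities sum to {total}, expected 1")
        if any(s not in VALENCE for s in self.elements):
            raise ValueError("element palette contains symbols outside the valence table")


def _try_random_graph(cfg: GenConfig, rng: np.random.Generator) -> ChemicalGraph | None:
    n = int(rng.integers(cfg.heavy_range[0], cfg.heavy_range[1] + 1))
    symbols = list(cfg.elements)
    probs = np.array([cfg.elements[s] for s in symbols], dtype=float)
    probs /= probs.sum()
    element = {v: symbols[rng.choice(len(symbols), p=probs)] for v in range(n)}
    slots = {v: VALENCE[element[v]] for v in range(n)}
    bond: dict[tuple[int, int], int] = {}
    degree = {v: 0 for v in range(n)}
    # random spanning tree under valence and degree-4 caps
    for v in range(1, n):
        hosts = [u for u in range(v) if slots[u] >= 1 and degree[u] < 4]
        if not hosts or slots[v] < 1:
            return None
        u = hosts[int(rng.integers(len(hosts)))]
        bond[(u, v)] = 1
        slots[u] -= 1
        slots[v] -= 1
        degree[u] += 1
        degree[v] += 1
    # optional ring closure
    if rng.random() < cfg.ring_prob:
        pairs = [
            (u, v)
            for u in range(n)
            for v in range(u + 1, n)
            if (u, v) not in bond and slots[u] >= 1 and slots[v] >= 1
            and degree[u] < 4 and degree[v] < 4
        ]
        if pairs:
            u, v = pairs[int(rng.integers(len(pairs)))]
            bond[(u, v)] = 1
            slots[u] -= 1
            slots[v] -= 1
            degree[u] += 1
            degree[v] += 1
    # bond-order upgrades where both endpoints have spare valence
    for (u, v) in list(bond):
        if rng.random() < cfg.multi_bond_prob:
            want = 2 if rng.random() > cfg.triple_frac else 3
            extra = want - 1
            if slots[u] >= extra and slots[v] >= extra:
                bond[(u, v)] = want
                slots[u] -= extra
                slots[v] -= extra
    hcount = {v: slots[v] for v in range(n)}  # fill to full valence
    g = ChemicalGraph(element, hcount, bond)
    g.validate()
    return g


def random_chemgraph(cfg: GenConfig, rng: np.random.Generator | None = None) -> ChemicalGraph:
    """One connected valence-valid random molecule; deterministic in the seed."""
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    for _ in range(cfg.max_retries):
        g = _try_random_graph(cfg, rng)
        if g is not None:
            return g
    raise RuntimeError("random_chemgraph: configuration unsatisfiable after bounded retries")


def random_chemgraphs(cfg: GenConfig) -> list[ChemicalGraph]:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out = []
    for i in range(cfg.n_graphs):
        g = random_chemgraph(cfg, rng)
        g.id = f"gen{i}"
        out.append(g)
    return out


@dataclass
class SyntheticDatasetSpec:
    """Linear ground truth for solubility over named descriptors."""

    weights: dict[str, float]
    intercept: float = 0.0
    sigma: float = 0.1
    n: int = 100
    rho: int = 2
    seed: int = 0


def synthetic_dataset(
    spec: SyntheticDatasetSpec, cfg: GenConfig
) -> tuple[list[ChemicalGraph], pd.DataFrame, np.ndarray]:
    """Generate molecules and logS = intercept + sum(w * descriptor) + noise.

    Returns (graphs, feature frame, y).  Every ground-truth descriptor name
    must be realizable (present in the generated schema).
    """
    cfg = GenConfig(**{**cfg.__dict__, "n_graphs": spec.n, "seed": cfg.seed})
    graphs = random_chemgraphs(cfg)
    X, schema = featurize_dataset(graphs, spec.rho)
    missing = [k for k in spec.weights if k not in schema]
    if missing:
        raise ValueError(f"ground-truth descriptors not realized by generator: {missing}")
    rng = np.random.default_rng(spec.seed)
    y = np.full(spec.n, spec.intercept, dtype=float)
    for name, w in spec.weights.items():
        y += w * X[name].to_numpy(dtype=float)
    y += rng.normal(0.0, spec.sigma, size=spec.n)
    return graphs, X, y


def planted_regression(
    n: int,
    p: int,
    support: dict[int, float],
    sigma: float,
    seed: int,
    intercept: float = 0.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Numeric planted linear model: X ~ N(0,1) iid, y = b0 + Xw + noise.

    ``support`` maps column index -> weight.  Columns are named x0..x{p-1}.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.full(n, intercept, dtype=float)
    for j, w in support.items():
        y += w * X[:, j]
    y += rng.normal(0.0, sigma, size=n)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(p)]), y
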