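import numpy as np
import pytest

from invqspr import GenConfig, LinearModel, SeedEdge, TopologicalSpec, worked_compound
from invqspr.datagen import random_chemgraphs
from invqspr.twolayer import psi


@pytest.fixture(scope="session")
def worked():
    """3-(3-ethylcyclopentyl)propanoic acid, the hand-encoded reference."""
    return worked_compound()


@pytest.fixture(scope="session")
def random_graphs():
    """100 seed-deterministic valence-valid random molecules."""
    return random_chemgraphs(GenConfig(n_graphs=100, seed=7))


# --- shared fringe-tree catalog (rho = 2) --------------------------------
@pytest.fixture(scope="session")
def catalog():
    return [
        psi("C", 2),                                                  # 0: CH2 root
        psi("C", 3),                                                  # 1: CH3 root
        psi("C", 2, [(1, psi("C", 3))]),                              # 2: ethyl-end, height 1
        psi("C", 2, [(1, psi("C", 2, [(1, psi("C", 3))]))]),          # 3: propyl-end, height 2
        psi("C", 2, [(1, psi("C", 0, [(2, psi("O", 0)),
                                      (1, psi("O", 1))]))]),          # 4: CH2-COOH, height 2
        psi("C", 2, [(1, psi("C", 2, [(1, psi("O", 1))]))]),          # 5: CH2-CH2-OH, height 2
        psi("N", 1, [(1, psi("C", 2, [(1, psi("C", 3))]))]),          # 6: N-ethyl, height 2
        psi("C", 1, [(1, psi("C", 3)), (1, psi("C", 3))]),            # 7: isopropyl-end, height 1
        psi("C", 1),                                                  # 8: CH root (branch points)
        psi("C", 0),                                                  # 9: bare C root
    ]


@pytest.fixture(scope="session")
def toy_specs(catalog):
    """Three enumerable specifications (path, cycle, bounded) used for the
    MILP-vs-enumeration agreement checks."""
    path_spec = TopologicalSpec(
        seed_vertices=[0, 1],
        seed_edges=[SeedEdge(0, 1, "typical", lengths=(1, 3), mults=(1,))],
        catalog=catalog,
        target_range=(-50, 50),
    )
    ring_spec = TopologicalSpec(
        seed_vertices=[0, 1, 2, 3],
        seed_edges=[
            SeedEdge(0, 1, "fixed", mults=(1, 2)),
            SeedEdge(1, 2, "fixed", mults=(1,)),
            SeedEdge(0, 2, "typical", lengths=(1, 2), mults=(1,)),
            SeedEdge(0, 3, "fixed", mults=(1,)),
        ],
        catalog=catalog,
        target_range=(-50, 50),
        site_fringes={1: [0, 1, 2], 2: [0, 2]},
    )
    bounded_spec = TopologicalSpec(
        seed_vertices=[0, 1],
        seed_edges=[SeedEdge(0, 1, "typical", lengths=(2, 4), mults=(1,))],
        catalog=catalog,
        target_range=(-50, 50),
        element_fix={0: "C"},
        n_range=(5, 14),
        descriptor_bounds={"elt_ext:O": (0, 2)},
    )
    return {"path": path_spec, "ring": ring_spec, "bounded": bounded_spec}


@pytest.fixture(scope="session")
def toy_model():
    """Linear solubility surrogate over count descriptors."""
    weights = {
        "n_heavy": -0.42,
        "elt_ext:O": 1.15,
        "elt_int:N": 0.6,
        "n_double_int": -0.8,
        "ac:CC_1": 0.3,
    }
    return LinearModel(list(weights), weights, intercept=1.0)


@pytest.fixture(scope="session")
def mass_model():
    """Surrogate that exercises average-mass and constant-descriptor linking."""
    weights = {"average_mass": -0.05, "rank": 0.9, "n_interior": -0.1}
    return LinearModel(list(weights), weights, intercept=-0.2)


def admissible_predictions(spec: TopologicalSpec, model) -> list[float]:
    """Predictions of every enumerated candidate that satisfies the spec's
    global count bounds (target range ignored) — the feasibility oracle."""
    from invqspr.inverse import enumerate_candidates

    preds = []
    for _, vec in enumerate_candidates(spec):
        if spec.n_range is not None and not (
            spec.n_range[0] <= vec["n_heavy"] <= spec.n_range[1]
        ):
            continue
        if any(
            not (lo <= vec.get(name, 0.0) <= hi)
            for name, (lo, hi) in spec.descriptor_bounds.items()
        ):
            continue
        preds.append(model.predict_vector(vec))
    return preds


def respec(spec: TopologicalSpec, target) -> TopologicalSpec:
    """Copy of a spec with a different target range."""
    return TopologicalSpec(
        spec.seed_vertices, spec.seed_edges, spec.catalog, target,
        spec.rho, spec.element_fix, spec.site_fringes, spec.n_range,
        spec.descriptor_bounds,
    )
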