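"""MILP construction, solving, decoding, and decode-and-verify exactness."""

import numpy as np
import pytest

from invqspr import (
    LinearModel,
    SeedEdge,
    TopologicalSpec,
    brute_force_infer,
    build_milp,
    build_milps,
    decode,
    enumerate_candidates,
    infer,
    solve,
    spec_from_json,
    spec_to_json,
    verify,
)
from invqspr.descriptors import featurize
from invqspr.inverse import ExactnessError, UnsupportedDescriptorError
from invqspr.twolayer import psi

from conftest import admissible_predictions, respec


class TestBuild:
    def test_variable_and_constraint_counts_are_self_consistent(self, toy_specs, toy_model):
        for spec in toy_specs.values():
            for m in build_milps(spec, toy_model):
                assert m.rows.shape == (m.n_cons, m.n_vars)
                assert len(m.row_lb) == len(m.row_ub) == m.n_cons
                assert m.n_vars >= len(m.topology.vertices) + len(m.topology.edges)

    def test_model_descriptor_missing_from_schema_rejected(self, toy_specs, toy_model):
        with pytest.raises(UnsupportedDescriptorError, match="schema"):
            build_milp(toy_specs["path"], toy_model, schema=["n_heavy"])

    def test_unlinkable_descriptor_rejected(self, toy_specs):
        model = LinearModel(["nonsense"], {"nonsense": 1.0}, 0.0)
        with pytest.raises(UnsupportedDescriptorError):
            build_milp(toy_specs["path"], model)

    def test_empty_catalog_rejected(self, toy_specs):
        spec = toy_specs["path"]
        bad = TopologicalSpec(spec.seed_vertices, spec.seed_edges, [], (0, 1))
        with pytest.raises(ValueError):
            bad.validate()


class TestSolve:
    def test_flipped_range_is_rejected_as_empty(self, toy_specs):
        spec = toy_specs["path"]
        with pytest.raises(ValueError, match="empty"):
            respec(spec, (1.0, 0.0)).validate()

    def test_unattainable_range_infeasible(self, toy_specs, toy_model):
        spec = respec(toy_specs["path"], (-1e6, -1e5))
        assert infer(spec, toy_model).status == "INFEASIBLE"

    def test_zero_time_limit_reports_limit_without_crash(self, toy_specs, toy_model):
        m = build_milp(toy_specs["path"], toy_model)
        assert solve(m, time_limit=0).status == "TIME_LIMIT"


class TestInferAndVerify:
    def test_feasible_run_decodes_to_valid_graph_in_range(self, toy_specs, toy_model):
        res = infer(toy_specs["path"], toy_model)
        assert res.status == "FEASIBLE"
        res.graph.validate()
        lo, hi = toy_specs["path"].target_range
        assert lo <= res.predicted <= hi
        # re-verification from scratch agrees
        verify(res, toy_specs["path"], toy_model)

    def test_singleton_search_space_returns_unique_graph(self, catalog):
        cooh = catalog[4]
        spec = TopologicalSpec(
            [0, 1], [SeedEdge(0, 1, "fixed", mults=(1,))],
            [cooh], target_range=(-100, 100),
        )
        model = LinearModel(["n_heavy"], {"n_heavy": 1.0}, 0.0)
        res = infer(spec, model)
        assert res.status == "FEASIBLE"
        cands = list(enumerate_candidates(spec))
        assert len(cands) == 1
        assert featurize(res.graph, 2) == cands[0][1]

    def test_maximize_matches_enumeration_oracle(self, toy_specs, toy_model):
        for name in ("path", "ring"):
            spec = toy_specs[name]
            preds = [toy_model.predict_vector(v) for _, v in enumerate_candidates(spec)]
            res = infer(spec, toy_model, objective="max")
            assert res.predicted == pytest.approx(max(preds), abs=1e-9)

    def test_average_mass_model_agrees_with_oracle(self, toy_specs, mass_model):
        spec = toy_specs["ring"]
        preds = [mass_model.predict_vector(v) for _, v in enumerate_candidates(spec)]
        res = infer(spec, mass_model, objective="min")
        assert res.predicted == pytest.approx(min(preds), abs=1e-9)

    def test_widening_range_preserves_feasibility(self, toy_specs, toy_model):
        spec = toy_specs["path"]
        preds = sorted(toy_model.predict_vector(v) for _, v in enumerate_candidates(spec))
        mid = preds[len(preds) // 2]
        narrow = respec(spec, (mid - 0.01, mid + 0.01))
        wide = respec(spec, (mid - 1.0, mid + 1.0))
        assert infer(narrow, toy_model).status == "FEASIBLE"
        assert infer(wide, toy_model).status == "FEASIBLE"

    def test_verify_rejects_perturbed_decode(self, toy_specs, toy_model):
        wide = infer(toy_specs["path"], toy_model)
        spec = respec(toy_specs["path"], (wide.predicted - 0.01, wide.predicted + 0.01))
        res = infer(spec, toy_model)
        assert res.status == "FEASIBLE"
        # drop a terminal heavy atom: still a valid molecule, but its
        # prediction moves outside the narrow target range
        tampered = res.graph.copy()
        leaf = next(v for v in tampered.vertices if tampered.degree(v) == 1)
        del tampered.element[leaf], tampered.hcount[leaf]
        tampered.bond = {e: m for e, m in tampered.bond.items() if leaf not in e}
        tampered.validate()
        res.graph = tampered
        with pytest.raises(ExactnessError):
            verify(res, spec, toy_model)

    def test_decode_rejects_fractional_solution(self, toy_specs, toy_model):
        m = build_milp(toy_specs["path"], toy_model)
        values = np.full(m.n_vars, 0.5)
        with pytest.raises(ExactnessError, match="non-integral"):
            decode(values, m)

    def test_bounds_are_respected(self, toy_specs, toy_model):
        spec = toy_specs["bounded"]
        res = infer(spec, toy_model)
        if res.status == "FEASIBLE":
            vec = featurize(res.graph, 2)
            assert spec.n_range[0] <= vec["n_heavy"] <= spec.n_range[1]
            assert vec.get("elt_ext:O", 0) <= 2


class TestEnumerationAgreement:
    def test_feasibility_matches_brute_force_on_random_ranges(self, toy_specs, toy_model):
        rng = np.random.default_rng(17)
        for spec in toy_specs.values():
            cands = list(enumerate_candidates(spec))
            assert 0 < len(cands) <= 500
            preds = admissible_predictions(spec, toy_model)
            for _ in range(6):
                lo = rng.uniform(min(preds) - 0.5, max(preds) + 0.5)
                hi = lo + rng.uniform(0.05, 1.0)
                sub = respec(spec, (lo, hi))
                expect = any(lo <= p <= hi for p in preds)
                assert (infer(sub, toy_model).status == "FEASIBLE") == expect

    def test_enumerated_candidates_redecompose_to_prescribed_interior(self, toy_specs):
        """The height-rho rule at interior leaves keeps the decomposition
        of every candidate equal to the seed-prescribed interior."""
        for spec in toy_specs.values():
            for g, vec in enumerate_candidates(spec):
                g.validate()
                assert vec["n_interior"] >= len(spec.seed_vertices)


class TestSpecSerialization:
    def test_json_roundtrip_preserves_search_space(self, toy_specs):
        for spec in toy_specs.values():
            back = spec_from_json(spec_to_json(spec))
            a = sorted(str(sorted(v.items())) for _, v in enumerate_candidates(spec))
            b = sorted(str(sorted(v.items())) for _, v in enumerate_candidates(back))
            assert a == b


class TestWorkedCompoundFromSeed:
    def test_seed_with_typical_edge_reaches_the_reference_molecule(self, worked):
        """A ring seed with one typical edge expanded to a path of length 2,
        plus the right fringe trees, reconstructs the reference compound."""
        cooh_tail = psi("C", 2, [(1, psi("C", 0, [(2, psi("O", 0)), (1, psi("O", 1))]))])
        ethyl = psi("C", 1, [(1, psi("C", 2, [(1, psi("C", 3))]))])
        ch = psi("C", 1)
        ch2 = psi("C", 2)
        # seed: the cyclopentane ring (5 vertices) with a pendant chain
        # vertex attached by a typical edge expandable to length 2
        spec = TopologicalSpec(
            seed_vertices=[0, 1, 2, 3, 4, 5],
            seed_edges=[
                SeedEdge(0, 1), SeedEdge(1, 2), SeedEdge(2, 3),
                SeedEdge(3, 4), SeedEdge(0, 4),
                SeedEdge(0, 5, "typical", lengths=(1, 3), path_fringes=[1]),
            ],
            catalog=[ch, ch2, ethyl, cooh_tail],
            site_fringes={0: [0], 1: [1], 2: [2], 3: [1], 4: [1], 5: [3]},
            target_range=(-100, 100),
        )
        model = LinearModel(["n_heavy"], {"n_heavy": -1.0}, 0.0)
        hits = [
            (g, v) for g, v in enumerate_candidates(spec) if v["n_heavy"] == 12
        ]
        assert any(v == featurize(worked, 2) for _, v in hits)
        res = infer(respec(spec, (-12.5, -11.5)), model)
        assert res.status == "FEASIBLE" and res.graph.n_heavy() == 12
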