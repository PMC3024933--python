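"""Backends, shortest-pathway search, and exclusion-driven enumeration."""

import pytest

import spabbats as sp
from spabbats.constraints import build_constraints
from spabbats.solver import BacktrackingBackend, MilpBackend
from conftest import enumerate_all, make_network, prepare

BACKENDS = ["milp", "backtracking"]


@pytest.mark.parametrize("backend", BACKENDS)
class TestSolve:
    def test_single_reaction_sat(self, backend):
        net = make_network({"R1": {"g": -1, "o": 1}})
        dnet, part = prepare(net, {"g"}, {"o"})
        asg = sp.solve(build_constraints(dnet, part, k=1), backend=backend)
        assert asg.active == {"R1"}
        assert asg.magnitudes["R1"] >= 1

    def test_unreachable_target_is_unsat(self, backend):
        net = make_network({"R1": {"o": -1, "g": 1}})  # only consumes the target
        dnet, part = prepare(net, {"g"}, {"o"})
        assert sp.solve(build_constraints(dnet, part), backend=backend) is None

    def test_fixture_sat_at_k2(self, backend, glutamate):
        _, dnet, part = glutamate
        asg = sp.solve(build_constraints(dnet, part, k=2), backend=backend)
        assert len(asg.active) <= 2
        # brute-force confirms a 2-subset is feasible at all
        assert any(k == 2 for _, k in sp.brute_force_enumerate(dnet, part, k_max=2))


@pytest.mark.parametrize("backend", BACKENDS)
class TestFindShortest:
    def test_chain_has_unique_two_step_pathway(self, backend, chain):
        dnet, part = chain
        sol = sp.find_shortest(dnet, part, backend=backend)
        assert sol.active_set == {"R1", "R2"}
        assert sol.k_op == 2
        assert sp.solve(build_constraints(dnet, part, k=1), backend=backend) is None

    def test_fixture_shortest_is_two_steps(self, backend, glutamate):
        _, dnet, part = glutamate
        sol = sp.find_shortest(dnet, part, backend=backend)
        assert sol.k_op == 2

    def test_after_excluding_all_two_step_routes_aspartase_remains(self, backend, glutamate):
        fx, dnet, part = glutamate
        two_step = [s for s, k in fx.expected_pathways if k == 2]
        sol = sp.find_shortest(dnet, part, exclusions=two_step, backend=backend)
        assert sol.active_set == {"ASPB", "ANSB", "CITG", "MDH"}
        assert sol.k_op == 4

    def test_linear_descent_agrees_with_binary_search(self, backend, glutamate):
        _, dnet, part = glutamate
        a = sp.find_shortest(dnet, part, backend=backend, strategy="binary")
        b = sp.find_shortest(dnet, part, backend=backend, strategy="linear")
        assert a.k_op == b.k_op == 2


class TestEnumerate:
    def test_single_pathway_network_exhausts(self, chain):
        dnet, part = chain
        result = sp.enumerate_pathways(dnet, part)
        assert [p.active_set for p in result.pathways] == [{"R1", "R2"}]
        assert result.terminated_by == "exhausted"

    @pytest.mark.parametrize("backend", BACKENDS)
    def test_fixture_enumeration(self, backend, glutamate):
        fx, dnet, part = glutamate
        result = sp.enumerate_pathways(dnet, part, max_pathways=10, backend=backend)
        assert [(p.active_set, p.k_op) for p in result.pathways] == list(fx.expected_pathways)
        assert result.terminated_by == "exhausted"

    def test_max_pathways_prefix_matches_full_run(self, glutamate):
        _, dnet, part = glutamate
        full = sp.enumerate_pathways(dnet, part, max_pathways=10)
        for cap in (1, 2, 3):
            capped = sp.enumerate_pathways(dnet, part, max_pathways=cap)
            assert capped.terminated_by == "max_pathways"
            assert [p.active_set for p in capped.pathways] == [
                p.active_set for p in full.pathways[:cap]
            ]

    def test_k_limit_stops_before_longer_pathways(self, glutamate):
        _, dnet, part = glutamate
        result = sp.enumerate_pathways(dnet, part, k_limit=2)
        assert [p.k_op for p in result.pathways] == [2, 2, 2]
        assert result.terminated_by == "k_limit"

    def test_lengths_nondecreasing_and_superset_free(self, glutamate):
        _, dnet, part = glutamate
        result = sp.enumerate_pathways(dnet, part)
        lengths = [p.k_op for p in result.pathways]
        assert lengths == sorted(lengths)
        for i, p in enumerate(result.pathways):
            for q in result.pathways[i + 1 :]:
                assert not p.active_set <= q.active_set

    def test_minimality_certificates(self, glutamate):
        """Re-solving below each returned length, same exclusions, is UNSAT."""
        _, dnet, part = glutamate
        result = sp.enumerate_pathways(dnet, part)
        system = build_constraints(dnet, part)
        exclusions = []
        for p in result.pathways:
            constrained = system
            for k in exclusions:
                constrained = sp.add_exclusion(constrained, k)
            if p.k_op > 1:
                assert sp.solve(sp.lower_cardinality(constrained, p.k_op - 1)) is None
            exclusions.append(p.active_set)


class TestSolutionObjects:
    def test_net_production_and_magnitude_masking(self, glutamate):
        _, dnet, part = glutamate
        sol = sp.find_shortest(dnet, part)
        assert set(sol.magnitudes) == sol.active_set  # inactive a_i masked out
        for t in part.targets:
            assert sol.net_production.get(t, 0) >= 1
        for m in part.intermediates:
            assert sol.net_production.get(m, 0) >= 0

    def test_normalized_magnitudes_are_coprime(self):
        sol = sp.PathwaySolution(
            active_set={"A", "B"}, magnitudes={"A": 4, "B": 6}, k_op=2,
            net_production={},
        )
        assert sol.normalized_magnitudes == {"A": 2, "B": 3}

    def test_result_invariants_enforced(self):
        p2 = sp.PathwaySolution(active_set={"A", "B"}, magnitudes={"A": 1, "B": 1},
                                k_op=2, net_production={})
        p1 = sp.PathwaySolution(active_set={"A"}, magnitudes={"A": 1}, k_op=1,
                                net_production={})
        with pytest.raises(sp.MalformedModelError):
            sp.EnumerationResult(pathways=(p2, p1), terminated_by="exhausted")
        p3 = sp.PathwaySolution(active_set={"A", "B", "C"},
                                magnitudes={"A": 1, "B": 1, "C": 1}, k_op=3,
                                net_production={})
        with pytest.raises(sp.MalformedModelError):
            sp.EnumerationResult(pathways=(p2, p3), terminated_by="exhausted")


class TestBackendContract:
    def test_backends_cross_validate_on_reversible_network(self):
        net = make_network(
            {
                "R1": {"g": -1, "x": 2},
                "R2": {"x": -1, "o": 1},
                "R3": {"g": -1, "o": 1, "y": -1},
                "R4": {"y": 1, "x": -1},
            },
            reversible={"R2", "R4"},
        )
        dnet, part = prepare(net, {"g"}, {"o"})
        a = enumerate_all(dnet, part, a_bounds=(1, 4), backend="milp")
        b = enumerate_all(dnet, part, a_bounds=(1, 4), backend="backtracking")
        assert a == b

    def test_product_linearization_semantics(self, glutamate):
        """The effective flux term equals a_i when active and 0 when not."""
        _, dnet, part = glutamate
        sol = sp.find_shortest(dnet, part)
        recomputed = {}
        by_id = {r.id: r for r in dnet.base.reactions}
        for rid in dnet.reaction_ids:
            a_times_b = sol.magnitudes.get(rid, 0) if rid in sol.active_set else 0
            for met, c in by_id[rid].stoichiometry.items():
                recomputed[met] = recomputed.get(met, 0) + int(c) * a_times_b
        for met, v in sol.net_production.items():
            assert recomputed.get(met, 0) == v

    def test_backtracking_guard_raises_unknown(self):
        backend = BacktrackingBackend(max_reactions=2)
        net = make_network({f"R{i}": {"g": -1, "o": 1} for i in range(3)})
        dnet, part = prepare(net, {"g"}, {"o"})
        with pytest.raises(sp.SolverUnknownError):
            backend.solve(build_constraints(dnet, part))

    def test_milp_timeout_is_unknown_not_unsat(self, glutamate):
        _, dnet, part = glutamate
        backend = MilpBackend(timeout=1e-9)
        with pytest.raises(sp.SolverUnknownError):
            backend.solve(build_constraints(dnet, part))
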