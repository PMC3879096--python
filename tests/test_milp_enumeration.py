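"""Indicator machinery, integer cuts, and both enumeration schemes."""

import numpy as np
import pytest

import mcskit as mk
from mcskit.milp_enumeration import (ContinuousSystem, EnumerationState,
                                     add_exclusion_constraint,
                                     attach_indicators, em_indicator_system)
from mcskit.network_model import ValidationError
from conftest import milp_mcs, oracle_mcs, random_net, target_ge

MODES = ["bigm", "indicator"]
ALGOS = ["iterative", "fixed_size"]


def _ems(net, size_ub, **kwargs):
    snet, pairing = mk.split_reversible(net)
    state = mk.shortest_ems(snet, mk.EnumerationConfig(size_ub=size_ub, **kwargs),
                            pairing=pairing)
    return state


class TestIndicators:
    def _cont(self, n):
        return ContinuousSystem(np.zeros((1, n)), np.zeros(1), ["E"],
                                np.zeros(n), np.full(n, np.inf))

    def test_one_binary_per_column_no_pairs(self):
        isys = attach_indicators(self._cont(3), range(3))
        assert len(isys.indicators) == 3
        assert isys.pairs == []

    def test_pairs_recorded_for_split_reactions(self):
        isys = attach_indicators(self._cont(4), range(4), pairs=[(1, 2)])
        assert isys.pairs == [(1, 2)]

    def test_dual_mode_has_one_pair_per_reaction(self, branch):
        dsys = mk.build_dual_system(branch, target_ge(branch, "R5"),
                                    knockable=set(branch.reaction_ids))
        from mcskit.milp_enumeration import dual_indicator_system

        isys = dual_indicator_system(dsys)
        assert len(isys.pairs) == branch.n_reactions

    def test_negative_lower_bound_rejected(self):
        cont = self._cont(2)
        cont.lb[0] = -1.0
        with pytest.raises(ValidationError):
            attach_indicators(cont, range(2))


class TestExclusionConstraints:
    def test_empty_support_rejected(self):
        with pytest.raises(ValidationError):
            add_exclusion_constraint(EnumerationState(), set())

    def test_rows_accumulate(self):
        state = EnumerationState()
        add_exclusion_constraint(state, {"R1"})
        add_exclusion_constraint(state, {"R2", "R3"})
        assert state.exclusion_rows == [frozenset({"R1"}),
                                        frozenset({"R2", "R3"})]

    @pytest.mark.parametrize("mode", MODES)
    def test_no_superset_of_a_found_support_is_returned(self, diamond, mode):
        # after {R1} is excluded, nothing containing R1 (e.g. {R1, R4}) appears
        cuts = milp_mcs(diamond, "R4", 3, mode=mode)
        sets = [c.reactions for c in cuts]
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                assert not (a <= b or b <= a)


class TestShortestEMs:
    @pytest.mark.parametrize("mode", MODES)
    @pytest.mark.parametrize("algorithm", ALGOS)
    def test_chain_has_single_mode(self, chain, algorithm, mode):
        state = _ems(chain, 3, algorithm=algorithm, mode=mode)
        assert state.found == [frozenset({"R1", "R2", "R3"})]
        assert state.status == "infeasible" or state.status == "complete"

    @pytest.mark.parametrize("mode", MODES)
    @pytest.mark.parametrize("algorithm", ALGOS)
    def test_diamond_has_two_modes_of_size_three(self, diamond, algorithm, mode):
        state = _ems(diamond, 4, algorithm=algorithm, mode=mode)
        assert {frozenset(s) for s in state.found} == {
            frozenset({"R1", "R2", "R4"}), frozenset({"R1", "R3", "R4"})}

    def test_split_two_cycle_never_appears(self, cycle_rev):
        snet, pairing = mk.split_reversible(cycle_rev)
        state = mk.shortest_ems(snet, mk.EnumerationConfig(size_ub=6),
                                pairing=pairing)
        for sup in state.found:
            for f, b in pairing.items():
                assert not {f, b} <= sup

    @pytest.mark.parametrize("seed", [1, 7, 31])
    def test_matches_bruteforce_oracle(self, seed):
        net = random_net(seed, n_reactions=8)
        snet, pairing = mk.split_reversible(net)
        oracle = {frozenset(s) for s in
                  mk.enumerate_ems_bruteforce(snet,
                                              forbidden_pairs=pairing.items())}
        state = mk.shortest_ems(snet,
                                mk.EnumerationConfig(size_ub=snet.n_reactions),
                                pairing=pairing)
        assert {frozenset(s) for s in state.found} == oracle
        sizes = [len(s) for s in state.found]
        assert sizes == sorted(sizes)

    def test_k_shortest_prefix_of_oracle(self):
        """With a solution cap, the output is exactly the k smallest supports."""
        net = random_net(13, n_reactions=9)
        snet, pairing = mk.split_reversible(net)
        oracle = sorted((frozenset(s) for s in
                         mk.enumerate_ems_bruteforce(
                             snet, forbidden_pairs=pairing.items())), key=len)
        k = max(1, len(oracle) - 1)
        state = mk.shortest_ems(
            snet, mk.EnumerationConfig(size_ub=snet.n_reactions,
                                       max_solutions=k), pairing=pairing)
        assert len(state.found) == k
        got_sizes = sorted(len(s) for s in state.found)
        assert got_sizes == sorted(len(s) for s in oracle[:k])
        assert set(state.found) <= set(oracle)


class TestSmallestMCS:
    @pytest.mark.parametrize("mode", MODES)
    @pytest.mark.parametrize("algorithm", ALGOS)
    def test_diamond_family_in_size_order(self, diamond, algorithm, mode):
        diamond.knockable[:] = True
        cuts = milp_mcs(diamond, "R4", 3, algorithm=algorithm, mode=mode)
        assert {c.reactions for c in cuts} == {
            frozenset({"R1"}), frozenset({"R4"}), frozenset({"R2", "R3"})}
        sizes = [c.size for c in cuts]
        assert sizes == sorted(sizes)

    def test_restricted_knockable_universe(self, chain):
        target = target_ge(chain, "R3")
        problem = mk.InterventionProblem(chain, target, knockable={"R2"},
                                         max_size=1)
        cuts = mk.smallest_mcs(problem)
        assert [c.reactions for c in cuts] == [frozenset({"R2"})]

    @pytest.mark.parametrize("mode", MODES)
    def test_branch_family(self, branch, mode):
        branch.knockable[:] = True
        cuts = milp_mcs(branch, "R5", 3, mode=mode)
        assert {c.reactions for c in cuts} == {
            frozenset({"R1"}), frozenset({"R3"}), frozenset({"R5"})}

    @pytest.mark.parametrize("seed", [4, 18])
    def test_algorithms_agree_as_sets(self, seed):
        net = random_net(seed)
        rxn = net.reaction_ids[-1]
        families = {
            (algo, mode): {c.reactions
                           for c in milp_mcs(net, rxn, 3, algorithm=algo,
                                             mode=mode)}
            for algo in ALGOS for mode in MODES}
        reference = next(iter(families.values()))
        assert all(f == reference for f in families.values())

    def test_fixed_size_completes_each_class_before_advancing(self, diamond):
        diamond.knockable[:] = True
        cuts, state = mk.smallest_mcs(
            mk.InterventionProblem(diamond, target_ge(diamond, "R4"),
                                   max_size=3),
            mk.EnumerationConfig(algorithm="fixed_size", size_ub=3),
            return_state=True)
        sizes = [c.size for c in cuts]
        assert sizes == sorted(sizes)
        assert state.size_complete == {1: True, 2: True, 3: True}

    def test_monotonicity_under_target_growth(self, diamond):
        """Expanding the target polyhedron can only increase the minimal
        required cut-set size."""
        small = mk.LinearFluxConstraintSet.flux_bound(diamond, "R2", ">=", 1)
        # {r2 >= 1} is contained in {r2 + r3 >= 1}
        large = mk.LinearFluxConstraintSet.from_text(
            ["1 R2 + 1 R3 >= 1"], diamond)
        knockable = {"R2", "R3"}
        cuts_small = mk.smallest_mcs(mk.InterventionProblem(
            diamond, small, knockable=knockable, max_size=2))
        cuts_large = mk.smallest_mcs(mk.InterventionProblem(
            diamond, large, knockable=knockable, max_size=2))
        assert min(c.size for c in cuts_small) == 1
        assert min(c.size for c in cuts_large) == 2


class TestLimitsAndStatus:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            mk.EnumerationConfig(size_lb=0)
        with pytest.raises(ValidationError):
            mk.EnumerationConfig(size_lb=3, size_ub=2)
        with pytest.raises(ValidationError):
            mk.EnumerationConfig(algorithm="magic")
        with pytest.raises(ValidationError):
            mk.EnumerationConfig(mode="quantum")

    @pytest.mark.parametrize("algorithm", ALGOS)
    def test_solution_limit_status(self, diamond, algorithm):
        diamond.knockable[:] = True
        problem = mk.InterventionProblem(diamond, target_ge(diamond, "R4"),
                                         max_size=3, max_solutions=2)
        cuts, state = mk.smallest_mcs(
            problem, mk.EnumerationConfig(algorithm=algorithm, size_ub=3,
                                          max_solutions=2), return_state=True)
        assert len(cuts) == 2
        assert state.status == "solution_limit"

    def test_time_limit_reports_partial_results(self, diamond):
        diamond.knockable[:] = True
        problem = mk.InterventionProblem(diamond, target_ge(diamond, "R4"),
                                         max_size=3)
        cuts, state = mk.smallest_mcs(
            problem, mk.EnumerationConfig(size_ub=3, time_limit_s=0.0),
            return_state=True)
        assert state.status == "time_limit"
        assert not any(state.size_complete.values())

    def test_oracle_guard_and_exhaustion(self, diamond):
        # a complete sweep of every size reports completion per size class
        state = _ems(diamond, 4)
        assert all(state.size_complete.get(s, True)
                   for s in range(1, 5))
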