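"""Network representation, file formats, splitting and target validation."""

import numpy as np
import pytest

import mcskit as mk
from mcskit.network_model import (FormatError, ValidationError, flux_lp_parts,
                                  parse_equation)
from mcskit._lp import solve_lp


class TestConstruction:
    def test_chain_transcription(self, chain):
        assert chain.n_metabolites == 2
        assert chain.n_reactions == 3
        assert not chain.reversible.any()
        assert set(chain.reaction_ids) == {"R1", "R2", "R3"}

    def test_duplicate_reaction_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            mk.MetabolicNetwork(np.zeros((1, 2)), ["R1", "R1"], ["A"],
                                np.array([False, False]))

    def test_irreversible_negative_lower_bound_rejected(self):
        with pytest.raises(ValidationError, match="negative lower bound"):
            mk.MetabolicNetwork(np.ones((1, 1)), ["R1"], ["A"],
                                np.array([False]),
                                lower_bound=np.array([-1.0]),
                                upper_bound=np.array([1.0]))

    def test_exchange_reactions_default_nonknockable(self, chain):
        # R1 / R3 touch a single metabolite but are not boundary columns here;
        # a genuine empty-side column is flagged exchange and non-knockable
        net = mk.MetabolicNetwork.from_equations(
            [("EX", " -> ", False), ("R", "A -> B", False)])
        assert not net.knockable[net.reaction_index("EX")]
        assert net.knockable[net.reaction_index("R")]

    @pytest.mark.parametrize("equation,coeffs,rev", [
        ("2 A + B -> C", {"A": -2, "B": -1, "C": 1}, False),
        ("A <-> B", {"A": -1, "B": 1}, True),
        ("-> A", {"A": 1}, False),
        ("B ->", {"B": -1}, False),
    ])
    def test_parse_equation(self, equation, coeffs, rev):
        got, got_rev = parse_equation(equation)
        assert got == coeffs
        assert got_rev is rev

    def test_parse_equation_rejects_garbage(self):
        with pytest.raises(FormatError):
            parse_equation("A B C")


class TestTabularRoundTrip:
    def test_round_trip(self, tmp_path, cycle_rev):
        cycle_rev.lower_bound = np.where(cycle_rev.reversible, -10.0, 0.0)
        cycle_rev.upper_bound = np.full(cycle_rev.n_reactions, 100.0)
        path = tmp_path / "net.tsv"
        mk.write_network(cycle_rev, path)
        back = mk.load_network(path)
        assert back.reaction_ids == cycle_rev.reaction_ids
        assert back.metabolite_ids == cycle_rev.metabolite_ids
        np.testing.assert_allclose(back.stoich, cycle_rev.stoich, atol=1e-9)
        assert (back.reversible == cycle_rev.reversible).all()
        np.testing.assert_allclose(back.lower_bound, cycle_rev.lower_bound,
                                   atol=1e-9)
        np.testing.assert_allclose(back.upper_bound, cycle_rev.upper_bound,
                                   atol=1e-9)
        assert (back.knockable == cycle_rev.knockable).all()

    def test_bad_reversible_flag_names_record(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("reaction_id\tequation\treversible\n"
                        "R1\t-> A\tmaybe\n")
        with pytest.raises(FormatError, match="R1"):
            mk.load_network(path)


class TestSBML:
    def test_reversibility_flag_passthrough(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        model = cobra.Model("toy")
        a = cobra.Metabolite("A", compartment="c")
        b = cobra.Metabolite("B", compartment="c")
        rxn = cobra.Reaction("R2")
        model.add_reactions([rxn])
        rxn.add_metabolites({a: -1, b: 1})
        rxn.lower_bound, rxn.upper_bound = -1000, 1000
        path = str(tmp_path / "toy.xml")
        cobra.io.write_sbml_model(model, path)
        net = mk.load_network(path)
        assert net.reversible[net.reaction_index("R2")]


class TestSplitReversible:
    def test_split_structure(self, cycle_rev):
        snet, pairing = mk.split_reversible(cycle_rev)
        assert pairing == {"R2_fwd": "R2_bwd"}
        assert snet.n_reactions == cycle_rev.n_reactions + 1
        assert not snet.reversible.any()
        j = cycle_rev.reaction_index("R2")
        f = snet.reaction_index("R2_fwd")
        bw = snet.reaction_index("R2_bwd")
        np.testing.assert_allclose(snet.stoich[:, f], cycle_rev.stoich[:, j])
        np.testing.assert_allclose(snet.stoich[:, bw], -cycle_rev.stoich[:, j])

    def test_all_irreversible_identity(self, chain):
        snet, pairing = mk.split_reversible(chain)
        assert snet is chain
        assert pairing == {}

    @pytest.mark.parametrize("seed", [3, 11, 17])
    def test_split_preserves_steady_state_fluxes(self, seed):
        """Any LP-sampled steady-state flux maps onto the split network and
        back: merging each pair's net flux recovers a steady state."""
        from conftest import random_net

        net = random_net(seed, n_reactions=8, reversible_fraction=0.5)
        snet, pairing = mk.split_reversible(net)
        # sample a flux of the original by pushing through the export reaction
        n = net.n_reactions
        bounds = [(None if net.reversible[j] else 0.0, 50.0) for j in range(n)]
        bounds = [(lo, 50.0) if lo is not None else (-50.0, 50.0)
                  for lo, _ in bounds]
        c = np.zeros(n)
        c[-1] = -1.0
        res = solve_lp(c, A_eq=net.stoich, b_eq=np.zeros(net.n_metabolites),
                       bounds=bounds)
        assert res.feasible
        r = res.x
        # map to split coordinates and verify steady state there
        split_flux = []
        for j, rid in enumerate(snet.reaction_ids):
            if rid.endswith("_fwd"):
                v = r[net.reaction_index(rid[:-4])]
                split_flux.append(max(v, 0.0))
            elif rid.endswith("_bwd"):
                v = r[net.reaction_index(rid[:-4])]
                split_flux.append(max(-v, 0.0))
            else:
                split_flux.append(r[net.reaction_index(rid)])
        np.testing.assert_allclose(snet.stoich @ np.array(split_flux), 0.0,
                                   atol=1e-7)


class TestConstraintSets:
    def test_text_grammar_and_normalisation(self, chain):
        cs = mk.LinearFluxConstraintSet.from_text(
            ["1 R3 >= 1", "2 R1 - 1 R2 <= 4", "1 R2 = 3"], chain)
        # >= is negated, = becomes two rows
        assert cs.n_rows == 4
        np.testing.assert_allclose(cs.coeffs[0], [0, 0, -1])
        assert cs.rhs[0] == -1
        np.testing.assert_allclose(cs.coeffs[1], [2, -1, 0])
        np.testing.assert_allclose(cs.coeffs[2], [0, 1, 0])
        np.testing.assert_allclose(cs.coeffs[3], [0, -1, 0])

    def test_unknown_reaction_and_missing_operator(self, chain):
        with pytest.raises(KeyError):
            mk.LinearFluxConstraintSet.from_text(["1 R9 >= 1"], chain)
        with pytest.raises(FormatError):
            mk.LinearFluxConstraintSet.from_text(["1 R1 1"], chain)

    def test_width_check(self, chain, diamond):
        cs = mk.LinearFluxConstraintSet.flux_bound(chain, "R3", ">=", 1)
        with pytest.raises(ValidationError):
            cs.check_width(diamond)


class TestValidateTarget:
    def test_demand_is_blockable(self, chain):
        report = mk.validate_target(
            chain, mk.LinearFluxConstraintSet.flux_bound(chain, "R3", ">=", 1))
        assert report.ok
        assert not report.zero_in_polyhedron
        assert report.polyhedron_nonempty

    def test_zero_vector_target_is_invalid(self, chain):
        report = mk.validate_target(
            chain, mk.LinearFluxConstraintSet.flux_bound(chain, "R3", "<=", 5))
        assert report.zero_in_polyhedron
        assert not report.ok
        assert any("zero flux vector" in m for m in report.messages)

    def test_blocked_demand_reports_empty_polyhedron(self):
        # chain without its substrate import: R3 cannot run
        net = mk.MetabolicNetwork.from_equations(
            [("R2", "A -> B", False), ("R3", "B ->", False)])
        report = mk.validate_target(
            net, mk.LinearFluxConstraintSet.flux_bound(net, "R3", ">=", 1))
        assert not report.polyhedron_nonempty
        assert any("empty" in m for m in report.messages)


class TestInterventionProblem:
    def test_knockable_must_exist(self, chain):
        target = mk.LinearFluxConstraintSet.flux_bound(chain, "R3", ">=", 1)
        with pytest.raises(ValidationError):
            mk.InterventionProblem(chain, target, knockable={"R9"}, max_size=1)

    def test_max_size_within_universe(self, chain):
        target = mk.LinearFluxConstraintSet.flux_bound(chain, "R3", ">=", 1)
        with pytest.raises(ValidationError):
            mk.InterventionProblem(chain, target, knockable={"R2"}, max_size=2)


def test_flux_lp_parts_knockouts_zero_the_rate(diamond):
    A_ub, b_ub, A_eq, b_eq, bounds = flux_lp_parts(diamond, knocked={"R2"})
    assert bounds[diamond.reaction_index("R2")] == (0.0, 0.0)
    assert A_ub is None and b_ub is None
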