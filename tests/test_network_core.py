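import pytest
from hypothesis import given, settings, strategies as st

from molcode import (
    ParseError,
    Reaction,
    ReactionNetwork,
    ValidationError,
    closure,
    enumerate_closed_sets,
    is_closed,
    k_shortest_paths,
    parse_chemkin,
    parse_reaction_list,
    path_context,
    single_molecule_closures,
    write_reaction_list,
)
from molcode.network_core import all_simple_paths
from molcode import build_grn, build_phospho_cascade

from _oracles import brute_force_closed_sets, brute_force_simple_paths, naive_closure
from conftest import small_random_network


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------


class TestParseReactionList:
    def test_simple_reaction(self):
        net = parse_reaction_list("A + B -> C")
        assert set(net.species) == {"A", "B", "C"}
        assert net.n_reactions == 1
        (r,) = net.reactions
        assert r.reactants == {"A", "B"}
        assert r.products == {"C"}

    def test_inflow(self):
        net = parse_reaction_list("-> hv")
        (r,) = net.reactions
        assert r.reactants == frozenset()
        assert r.products == {"hv"}

    def test_outflow(self):
        net = parse_reaction_list("A ->")
        (r,) = net.reactions
        assert r.products == frozenset()

    def test_labels_comments_coefficients(self):
        text = "# a comment\nburn : 2 H2 + O2 -> 2 H2O  # trailing\n"
        net = parse_reaction_list(text)
        (r,) = net.reactions
        assert r.id == "burn"
        assert r.reactant_stoich == {"H2": 2, "O2": 1}
        assert r.product_stoich == {"H2O": 2}

    def test_declared_only_species(self):
        net = parse_reaction_list("species: N2 AR\nA -> B")
        assert set(net.species) == {"A", "B", "N2", "AR"}

    def test_duplicate_signatures_collapse(self):
        net = parse_reaction_list("A + B -> C\nB + A -> C\n")
        assert net.n_reactions == 1

    def test_malformed_line_names_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_reaction_list("A -> B\ngarbage line\n")

    def test_both_sides_empty(self):
        with pytest.raises(ValidationError):
            parse_reaction_list("->")

    def test_write_single_reaction(self, abc_network):
        assert write_reaction_list(abc_network) == "A + B -> C\n"

    def test_write_empty_network(self):
        net = ReactionNetwork((), (), name="empty")
        out = write_reaction_list(net)
        assert out.startswith("#")
        assert len(out.splitlines()) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_random(self, seed):
        net = small_random_network(6, 10, seed)
        assert parse_reaction_list(write_reaction_list(net)) == net

    def test_write_is_idempotent(self):
        text = "b : X + Y -> Z\na : -> X\nspecies: Q\n"
        once = write_reaction_list(parse_reaction_list(text))
        twice = write_reaction_list(parse_reaction_list(once))
        assert once == twice


CHEMKIN_SNIPPET = """
! comment
ELEMENTS
H O
END
SPECIES
H2 O2 HO2 H OH O H2O
END
REACTIONS
H2+O2=HO2+H      1.0E10 0.0 10.0
H+O2=>OH+O       1.0E10 0.0 10.0
H+O2(+M)=HO2(+M) 1.0E10 0.0 10.0
H2/2.5/ H2O/12.0/
END
"""


class TestParseChemkin:
    def test_reversible_split_both(self):
        net = parse_chemkin(CHEMKIN_SNIPPET)
        sigs = {(tuple(sorted(r.reactants)), tuple(sorted(r.products))) for r in net.reactions}
        assert (("H2", "O2"), ("H", "HO2")) in sigs
        assert (("H", "HO2"), ("H2", "O2")) in sigs

    def test_irreversible_arrow(self):
        net = parse_chemkin(CHEMKIN_SNIPPET)
        sigs = {(tuple(sorted(r.reactants)), tuple(sorted(r.products))) for r in net.reactions}
        assert (("H", "O2"), ("O", "OH")) in sigs
        assert (("O", "OH"), ("H", "O2")) not in sigs

    def test_forward_only(self):
        net = parse_chemkin(CHEMKIN_SNIPPET, reversible_mode="forward_only")
        assert net.n_reactions == 3

    def test_third_body_stripped(self):
        net = parse_chemkin(CHEMKIN_SNIPPET)
        sigs = {(tuple(sorted(r.reactants)), tuple(sorted(r.products))) for r in net.reactions}
        assert (("H", "O2"), ("HO2",)) in sigs

    def test_missing_reactions_block(self):
        with pytest.raises(ParseError, match="REACTIONS"):
            parse_chemkin("SPECIES\nA B\nEND\n")

    def test_unknown_species_token(self):
        bad = "SPECIES\nA B\nEND\nREACTIONS\nA+XX=B 1.0 0.0 0.0\nEND\n"
        with pytest.raises(ValidationError, match="XX"):
            parse_chemkin(bad)


# ---------------------------------------------------------------------------
# closure operator
# ---------------------------------------------------------------------------


class TestClosure:
    def test_closure_examples(self, abc_network):
        assert closure(abc_network, {"A"}) == {"A"}
        assert closure(abc_network, {"A", "B"}) == {"A", "B", "C"}

    def test_inflow_fires_unconditionally(self):
        net = parse_reaction_list("-> L\nL + X -> Y\n")
        assert closure(net, set()) == {"L"}
        assert closure(net, {"X"}) == {"X", "L", "Y"}

    def test_unknown_species_rejected(self, abc_network):
        with pytest.raises(ValidationError):
            closure(abc_network, {"Z"})

    def test_is_closed_examples(self, abc_network):
        assert not is_closed(abc_network, {"A", "B"})
        assert is_closed(abc_network, {"A", "C"})
        assert is_closed(abc_network, set(abc_network.species))

    @pytest.mark.parametrize("seed", range(10))
    def test_closure_matches_naive_oracle(self, seed):
        net = small_random_network(7, 12, seed)
        rxns = [(set(r.reactants), set(r.products)) for r in net.reactions]
        seeds = [set(), {net.species[0]}, set(net.species[:3]), set(net.species)]
        for s in seeds:
            assert closure(net, s) == naive_closure(rxns, s)


@st.composite
def network_and_subsets(draw):
    n = draw(st.integers(min_value=3, max_value=9))
    max_r = n * (n - 1) // 2 * n
    r = draw(st.integers(min_value=0, max_value=min(3 * n, max_r)))
    seed = draw(st.integers(min_value=0, max_value=10_000))
    net = small_random_network(n, r, seed)
    pick = lambda: draw(st.sets(st.sampled_from(sorted(net.species)), max_size=n))
    return net, pick(), pick()


class TestClosureProperties:
    @settings(max_examples=60, deadline=None)
    @given(network_and_subsets())
    def test_extensive_monotone_idempotent(self, payload):
        net, x, y = payload
        cx = closure(net, x)
        assert x <= cx
        assert closure(net, cx) == cx
        if x <= y:
            assert cx <= closure(net, y)
        assert cx <= closure(net, x | y)

    @settings(max_examples=60, deadline=None)
    @given(network_and_subsets(), st.integers(min_value=0, max_value=8))
    def test_context_closure_lemma(self, payload, pick):
        # closure(C | {s}) == closure(closure(C) | {s}): the lemma that
        # justifies restricting context search to closed sets
        net, c, _ = payload
        s = sorted(net.species)[pick % net.n_species]
        lhs = closure(net, c | {s})
        rhs = closure(net, closure(net, c) | {s})
        assert lhs == rhs


# ---------------------------------------------------------------------------
# closed-set enumeration
# ---------------------------------------------------------------------------


class TestEnumerateClosedSets:
    def test_abc_network_has_seven(self, abc_network):
        got = set(enumerate_closed_sets(abc_network))
        expected = {
            frozenset(),
            frozenset("A"),
            frozenset("B"),
            frozenset("C"),
            frozenset("AC"),
            frozenset("BC"),
            frozenset("ABC"),
        }
        assert got == expected

    def test_no_reactions_gives_power_set(self):
        net = ReactionNetwork(["A", "B", "C", "D"], ())
        assert len(enumerate_closed_sets(net)) == 2**4

    def test_each_set_closed_and_unique(self):
        net = small_random_network(8, 10, seed=3)
        result = enumerate_closed_sets(net)
        sets = result.sets()
        assert len(sets) == len(set(sets))
        assert all(is_closed(net, s) for s in sets)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        net = small_random_network(7, 9, seed)
        assert set(enumerate_closed_sets(net)) == brute_force_closed_sets(net)

    def test_brute_force_at_twelve_species(self):
        net = small_random_network(12, 20, seed=11)
        assert set(enumerate_closed_sets(net)) == brute_force_closed_sets(net)

    def test_lectic_order_is_deterministic(self):
        net = small_random_network(8, 12, seed=5)
        a = enumerate_closed_sets(net).masks
        b = enumerate_closed_sets(net).masks
        assert a == b

    def test_cap_truncates_with_flag(self):
        net = ReactionNetwork(["A", "B", "C", "D", "E"], ())
        result = enumerate_closed_sets(net, cap=10)
        assert result.truncated
        assert len(result) == 10

    def test_single_molecule_closures(self):
        net = parse_reaction_list("A -> B\nB -> A\n")
        smc = single_molecule_closures(net)
        assert smc == {"A": {"A", "B"}, "B": {"A", "B"}}
        grn = build_grn(2)
        assert single_molecule_closures(grn)["TF1"] == {"TF1"}
        assert len(single_molecule_closures(grn)) == grn.n_species


# ---------------------------------------------------------------------------
# paths
# ---------------------------------------------------------------------------


class TestPaths:
    def test_single_path(self):
        net = parse_reaction_list("r1 : A + C -> B")
        paths = k_shortest_paths(net, "A", "B", k=5)
        assert [p.nodes for p in paths] == [("A", "r1", "B")]
        assert paths[0].length == 1

    def test_no_path_gives_empty(self, abc_network):
        assert k_shortest_paths(abc_network, "C", "A", k=3) == []

    def test_two_step_cascade_shortest_length(self):
        net = build_phospho_cascade(two_step=True)
        paths = k_shortest_paths(net, "X0", "Tp", k=1)
        assert paths and paths[0].length == 2

    def test_source_equals_target_rejected(self, abc_network):
        with pytest.raises(ValidationError):
            k_shortest_paths(abc_network, "A", "A", k=1)

    @pytest.mark.parametrize("seed", range(6))
    def test_exhaustive_equivalence(self, seed):
        net = small_random_network(6, 9, seed)
        for s in net.species[:3]:
            for t in net.species[3:]:
                ours = [p.nodes for p in all_simple_paths(net, s, t)]
                ref = brute_force_simple_paths(net, s, t)
                assert sorted(ours) == sorted(ref)
                # and sorted by (length, lexicographic nodes)
                assert ours == sorted(ours, key=lambda n: (len(n) // 2, n))

    def test_k_prefix_property(self):
        net = small_random_network(7, 14, seed=2)
        s, t = net.species[0], net.species[-1]
        k5 = [p.nodes for p in k_shortest_paths(net, s, t, k=5)]
        k2 = [p.nodes for p in k_shortest_paths(net, s, t, k=2)]
        assert k5[: len(k2)] == k2

    def test_path_context_examples(self):
        net = parse_reaction_list("r1 : A + C -> B")
        (p,) = k_shortest_paths(net, "A", "B", k=1)
        assert path_context(net, p) == {"C"}

    def test_path_context_two_reaction_chain(self):
        net = parse_reaction_list("r1 : A + U -> X\nr2 : X + V -> B\n")
        paths = k_shortest_paths(net, "A", "B", k=4)
        chain = [p for p in paths if p.length == 2][0]
        assert path_context(net, chain) == {"U", "V"}

    def test_path_context_in_motif(self, motif):
        (p,) = k_shortest_paths(motif, "s1", "m1", k=1)
        assert path_context(motif, p) == {"c1"}
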