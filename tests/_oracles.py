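"""Independent brute-force reference implementations for the test suite.

Everything here works on plain Python sets and exhaustive iteration,
deliberately sharing no machinery with the package's bitmask core.
"""

from __future__ import annotations

from itertools import combinations, permutations
from typing import Dict, FrozenSet, List, Set, Tuple


def naive_closure(reactions, seed) -> FrozenSet[str]:
    """Fixpoint of firing every applicable reaction, with plain sets."""
    current: Set[str] = set(seed)
    while True:
        produced: Set[str] = set()
        for reactants, products in reactions:
            if reactants <= current:
                produced |= products
        if produced <= current:
            return frozenset(current)
        current |= produced


def _reaction_sets(network) -> List[Tuple[Set[str], Set[str]]]:
    return [(set(r.reactants), set(r.products)) for r in network.reactions]


def brute_force_closed_sets(network) -> Set[FrozenSet[str]]:
    """All closed subsets by testing every subset directly."""
    species = sorted(network.species)
    rxns = _reaction_sets(network)
    closed = set()
    for k in range(len(species) + 1):
        for combo in combinations(species, k):
            cand = set(combo)
            if all(not (reactants <= cand) or (products <= cand) for reactants, products in rxns):
                closed.add(frozenset(cand))
    return closed


def brute_force_simple_paths(network, source: str, target: str) -> List[Tuple[str, ...]]:
    """All simple species-reaction-...-species paths via recursive DFS."""
    succ_species = {s: sorted(r.id for r in network.reactions if s in r.reactants) for s in network.species}
    succ_reaction = {r.id: sorted(r.products) for r in network.reactions}
    out: List[Tuple[str, ...]] = []

    def walk(node: str, path: Tuple[str, ...], at_species: bool) -> None:
        if at_species and node == target and len(path) > 1:
            out.append(path)
            return
        nxt = succ_species[node] if at_species else succ_reaction[node]
        for n in nxt:
            if n not in path:
                walk(n, path + (n,), not at_species)

    walk(source, (source,), True)
    return out


def brute_force_code_pairs(network) -> Set[Tuple[FrozenSet[str], FrozenSet[str]]]:
    """All (sign-pair, meaning-pair) code pairs by scanning every sign pair,
    meaning assignment and EVERY context subset, straight off the BMC
    definition."""
    species = sorted(network.species)
    rxns = _reaction_sets(network)
    subsets = [
        frozenset(c) for k in range(len(species) + 1) for c in combinations(species, k)
    ]
    clo: Dict[FrozenSet[str], FrozenSet[str]] = {A: naive_closure(rxns, A) for A in subsets}

    def realizable(s1: str, m1: str, s2: str, m2: str) -> bool:
        M = {m1, m2}
        for C in subsets:
            if clo[C] & M:
                continue
            t1 = clo[frozenset(C | {s1})]
            if t1 & M != {m1}:
                continue
            t2 = clo[frozenset(C | {s2})]
            if t2 & M != {m2}:
                continue
            return True
        return False

    codes: Set[Tuple[FrozenSet[str], FrozenSet[str]]] = set()
    for s1, s2 in combinations(species, 2):
        for m1, m2 in combinations(species, 2):
            if {m1, m2} & {s1, s2}:
                continue
            if realizable(s1, m1, s2, m2) and realizable(s1, m2, s2, m1):
                codes.add((frozenset((s1, s2)), frozenset((m1, m2))))
    return codes
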