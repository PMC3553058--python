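"""Detection of binary molecular codes (BMCs) and semantic capacity.

A mapping between two species sets S (signs) and M (meanings) is realized
by a context C when closure(C) contains no meaning and, for every sign s,
closure(C | {s}) contains exactly one meaning.  A *binary molecular code*
is a 2->2 mapping for which a second context realizes the crossed mapping;
the two together form a *code pair*.  The semantic capacity n_cp counts
distinct (sign-pair, meaning-pair) code pairs once; the logarithmic
capacity is L = log2(n_cp + 1).

Two finders are provided: closure-based (contexts range over all closed
sets, exact) and path-based (contexts assembled from k-shortest-path
reactant sets, a lower bound converging to the exact result for large k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .network_core import (
    Path,
    ReactionNetwork,
    ValidationError,
    enumerate_closed_sets,
    k_shortest_paths,
    path_context,
)


@dataclass(frozen=True)
class MappingWitness:
    """A realized molecular mapping: (s -> m) assignments under context C."""

    domain: FrozenSet[str]
    codomain: FrozenSet[str]
    context: FrozenSet[str]
    pairs: Tuple[Tuple[str, str], ...]

    @property
    def mapping(self) -> Dict[str, str]:
        return dict(self.pairs)


@dataclass(frozen=True)
class BinaryCodePair:
    """A code pair: the mapping f = {s1->m1, s2->m2} realized under
    ``context1`` together with the crossed mapping under ``context2``."""

    s1: str
    s2: str
    m1: str
    m2: str
    context1: FrozenSet[str]
    context2: FrozenSet[str]

    def __post_init__(self):
        if self.s1 >= self.s2:
            raise ValidationError("code pair must be canonical (s1 < s2)")

    @property
    def signs(self) -> FrozenSet[str]:
        return frozenset((self.s1, self.s2))

    @property
    def meanings(self) -> FrozenSet[str]:
        return frozenset((self.m1, self.m2))

    @property
    def key(self) -> Tuple[FrozenSet[str], FrozenSet[str]]:
        return (self.signs, self.meanings)

    @property
    def label(self) -> str:
        return f"{{{self.s1},{self.s2}}}->{{{min(self.m1, self.m2)},{max(self.m1, self.m2)}}}"

    def to_dict(self) -> dict:
        return {
            "signs": [self.s1, self.s2],
            "meanings": sorted((self.m1, self.m2)),
            "f": {self.s1: self.m1, self.s2: self.m2},
            "context1": sorted(self.context1),
            "context2": sorted(self.context2),
        }


@dataclass
class CodeReport:
    """Deduplicated code pairs of a network plus the capacity measures."""

    network_name: str
    code_pairs: List[BinaryCodePair]
    method: str
    k: Optional[int] = None
    truncated: bool = False
    n_closed_sets: Optional[int] = None
    n_paths: Optional[int] = None

    @property
    def n_cp(self) -> int:
        return len(self.code_pairs)

    @property
    def L(self) -> float:
        return math.log2(self.n_cp + 1)

    def to_dict(self) -> dict:
        return {
            "network": self.network_name,
            "method": self.method,
            "k": self.k,
            "n_cp": self.n_cp,
            "L": self.L,
            "truncated": self.truncated,
            "n_closed_sets": self.n_closed_sets,
            "n_paths": self.n_paths,
            "code_pairs": [cp.to_dict() for cp in self.code_pairs],
        }


# ---------------------------------------------------------------------------
# mapping / code-pair predicates
# ---------------------------------------------------------------------------


def realizes_mapping(
    network: ReactionNetwork,
    S: Iterable[str],
    M: Iterable[str],
    C: Iterable[str],
) -> Optional[MappingWitness]:
    """The mapping realized by context C on domain S / codomain M, or None.

    Requires closure(C) to contain no element of M and closure(C | {s}) to
    contain exactly one element of M for every sign s.
    """
    S, M, C = frozenset(S), frozenset(M), frozenset(C)
    if not S or not M:
        raise ValidationError("domain and codomain must be non-empty")
    if S & M:
        raise ValidationError("domain and codomain must be disjoint")
    m_mask = network.mask(M)
    c_mask = network.mask(C)
    if network.closure_mask(c_mask) & m_mask:
        return None
    pairs = []
    for s in sorted(S):
        hit = network.closure_mask(c_mask | network.mask([s])) & m_mask
        if hit == 0 or hit & (hit - 1):  # zero or more than one meaning
            return None
        pairs.append((s, next(iter(network.unmask(hit)))))
    return MappingWitness(domain=S, codomain=M, context=C, pairs=tuple(pairs))


def _ctx_sort_key(ctx: FrozenSet[str]) -> Tuple[str, ...]:
    return tuple(sorted(ctx))


def is_code_pair(
    network: ReactionNetwork,
    S: Iterable[str],
    M: Iterable[str],
    candidate_contexts: Iterable[Iterable[str]],
) -> Optional[BinaryCodePair]:
    """First code pair on (S, M) witnessed by the given contexts, or None.

    Scans contexts in deterministic (sorted-tuple) order; a code pair needs
    one context realizing a bijective assignment S -> M and another
    realizing the crossed assignment.
    """
    S, M = sorted(frozenset(S)), sorted(frozenset(M))
    if len(S) != 2 or len(M) != 2:
        raise ValidationError("S and M must contain exactly two species each")
    if set(S) & set(M):
        raise ValidationError("S and M must be disjoint")
    s1, s2 = S
    contexts = sorted({frozenset(c) for c in candidate_contexts}, key=_ctx_sort_key)
    witness: Dict[Tuple[str, str], FrozenSet[str]] = {}
    for ctx in contexts:
        w = realizes_mapping(network, S, M, ctx)
        if w is None:
            continue
        f = w.mapping
        if f[s1] == f[s2]:  # constant mapping: not a code
            continue
        assign = (f[s1], f[s2])
        if assign not in witness:
            witness[assign] = ctx
        straight, crossed = (M[0], M[1]), (M[1], M[0])
        if straight in witness and crossed in witness:
            return BinaryCodePair(
                s1=s1,
                s2=s2,
                m1=straight[0],
                m2=straight[1],
                context1=witness[straight],
                context2=witness[crossed],
            )
    return None


# ---------------------------------------------------------------------------
# closure-based finder
# ---------------------------------------------------------------------------


def _bits(mask: int) -> Iterable[int]:
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def _pair_codes_from_realized(
    network: ReactionNetwork,
    realized: Dict[Tuple[int, int, int, int], FrozenSet[str]],
) -> List[BinaryCodePair]:
    """Combine realized directed mappings (s1,m1,s2,m2) with their crossed
    counterparts into deduplicated, canonically ordered code pairs."""
    species = network.species
    out: List[BinaryCodePair] = []
    for (i1, j1, i2, j2), ctx in realized.items():
        if j1 > j2:  # dedupe: keep the orientation with the smaller first meaning
            continue
        crossed = realized.get((i1, j2, i2, j1))
        if crossed is None:
            continue
        out.append(
            BinaryCodePair(
                s1=species[i1],
                s2=species[i2],
                m1=species[j1],
                m2=species[j2],
                context1=ctx,
                context2=crossed,
            )
        )
    out.sort(key=lambda cp: (cp.s1, cp.s2, cp.m1, cp.m2))
    return out


def find_codes_closure(network: ReactionNetwork, cap: int = 1_000_000) -> CodeReport:
    """Exact code-pair search with contexts ranging over all closed sets.

    Correctness rests on closure(C | {s}) = closure(closure(C) | {s}): any
    subset context is equivalent to its closure, so only closed sets need
    to be scanned.  For each closed context C the sets D(s) = closure(C|{s})
    \\ C collect the candidate meanings contributed by each sign; the BMC
    conditions on the two contexts are independent, so realized directed
    mappings are recorded per context and paired afterwards.
    """
    closed = enumerate_closed_sets(network, cap=cap)
    n = network.n_species
    clo = network.closure_mask
    realized: Dict[Tuple[int, int, int, int], FrozenSet[str]] = {}
    witness_key: Dict[Tuple[int, int, int, int], Tuple[str, ...]] = {}
    for c_mask in closed.masks:
        outside = ~c_mask & network._full_mask
        cl_cs: Dict[int, int] = {}
        d: Dict[int, int] = {}
        for i in _bits(outside):
            cl = clo(c_mask | (1 << i))
            cl_cs[i] = cl
            d[i] = cl & ~c_mask
        idxs = [i for i in d if d[i]]
        idxs.sort()
        ctx_set: Optional[FrozenSet[str]] = None
        ctx_key: Optional[Tuple[str, ...]] = None
        for a, i1 in enumerate(idxs):
            for i2 in idxs[a + 1:]:
                pair_mask = (1 << i1) | (1 << i2)
                m1s = d[i1] & ~cl_cs[i2] & ~pair_mask
                if not m1s:
                    continue
                m2s = d[i2] & ~cl_cs[i1] & ~pair_mask
                if not m2s:
                    continue
                if ctx_key is None:
                    ctx_set = network.unmask(c_mask)
                    ctx_key = tuple(sorted(ctx_set))
                for j1 in _bits(m1s):
                    for j2 in _bits(m2s):
                        key = (i1, j1, i2, j2)
                        old = witness_key.get(key)
                        if old is None or ctx_key < old:
                            witness_key[key] = ctx_key
                            realized[key] = ctx_set
    code_pairs = _pair_codes_from_realized(network, realized)
    return CodeReport(
        network_name=network.name,
        code_pairs=code_pairs,
        method="closure",
        truncated=closed.truncated,
        n_closed_sets=len(closed.masks),
    )


# ---------------------------------------------------------------------------
# path-based finder
# ---------------------------------------------------------------------------


def find_codes_paths(network: ReactionNetwork, k: int = 20) -> CodeReport:
    """Approximate code-pair search assembling contexts from k-shortest
    paths; every candidate is verified by the closure conditions, so the
    result is always a subset of the closure-based finder's."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    species = network.species
    n = len(species)
    # contexts of the up-to-k shortest paths per ordered species pair
    ctx_by_pair: Dict[Tuple[int, int], List[int]] = {}
    n_paths = 0
    for i, s in enumerate(species):
        for j, t in enumerate(species):
            if i == j:
                continue
            paths = k_shortest_paths(network, s, t, k)
            n_paths += len(paths)
            if paths:
                masks: List[int] = []
                seen: Set[int] = set()
                for p in paths:
                    m = network.mask(path_context(network, p))
                    if m not in seen:
                        seen.add(m)
                        masks.append(m)
                ctx_by_pair[(i, j)] = masks

    clo_memo: Dict[int, int] = {}

    def clo(mask: int) -> int:
        r = clo_memo.get(mask)
        if r is None:
            r = network.closure_mask(mask)
            clo_memo[mask] = r
        return r

    def realize(i1: int, j1: int, i2: int, j2: int) -> Optional[FrozenSet[str]]:
        """Smallest path-assembled context realizing s_i1->m_j1, s_i2->m_j2."""
        c1s = ctx_by_pair.get((i1, j1))
        c2s = ctx_by_pair.get((i2, j2))
        if not c1s or not c2s:
            return None
        m_mask = (1 << j1) | (1 << j2)
        b1, b2 = 1 << i1, 1 << i2
        best: Optional[Tuple[Tuple[str, ...], FrozenSet[str]]] = None
        for ca in c1s:
            for cb in c2s:
                c = ca | cb
                if clo(c) & m_mask:
                    continue
                if clo(c | b1) & m_mask != (1 << j1):
                    continue
                if clo(c | b2) & m_mask != (1 << j2):
                    continue
                ctx = network.unmask(c)
                key = tuple(sorted(ctx))
                if best is None or key < best[0]:
                    best = (key, ctx)
        return None if best is None else best[1]

    realized: Dict[Tuple[int, int, int, int], FrozenSet[str]] = {}
    sources = sorted({i for (i, _) in ctx_by_pair})
    targets_of = {i: sorted({j for (a, j) in ctx_by_pair if a == i}) for i in sources}
    for a, i1 in enumerate(sources):
        for i2 in sources[a + 1:]:
            for j1 in targets_of[i1]:
                if j1 in (i1, i2):
                    continue
                for j2 in targets_of[i2]:
                    if j2 in (i1, i2) or j2 == j1:
                        continue
                    # only pursue assignments whose crossed partner is possible
                    if (i1, j2) not in ctx_by_pair or (i2, j1) not in ctx_by_pair:
                        continue
                    key = (i1, j1, i2, j2)
                    if key in realized:
                        continue
                    ctx = realize(i1, j1, i2, j2)
                    if ctx is not None:
                        realized[key] = ctx
    code_pairs = _pair_codes_from_realized(network, realized)
    return CodeReport(
        network_name=network.name,
        code_pairs=code_pairs,
        method="paths",
        k=k,
        n_paths=n_paths,
    )


def find_codes(network: ReactionNetwork, method: str = "closure", k: int = 20, cap: int = 1_000_000) -> CodeReport:
    if method == "closure":
        return find_codes_closure(network, cap=cap)
    if method == "paths":
        return find_codes_paths(network, k=k)
    raise ValidationError(f"unknown method {method!r}")


def semantic_capacity(report: CodeReport) -> Tuple[int, float]:
    """(n_cp, L) of a report; L = log2(n_cp + 1)."""
    return report.n_cp, report.L


# ---------------------------------------------------------------------------
# merging binary codes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MergedCode:
    signs: FrozenSet[str]
    meanings: FrozenSet[str]
    members: Tuple[str, ...]  # labels of the member BMCs


def merge_binary_codes(report: CodeReport) -> List[MergedCode]:
    """Connected components of BMCs, linked when they share a meaning pair
    and their sign pairs overlap, or share a sign pair and their meaning
    pairs overlap."""
    cps = report.code_pairs
    parent = list(range(len(cps)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in range(len(cps)):
        for j in range(i + 1, len(cps)):
            a, b = cps[i], cps[j]
            if (a.meanings == b.meanings and a.signs & b.signs) or (
                a.signs == b.signs and a.meanings & b.meanings
            ):
                union(i, j)
    groups: Dict[int, List[int]] = {}
    for i in range(len(cps)):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members in groups.values():
        signs: FrozenSet[str] = frozenset().union(*(cps[i].signs for i in members))
        meanings: FrozenSet[str] = frozenset().union(*(cps[i].meanings for i in members))
        merged.append(
            MergedCode(
                signs=signs,
                meanings=meanings,
                members=tuple(cps[i].label for i in sorted(members)),
            )
        )
    merged.sort(key=lambda mc: (-len(mc.members), tuple(sorted(mc.signs))))
    return merged
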