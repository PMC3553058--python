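"""Reaction-network data model, I/O, closure operator and path machinery.

A reaction network is a pair (species, reactions).  Closure semantics are
set-based: a reaction fires as soon as all its reactant *species* are
present; stoichiometric coefficients are parsed and retained (the dynamics
module uses them) but ignored by the closure operator.  Reactions with an
empty reactant set ("inflow") fire unconditionally.
"""

from __future__ import annotations

import heapq
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple


class NetworkError(ValueError):
    """Base class for network construction/IO errors."""


class ParseError(NetworkError):
    """Malformed input text; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(NetworkError):
    """Semantically invalid input (unknown species, bad sizes, ...)."""


_TOKEN_RE = re.compile(r"^\S+$")


@dataclass(frozen=True)
class Reaction:
    """A directed reaction.

    ``reactants``/``products`` are species-id sets; an empty reactant set
    denotes an inflow reaction, an empty product set an outflow.  The
    stoichiometry maps carry integer counts and default to 1 per species.
    """

    id: str
    reactants: FrozenSet[str]
    products: FrozenSet[str]
    reactant_stoich: Mapping[str, int] = field(default=None, compare=False)  # type: ignore[assignment]
    product_stoich: Mapping[str, int] = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.reactants and not self.products:
            raise ValidationError(f"reaction {self.id!r}: both sides empty")
        if self.reactant_stoich is None:
            object.__setattr__(self, "reactant_stoich", {s: 1 for s in self.reactants})
        if self.product_stoich is None:
            object.__setattr__(self, "product_stoich", {s: 1 for s in self.products})

    @property
    def signature(self) -> Tuple[FrozenSet[str], FrozenSet[str]]:
        """Identity of the reaction for deduplication (set semantics)."""
        return (self.reactants, self.products)

    def format(self, with_coefficients: bool = True) -> str:
        def side(species: FrozenSet[str], stoich: Mapping[str, int]) -> str:
            terms = []
            for s in sorted(species):
                c = stoich.get(s, 1)
                terms.append(s if (c == 1 or not with_coefficients) else f"{c} {s}")
            return " + ".join(terms)

        return f"{side(self.reactants, self.reactant_stoich)} -> {side(self.products, self.product_stoich)}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Reaction({self.id!r}: {self.format()})"


class ReactionNetwork:
    """Immutable reaction network N = (species, reactions).

    Species ids are case-sensitive whitespace-free tokens.  Reactions are
    deduplicated by their (reactants, products) signature; the species set
    is the union of all species referenced by reactions plus any
    declared-only species.
    """

    def __init__(self, species: Iterable[str], reactions: Iterable[Reaction], name: str = ""):
        declared = set(species)
        rxns: List[Reaction] = []
        seen = set()
        for r in reactions:
            if r.signature in seen:
                continue
            seen.add(r.signature)
            rxns.append(r)
        referenced = set()
        for r in rxns:
            referenced |= r.reactants | r.products
        missing = referenced - declared
        if missing and declared:
            # tolerate construction from reactions alone
            declared |= missing
        all_species = declared | referenced
        for s in all_species:
            if not s or not _TOKEN_RE.match(s):
                raise ValidationError(f"invalid species id {s!r}")
        self.name = name
        self.species: Tuple[str, ...] = tuple(sorted(all_species))
        self.reactions: Tuple[Reaction, ...] = tuple(rxns)
        self._index: Dict[str, int] = {s: i for i, s in enumerate(self.species)}
        # bitmask representation used by the closure machinery
        self._rx_masks: List[Tuple[int, int]] = []
        for r in rxns:
            rm = self.mask(r.reactants)
            pm = self.mask(r.products)
            self._rx_masks.append((rm, pm))
        self._full_mask = (1 << len(self.species)) - 1

    # -- basic protocol -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (
            self.species == other.species
            and {r.signature for r in self.reactions} == {r.signature for r in other.reactions}
        )

    def __hash__(self):
        return hash((self.species, frozenset(r.signature for r in self.reactions)))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<ReactionNetwork {self.name!r}: {self.n_species} species, {self.n_reactions} reactions>"

    # -- bitmask helpers ------------------------------------------------

    def mask(self, species: Iterable[str]) -> int:
        m = 0
        for s in species:
            try:
                m |= 1 << self._index[s]
            except KeyError:
                raise ValidationError(f"unknown species {s!r}") from None
        return m

    def unmask(self, mask: int) -> FrozenSet[str]:
        out = []
        i = 0
        while mask:
            if mask & 1:
                out.append(self.species[i])
            mask >>= 1
            i += 1
        return frozenset(out)

    # -- closure operator ------------------------------------------------

    def closure_mask(self, mask: int) -> int:
        """Smallest closed superset of ``mask``, as a bitmask."""
        state = mask
        rx = self._rx_masks
        changed = True
        while changed:
            changed = False
            for rm, pm in rx:
                if not rm & ~state and pm & ~state:
                    state |= pm
                    changed = True
        return state

    def closure(self, seed: Iterable[str]) -> FrozenSet[str]:
        return self.unmask(self.closure_mask(self.mask(seed)))

    def is_closed_mask(self, mask: int) -> bool:
        for rm, pm in self._rx_masks:
            if not rm & ~mask and pm & ~mask:
                return False
        return True

    def is_closed(self, candidate: Iterable[str]) -> bool:
        return self.is_closed_mask(self.mask(candidate))


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def closure(network: ReactionNetwork, seed: Iterable[str]) -> FrozenSet[str]:
    """The smallest closed set containing ``seed``."""
    return network.closure(seed)


def is_closed(network: ReactionNetwork, candidate: Iterable[str]) -> bool:
    """True iff every applicable reaction keeps its products inside ``candidate``."""
    return network.is_closed(candidate)


@dataclass
class ClosedSets:
    """Result of closed-set enumeration, in lectic order."""

    masks: List[int]
    truncated: bool
    network: ReactionNetwork

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self) -> Iterator[FrozenSet[str]]:
        for m in self.masks:
            yield self.network.unmask(m)

    def sets(self) -> List[FrozenSet[str]]:
        return list(self)


def iter_closed_set_masks(network: ReactionNetwork) -> Iterator[int]:
    """Yield every closed set (as bitmask) exactly once, in lectic order.

    Ganter's next-closure scheme over the sorted species alphabet: the
    successor of A is closure((A & prefix(i)) | {i}) for the largest i not
    in A whose new elements are all >= i.
    """
    n = network.n_species
    full = (1 << n) - 1
    clo = network.closure_mask
    current = clo(0)
    yield current
    while current != full:
        nxt = None
        for i in range(n - 1, -1, -1):
            bit = 1 << i
            if current & bit:
                continue
            prefix = bit - 1
            cand = clo((current & prefix) | bit)
            if not (cand & ~current) & prefix:
                nxt = cand
                break
        if nxt is None:  # pragma: no cover - cannot happen for a closure operator
            return
        current = nxt
        yield current


def enumerate_closed_sets(network: ReactionNetwork, cap: int = 1_000_000) -> ClosedSets:
    """All closed sets of the network, stopping (flagged) after ``cap`` sets."""
    if cap < 1:
        raise ValidationError("cap must be >= 1")
    masks: List[int] = []
    truncated = False
    for m in iter_closed_set_masks(network):
        if len(masks) >= cap:
            truncated = True
            break
        masks.append(m)
    return ClosedSets(masks=masks, truncated=truncated, network=network)


def single_molecule_closures(network: ReactionNetwork) -> Dict[str, FrozenSet[str]]:
    """closure({s}) for each species s."""
    return {s: network.closure([s]) for s in network.species}


# ---------------------------------------------------------------------------
# bipartite species-reaction paths
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Path:
    """Simple path in the bipartite species/reaction digraph.

    ``nodes`` alternates species, reaction-id, species, ..., species.
    ``length`` is the number of reaction nodes.
    """

    nodes: Tuple[str, ...]

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]

    @property
    def length(self) -> int:
        return len(self.nodes) // 2

    @property
    def reaction_ids(self) -> Tuple[str, ...]:
        return self.nodes[1::2]

    @property
    def species_nodes(self) -> Tuple[str, ...]:
        return self.nodes[0::2]


def _adjacency(network: ReactionNetwork):
    by_reactant: Dict[str, List[str]] = {s: [] for s in network.species}
    products: Dict[str, List[str]] = {}
    for r in network.reactions:
        for s in r.reactants:
            by_reactant[s].append(r.id)
        products[r.id] = sorted(r.products)
    for s in by_reactant:
        by_reactant[s].sort()
    return by_reactant, products


def k_shortest_paths(
    network: ReactionNetwork,
    source: str,
    target: str,
    k: int,
    max_expansions: int = 500_000,
) -> List[Path]:
    """Up to ``k`` loopless source->target paths, shortest first.

    Best-first enumeration of simple paths keyed by (number of reaction
    nodes, lexicographic node sequence); the key grows monotonically along
    extensions, so the first k targets popped are exactly the k shortest
    under the documented deterministic tie-break.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if source == target:
        raise ValidationError("source and target must differ")
    for s in (source, target):
        if s not in network._index:
            raise ValidationError(f"unknown species {s!r}")
    by_reactant, products = _adjacency(network)
    heap: List[Tuple[int, Tuple[str, ...]]] = [(0, (source,))]
    found: List[Path] = []
    expansions = 0
    while heap and len(found) < k and expansions < max_expansions:
        expansions += 1
        length, nodes = heapq.heappop(heap)
        last = nodes[-1]
        on_path = set(nodes)
        if last == target:
            found.append(Path(nodes=nodes))
            continue
        at_species = len(nodes) % 2 == 1
        succ = by_reactant.get(last, ()) if at_species else products[last]
        for nxt in succ:
            if nxt in on_path:
                continue
            new_len = length + 1 if at_species else length
            heapq.heappush(heap, (new_len, nodes + (nxt,)))
    return found


def all_simple_paths(network: ReactionNetwork, source: str, target: str) -> List[Path]:
    """Exhaustive simple-path enumeration (reference implementation)."""
    return k_shortest_paths(network, source, target, k=10**9, max_expansions=10**9)


def path_context(network: ReactionNetwork, path: Path) -> FrozenSet[str]:
    """Candidate context of a path: all reactant species of its reactions
    minus the species visited by the path itself."""
    rxn_by_id = {r.id: r for r in network.reactions}
    ctx: set = set()
    for rid in path.reaction_ids:
        ctx |= rxn_by_id[rid].reactants
    return frozenset(ctx - set(path.species_nodes))


# ---------------------------------------------------------------------------
# reaction-list ( .rxn ) format
# ---------------------------------------------------------------------------

_COEF_TOKEN_RE = re.compile(r"^(\d+)\s+(\S+)$")
_GLUED_COEF_RE = re.compile(r"^(\d+)([A-Za-z_].*)$")


def _parse_side(text: str, lineno: int) -> Dict[str, int]:
    text = text.strip()
    stoich: Dict[str, int] = {}
    if not text:
        return stoich
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ParseError("empty term in reaction side", lineno)
        m = _COEF_TOKEN_RE.match(term)
        if m:
            coef, sp = int(m.group(1)), m.group(2)
        elif term.isdigit():
            raise ParseError(f"coefficient {term!r} without species", lineno)
        else:
            coef, sp = 1, term
        if " " in sp or "\t" in sp:
            raise ParseError(f"species token {sp!r} contains whitespace", lineno)
        stoich[sp] = stoich.get(sp, 0) + coef
    return stoich


def parse_reaction_list(text: str, name: str = "") -> ReactionNetwork:
    """Parse the plain-text reaction-list format.

    One reaction per line: ``[label :] LHS -> RHS`` with "+"-separated
    terms and optional integer coefficients.  ``# ...`` lines are comments;
    a ``species: A B C`` line declares species not mentioned in any
    reaction.  Empty LHS (inflow) and empty RHS (outflow) are allowed.
    """
    reactions: List[Reaction] = []
    declared: set = set()
    auto = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("species:"):
            declared.update(line[len("species:"):].split())
            continue
        if "->" not in line:
            raise ParseError(f"no '->' arrow in {raw.strip()!r}", lineno)
        label = None
        head, arrow, tail = line.partition("->")
        if ":" in head:
            label, _, head = head.partition(":")
            label = label.strip()
            if not label:
                raise ParseError("empty reaction label", lineno)
        lhs = _parse_side(head, lineno)
        rhs = _parse_side(tail, lineno)
        if not lhs and not rhs:
            raise ValidationError(f"line {lineno}: reaction with both sides empty")
        if label is None:
            auto += 1
            label = f"r{auto:04d}"
        reactions.append(
            Reaction(
                id=label,
                reactants=frozenset(lhs),
                products=frozenset(rhs),
                reactant_stoich=lhs,
                product_stoich=rhs,
            )
        )
    return ReactionNetwork(declared, reactions, name=name)


def write_reaction_list(network: ReactionNetwork) -> str:
    """Canonical, byte-stable writer for the reaction-list format.

    Reactions are emitted sorted by their formatted string; a ``species:``
    directive is added only when some species appears in no reaction.
    """
    lines: List[str] = []
    mentioned: set = set()
    for r in network.reactions:
        mentioned |= r.reactants | r.products
    isolated = sorted(set(network.species) - mentioned)
    if not network.reactions:
        lines.append(f"# reaction network {network.name or '(unnamed)'}: empty")
    if isolated:
        lines.append("species: " + " ".join(isolated))
    lines.extend(sorted(r.format() for r in network.reactions))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# CHEMKIN-II mechanism files (SPECIES / REACTIONS blocks only)
# ---------------------------------------------------------------------------

_CHEMKIN_ARROW_RE = re.compile(r"<=>|=>|=")


def _strip_third_body(term: str) -> Optional[str]:
    term = term.strip()
    if term in ("M", "m"):
        return None
    return term or None


def _parse_chemkin_side(text: str, lineno: int, known: set) -> Dict[str, int]:
    text = re.sub(r"\(\s*\+\s*[Mm]\s*\)", "", text)  # pressure dependence (+M)
    stoich: Dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        if not term:
            continue
        sp = _strip_third_body(term)
        if sp is None:
            continue
        coef = 1
        m = _GLUED_COEF_RE.match(sp)
        if m and m.group(2) in known:
            coef, sp = int(m.group(1)), m.group(2)
        if sp not in known:
            raise ValidationError(f"line {lineno}: unknown species token {sp!r} in reaction")
        stoich[sp] = stoich.get(sp, 0) + coef
    return stoich


def parse_chemkin(text: str, reversible_mode: str = "split_both", name: str = "") -> ReactionNetwork:
    """Parse a CHEMKIN-II mechanism (SPECIES and REACTIONS blocks).

    Reversible reactions ("=" or "<=>") become two directed reactions under
    ``split_both`` and one under ``forward_only``; "=>" is always one.
    Third bodies (+M / M), Arrhenius coefficients, efficiencies and other
    auxiliary lines are ignored.
    """
    if reversible_mode not in ("split_both", "forward_only"):
        raise ValidationError(f"unknown reversible_mode {reversible_mode!r}")
    lines = [ln.split("!", 1)[0] for ln in text.splitlines()]
    upper = [ln.strip().upper() for ln in lines]

    def block(keyword: str) -> Tuple[int, int]:
        start = end = -1
        for i, ln in enumerate(upper):
            if start < 0 and (ln == keyword or ln.startswith(keyword + " ")):
                start = i
            elif start >= 0 and ln.startswith("END"):
                end = i
                break
        if start < 0:
            raise ParseError(f"missing {keyword} block")
        return start, (end if end >= 0 else len(lines))

    s0, s1 = block("SPECIES")
    species: List[str] = []
    for ln in lines[s0 + 1:s1]:
        species.extend(ln.split())
    known = set(species)

    r0, r1 = block("REACTIONS")
    reactions: List[Reaction] = []
    auto = 0
    for offset, ln in enumerate(lines[r0 + 1:r1]):
        lineno = r0 + 2 + offset
        ln = ln.strip()
        if not ln or ln.upper().startswith(("DUPLICATE", "LOW", "TROE", "SRI", "REV", "PLOG", "UNITS")):
            continue
        m = _CHEMKIN_ARROW_RE.search(ln)
        if m is None:
            # third-body efficiency lines like "H2/2.5/ H2O/12.0/"
            if "/" in ln:
                continue
            raise ParseError(f"unparseable reaction line {ln!r}", lineno)
        lhs_text = ln[: m.start()]
        rest = ln[m.end():]
        # the RHS runs until the Arrhenius numbers; take tokens that still
        # belong to the species expression
        rhs_tokens = rest.split()
        rhs_parts: List[str] = []
        for tok in rhs_tokens:
            if re.match(r"^[-+]?\d*\.?\d+([EeDd][-+]?\d+)?$", tok) and rhs_parts and not rhs_parts[-1].endswith("+"):
                break
            rhs_parts.append(tok)
        rhs_text = " ".join(rhs_parts)
        lhs = _parse_chemkin_side(lhs_text, lineno, known)
        rhs = _parse_chemkin_side(rhs_text, lineno, known)
        if not lhs and not rhs:
            continue
        directions = [(lhs, rhs)]
        if m.group(0) != "=>" and reversible_mode == "split_both":
            directions.append((rhs, lhs))
        for left, right in directions:
            auto += 1
            reactions.append(
                Reaction(
                    id=f"r{auto:04d}",
                    reactants=frozenset(left),
                    products=frozenset(right),
                    reactant_stoich=dict(left),
                    product_stoich=dict(right),
                )
            )
    return ReactionNetwork(known, reactions, name=name)
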