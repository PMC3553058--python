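"""Constructors for the model chemistries: genetic-code translation
networks (basic and aaRS-refined), gene regulatory networks, and
phosphorylation cascades, plus the closed-form code-pair counts.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

from .network_core import Reaction, ReactionNetwork, ValidationError

CODON_RE = re.compile(r"^[TCAG]{3}$")

#: the 21 meaning symbols: 20 proteinogenic amino acids + translation stop
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
MEANING_ALPHABET = frozenset(AMINO_ACIDS) | {"Stop"}

ALL_CODONS = tuple(a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG")


@dataclass
class CodeTable:
    """A genetic code: codon -> set of meanings."""

    entries: Dict[str, Set[str]]
    label: str = ""

    def __post_init__(self):
        for codon, meanings in self.entries.items():
            if not CODON_RE.match(codon):
                raise ValidationError(f"invalid codon {codon!r} (must be 3 letters over TCAG)")
            bad = set(meanings) - MEANING_ALPHABET
            if bad:
                raise ValidationError(f"invalid meaning symbol(s) {sorted(bad)} for codon {codon}")

    def assignments(self) -> List[tuple]:
        return sorted((c, m) for c, ms in self.entries.items() for m in ms)


def load_code_tables_tsv(text: str) -> List[CodeTable]:
    """Parse CodeTable TSV (columns: codon, meaning, table_label)."""
    tables: Dict[str, Dict[str, Set[str]]] = {}
    order: List[str] = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    required = {"codon", "meaning", "table_label"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ValidationError(f"code-table TSV must have columns {sorted(required)}")
    for row in reader:
        label = row["table_label"]
        if label not in tables:
            tables[label] = {}
            order.append(label)
        tables[label].setdefault(row["codon"], set()).add(row["meaning"])
    return [CodeTable(entries=tables[label], label=label) for label in order]


def ncbi_code_tables() -> List[CodeTable]:
    """The 17 NCBI genetic codes (transl_table 1-6, 9-16, 21-23),
    packaged as data."""
    text = resources.files("molcode.data").joinpath("ncbi_codes.tsv").read_text()
    return load_code_tables_tsv(text)


@dataclass
class TranslationSpec:
    """Counting parameters of the aaRS translation model."""

    n_c: int
    n_aa: int

    def __post_init__(self):
        if self.n_c < 1 or self.n_aa < 1:
            raise ValidationError("codon and amino-acid counts must be positive")

    @property
    def n_t(self) -> int:  # one unloaded tRNA per codon
        return self.n_c

    @property
    def n_S(self) -> int:  # signs: codons plus unloaded tRNAs
        return self.n_c + self.n_t

    @property
    def n_M(self) -> int:  # meanings: amino acids
        return self.n_aa


def trna_species(codon: str, meaning: str) -> str:
    return f"tRNA_{codon}_{meaning}"


def build_translation_basic(tables: Sequence[CodeTable], name: str = "translation_basic") -> ReactionNetwork:
    """Merge code tables into a translation network.

    One tRNA species per distinct (codon, meaning) assignment across all
    tables; each assignment becomes the catalytic reaction
    ``codon + tRNA -> codon + tRNA + meaning``.
    """
    if not tables:
        raise ValidationError("need at least one code table")
    assignments = sorted({a for t in tables for a in t.assignments()})
    reactions = []
    for i, (codon, meaning) in enumerate(assignments, start=1):
        t = trna_species(codon, meaning)
        reactions.append(
            Reaction(
                id=f"tr{i:04d}",
                reactants=frozenset((codon, t)),
                products=frozenset((codon, t, meaning)),
            )
        )
    return ReactionNetwork((), reactions, name=name)


def all_mappings_table(codons: Sequence[str], meanings: Sequence[str]) -> CodeTable:
    """The table in which every codon can be read for every meaning."""
    return CodeTable(entries={c: set(meanings) for c in codons}, label="all_mappings")


def eq1_code_count(n_c: int, n_aa: int) -> int:
    """Code pairs of the basic all-possible-tRNA model:
    C(n_c, 2) * C(n_aa, 2)."""
    if n_c < 0 or n_aa < 0:
        raise ValidationError("counts must be non-negative")
    return math.comb(n_c, 2) * math.comb(n_aa, 2)


def eq2_code_count(spec: TranslationSpec) -> int:
    """Code pairs of the aaRS model: (C(n_S, 2) - n_c) * C(n_M, 2).

    Every sign pair except the n_c codon/own-tRNA pairs (which belong
    together and cannot be mapped independently) combines with every
    meaning pair.
    """
    return (math.comb(spec.n_S, 2) - spec.n_c) * math.comb(spec.n_M, 2)


def build_translation_aars(
    n_c: int,
    n_aa: int,
    codon_labels: Optional[Sequence[str]] = None,
    aa_labels: Optional[Sequence[str]] = None,
    name: str = "translation_aars",
) -> ReactionNetwork:
    """Translation model with explicit tRNA loading by synthetases.

    Species: codons, free amino acids, bound amino acids, one unloaded
    tRNA per codon, loaded tRNAs and aaRS for every (codon, aa) pair.
    Reactions: loading ``aa + tRNA_c + aaRS_c_a -> tRNA_c.a + aaRS_c_a``
    and translation ``codon + tRNA_c.a -> codon + tRNA_c + bound_a``.
    """
    if codon_labels is None:
        codon_labels = ALL_CODONS[:n_c]
    if aa_labels is None:
        aa_labels = [a for a in AMINO_ACIDS[:n_aa]]
    if len(codon_labels) != n_c or len(aa_labels) != n_aa:
        raise ValidationError("label lists must match n_c / n_aa")
    reactions = []
    rid = 0
    for c in codon_labels:
        trna = f"tRNA_{c}"
        for a in aa_labels:
            loaded = f"tRNA_{c}.{a}"
            aars = f"aaRS_{c}_{a}"
            bound = f"bound_{a}"
            rid += 1
            reactions.append(
                Reaction(
                    id=f"load{rid:04d}",
                    reactants=frozenset((a, trna, aars)),
                    products=frozenset((loaded, aars)),
                )
            )
            reactions.append(
                Reaction(
                    id=f"tsl{rid:04d}",
                    reactants=frozenset((c, loaded)),
                    products=frozenset((c, trna, bound)),
                )
            )
    return ReactionNetwork((), reactions, name=name)


def build_grn(n: int, name: str = "grn") -> ReactionNetwork:
    """Gene regulatory network: n transcription factors, n products and
    all n^2 promoter/coding-region combinations G_ij, with catalytic
    expression ``TF_i + G_ij -> TF_i + G_ij + P_j``."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    reactions = []
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            tf, gene, product = f"TF{i}", f"G{i}{j}", f"P{j}"
            reactions.append(
                Reaction(
                    id=f"expr_{i}_{j}",
                    reactants=frozenset((tf, gene)),
                    products=frozenset((tf, gene, product)),
                )
            )
    return ReactionNetwork((), reactions, name=f"{name}{n}")


def build_phospho_cascade(two_step: bool, name: Optional[str] = None) -> ReactionNetwork:
    """Phosphorylation motifs.

    one-step: ``X0 + K -> X0 + Kp``, ``Kp -> K`` (no code possible).
    two-step: adds the branch kinases A (active unphosphorylated) and B
    (active phosphorylated) acting on the target T; K/Kp are retained as
    the buffered one-step pool.
    """
    one_step = [
        Reaction(id="phos_K", reactants=frozenset(("X0", "K")), products=frozenset(("X0", "Kp"))),
        Reaction(id="dephos_K", reactants=frozenset(("Kp",)), products=frozenset(("K",))),
    ]
    if not two_step:
        return ReactionNetwork((), one_step, name=name or "cascade_one_step")
    reactions = [
        Reaction(id="phos_A", reactants=frozenset(("X0", "A")), products=frozenset(("X0", "Ap"))),
        Reaction(id="dephos_A", reactants=frozenset(("Ap",)), products=frozenset(("A",))),
        Reaction(id="act_T_by_A", reactants=frozenset(("A", "T")), products=frozenset(("A", "Tp"))),
        Reaction(id="phos_B", reactants=frozenset(("X0", "B")), products=frozenset(("X0", "Bp"))),
        Reaction(id="dephos_B", reactants=frozenset(("Bp",)), products=frozenset(("B",))),
        Reaction(id="act_T_by_B", reactants=frozenset(("Bp", "T")), products=frozenset(("Bp", "Tp"))),
        Reaction(id="dephos_T", reactants=frozenset(("Tp",)), products=frozenset(("T",))),
    ]
    return ReactionNetwork(("K", "Kp"), reactions, name=name or "cascade_two_step")


def minimal_code_motif(name: str = "minimal_motif") -> ReactionNetwork:
    """The minimal binary-code motif: two signs, two meanings, and two
    contexts wiring the crossed mappings."""
    reactions = [
        Reaction(id="r1", reactants=frozenset(("s1", "c1")), products=frozenset(("m1",))),
        Reaction(id="r2", reactants=frozenset(("s2", "c1")), products=frozenset(("m2",))),
        Reaction(id="r3", reactants=frozenset(("s1", "c2")), products=frozenset(("m2",))),
        Reaction(id="r4", reactants=frozenset(("s2", "c2")), products=frozenset(("m1",))),
    ]
    return ReactionNetwork((), reactions, name=name)


def hydrogen_combustion(reversible_mode: str = "split_both") -> ReactionNetwork:
    """The packaged H2/O2 combustion mechanism (10 species, 19 reversible
    reactions -> 38 directed under split_both)."""
    from .network_core import parse_chemkin

    text = resources.files("molcode.data").joinpath("hydrogen_oconaire.mech").read_text()
    return parse_chemkin(text, reversible_mode=reversible_mode, name="hydrogen_combustion")
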