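"""Random bimolecular reaction networks (null model), density surveys and
network randomization.

Sampling convention: each rule has two *distinct* reactants (unordered,
uniform over species pairs) and one product (uniform over all species,
possibly equal to a reactant); duplicate rules are rejected and redrawn.
All randomness flows from a single integer seed via numpy Generators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .code_finder import find_codes
from .network_core import (
    Reaction,
    ReactionNetwork,
    ValidationError,
    enumerate_closed_sets,
    k_shortest_paths,
)


@dataclass(frozen=True)
class RandomNetConfig:
    n_species: int
    n_reactions: int
    seed: int

    def __post_init__(self):
        if self.n_species < 2:
            raise ValidationError("need at least two species")
        if self.n_reactions < 0:
            raise ValidationError("n_reactions must be non-negative")
        if self.n_reactions > self.max_rules:
            raise ValidationError(
                f"{self.n_reactions} rules infeasible: at most {self.max_rules} "
                f"distinct bimolecular rules on {self.n_species} species"
            )

    @property
    def max_rules(self) -> int:
        return math.comb(self.n_species, 2) * self.n_species


def _species_labels(n: int) -> List[str]:
    width = len(str(n - 1))
    return [f"S{i:0{width}d}" for i in range(n)]


def random_network(config: RandomNetConfig, name: Optional[str] = None) -> ReactionNetwork:
    """A seeded random network of distinct bimolecular rules."""
    rng = np.random.default_rng(config.seed)
    labels = _species_labels(config.n_species)
    n = config.n_species
    seen = set()
    reactions: List[Reaction] = []
    while len(reactions) < config.n_reactions:
        i, j = rng.choice(n, size=2, replace=False)
        p = int(rng.integers(n))
        sig = (frozenset((int(i), int(j))), p)
        if sig in seen:
            continue
        seen.add(sig)
        reactions.append(
            Reaction(
                id=f"r{len(reactions) + 1:04d}",
                reactants=frozenset((labels[int(i)], labels[int(j)])),
                products=frozenset((labels[p],)),
            )
        )
    return ReactionNetwork(
        labels, reactions, name=name or f"random_{config.n_species}x{config.n_reactions}_s{config.seed}"
    )


def count_paths(network: ReactionNetwork, k: int) -> int:
    """Total number of k-limited shortest paths over all ordered species
    pairs (saturates at k * n * (n-1))."""
    total = 0
    for s in network.species:
        for t in network.species:
            if s != t:
                total += len(k_shortest_paths(network, s, t, k))
    return total


@dataclass
class SurveyResult:
    """Per-(size, density) Monte-Carlo summary rows."""

    rows: pd.DataFrame

    def argmax_reactions(self) -> Dict[int, int]:
        """Reaction count maximizing mean code pairs, per network size."""
        out = {}
        for n, grp in self.rows.groupby("n_species"):
            out[int(n)] = int(grp.loc[grp["mean_cp"].idxmax(), "n_reactions"])
        return out

    def optimum_slope(self) -> float:
        """Least-squares slope (through the origin) of r*(n) against n."""
        opt = self.argmax_reactions()
        ns = np.array(sorted(opt), dtype=float)
        rs = np.array([opt[int(n)] for n in ns], dtype=float)
        return float((ns @ rs) / (ns @ ns))


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def null_model_estimate(
    n_species: int,
    n_reactions: int,
    replicates: int,
    k: int = 20,
    seed: int = 0,
    method: str = "closure",
    closed_set_cap: int = 200_000,
    with_paths: bool = True,
) -> pd.Series:
    """Means/SEMs of closed sets, k-limited paths and code pairs across
    seeded random-network replicates."""
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(replicates)
    n_closed, n_paths, n_cp, caps_l = [], [], [], []
    for s in child_seeds:
        net = random_network(RandomNetConfig(n_species, n_reactions, int(s)))
        closed = enumerate_closed_sets(net, cap=closed_set_cap)
        n_closed.append(len(closed.masks))
        if with_paths:
            n_paths.append(count_paths(net, k))
        report = find_codes(net, method=method, k=k, cap=closed_set_cap)
        n_cp.append(report.n_cp)
        caps_l.append(report.L)
    n_closed_a = np.asarray(n_closed, dtype=float)
    n_cp_a = np.asarray(n_cp, dtype=float)
    l_a = np.asarray(caps_l, dtype=float)
    data = {
        "n_species": n_species,
        "n_reactions": n_reactions,
        "replicates": replicates,
        "mean_closed": float(n_closed_a.mean()),
        "sem_closed": _sem(n_closed_a),
        "mean_cp": float(n_cp_a.mean()),
        "sem_cp": _sem(n_cp_a),
        "mean_L": float(l_a.mean()),
        "sem_L": _sem(l_a),
    }
    if with_paths:
        n_paths_a = np.asarray(n_paths, dtype=float)
        data["mean_paths"] = float(n_paths_a.mean())
        data["sem_paths"] = _sem(n_paths_a)
    else:
        data["mean_paths"] = float("nan")
        data["sem_paths"] = float("nan")
    return pd.Series(data)


def density_survey(
    n_species_list: Sequence[int],
    density_grid: Sequence[float],
    replicates: int,
    k: int = 20,
    seed: int = 0,
    method: str = "closure",
    closed_set_cap: int = 200_000,
    with_paths: bool = False,
) -> SurveyResult:
    """Full-factorial Monte-Carlo survey over sizes and densities
    (density = reactions per species)."""
    if not n_species_list or not len(density_grid):
        raise ValidationError("size and density grids must be non-empty")
    rows = []
    root = np.random.SeedSequence(seed)
    cell_seeds = root.generate_state(len(n_species_list) * len(density_grid))
    idx = 0
    for n in n_species_list:
        for d in density_grid:
            r = int(round(d * n))
            row = null_model_estimate(
                n,
                r,
                replicates,
                k=k,
                seed=int(cell_seeds[idx]),
                method=method,
                closed_set_cap=closed_set_cap,
                with_paths=with_paths,
            )
            row["density"] = float(d)
            rows.append(row)
            idx += 1
    return SurveyResult(rows=pd.DataFrame(rows))


def randomize_network(network: ReactionNetwork, n_replacements: int, seed: int = 0) -> ReactionNetwork:
    """Rewire ``n_replacements`` randomly chosen rules, resampling their
    species while preserving each rule's reactant/product arity."""
    if n_replacements < 0:
        raise ValidationError("n_replacements must be non-negative")
    if n_replacements == 0:
        return network
    rng = np.random.default_rng(seed)
    species = list(network.species)
    n = len(species)
    rules: List[Tuple[frozenset, frozenset]] = [(r.reactants, r.products) for r in network.reactions]
    sigs = set(rules)
    for _ in range(n_replacements):
        pos = int(rng.integers(len(rules)))
        old = rules[pos]
        n_react, n_prod = len(old[0]), len(old[1])
        for _attempt in range(1000):
            new_react = frozenset(species[int(i)] for i in rng.choice(n, size=n_react, replace=False))
            new_prod = frozenset(species[int(i)] for i in rng.choice(n, size=n_prod, replace=True))
            if len(new_prod) != n_prod:
                continue
            sig = (new_react, new_prod)
            if sig not in sigs:
                break
        else:  # pragma: no cover - saturated rule space
            continue
        sigs.discard(old)
        sigs.add(sig)
        rules[pos] = sig
    reactions = [
        Reaction(id=f"r{i + 1:04d}", reactants=re_, products=pr) for i, (re_, pr) in enumerate(rules)
    ]
    return ReactionNetwork(species, reactions, name=f"{network.name}_randomized")
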