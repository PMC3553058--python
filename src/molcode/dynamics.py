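"""Mass-action kinetics for the phosphorylation-cascade demonstration.

The concentration-level code of the two-step cascade is shown by
simulating the network under the two alternative branch contexts and
discretizing the steady-state Tp/T response into high/low levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .model_builders import build_phospho_cascade
from .network_core import ReactionNetwork, ValidationError


@dataclass
class KineticModel:
    network: ReactionNetwork
    rates: Mapping[str, float]
    initial: Mapping[str, float]
    t_end: float = 200.0

    def __post_init__(self):
        for r in self.network.reactions:
            if r.id not in self.rates:
                raise ValidationError(f"missing rate for reaction {r.id!r}")
            if self.rates[r.id] <= 0:
                raise ValidationError(f"rate for {r.id!r} must be positive")
        for s in self.network.species:
            if self.initial.get(s, 0.0) < 0:
                raise ValidationError(f"negative initial concentration for {s!r}")
        if self.t_end <= 0:
            raise ValidationError("t_end must be positive")


@dataclass
class Trajectories:
    times: np.ndarray
    concentrations: np.ndarray  # shape (n_species, n_times)
    species: Tuple[str, ...]
    converged: bool

    def final(self, species: str) -> float:
        return float(self.concentrations[self.species.index(species), -1])

    @property
    def steady_state(self) -> Dict[str, float]:
        return {s: self.final(s) for s in self.species}


def default_model(network: ReactionNetwork, initial: Mapping[str, float], t_end: float = 200.0) -> KineticModel:
    """Unit rate constants everywhere; unspecified initials are zero."""
    init = {s: float(initial.get(s, 0.0)) for s in network.species}
    return KineticModel(network=network, rates={r.id: 1.0 for r in network.reactions}, initial=init, t_end=t_end)


def simulate_mass_action(
    model: KineticModel,
    n_eval: int = 200,
    steady_state_rtol: float = 1e-8,
) -> Trajectories:
    """Integrate mass-action ODEs; the steady-state flag compares the last
    10% of the trajectory against the final state."""
    net = model.network
    species = net.species
    idx = {s: i for i, s in enumerate(species)}
    terms = []  # (rate, reactant index/order array, net stoichiometry vector)
    for r in net.reactions:
        k = model.rates[r.id]
        r_idx = np.array([idx[s] for s in sorted(r.reactants)], dtype=int)
        r_ord = np.array([r.reactant_stoich[s] for s in sorted(r.reactants)], dtype=float)
        net_st = np.zeros(len(species))
        for s, c in r.reactant_stoich.items():
            net_st[idx[s]] -= c
        for s, c in r.product_stoich.items():
            net_st[idx[s]] += c
        terms.append((k, r_idx, r_ord, net_st))

    def rhs(_t, y):
        yc = np.clip(y, 0.0, None)
        dy = np.zeros_like(y)
        for k, r_idx, r_ord, net_st in terms:
            flux = k * np.prod(yc[r_idx] ** r_ord) if len(r_idx) else k
            dy += flux * net_st
        return dy

    y0 = np.array([model.initial.get(s, 0.0) for s in species], dtype=float)
    t_eval = np.linspace(0.0, model.t_end, n_eval)
    sol = solve_ivp(rhs, (0.0, model.t_end), y0, method="LSODA", t_eval=t_eval, rtol=1e-9, atol=1e-12)
    conc = sol.y
    tail = conc[:, int(0.9 * conc.shape[1]):]
    scale = np.abs(conc[:, -1]) + 1e-12
    rel_change = np.max(np.abs(tail - conc[:, -1:]) / scale[:, None])
    return Trajectories(
        times=sol.t,
        concentrations=conc,
        species=tuple(species),
        converged=bool(sol.success and rel_change < max(steady_state_rtol, 1e-6)),
    )


@dataclass
class ResponseCurve:
    input_values: np.ndarray
    ratio_values: np.ndarray
    context_label: str

    @property
    def trend_sign(self) -> int:
        """+1 monotone increasing, -1 decreasing, 0 otherwise."""
        d = np.diff(self.ratio_values)
        if np.all(d > 0):
            return 1
        if np.all(d < 0):
            return -1
        return 0


def response_curve(
    context: str,
    x0_grid: Sequence[float],
    rates: Optional[Mapping[str, float]] = None,
    branch_total: float = 1.0,
    target_total: float = 1.0,
    t_end: float = 500.0,
) -> ResponseCurve:
    """Steady-state Tp/T of the two-step cascade over an X0 grid.

    Context "C1" places the A branch (active unphosphorylated), "C2" the
    B branch (active phosphorylated).
    """
    if context not in ("C1", "C2"):
        raise ValidationError("context must be 'C1' or 'C2'")
    net = build_phospho_cascade(two_step=True)
    ratios = []
    for x0 in x0_grid:
        initial = {"X0": float(x0), "T": target_total}
        initial["A" if context == "C1" else "B"] = branch_total
        model = default_model(net, initial, t_end=t_end)
        if rates is not None:
            model = KineticModel(network=net, rates=dict(rates), initial=model.initial, t_end=t_end)
        traj = simulate_mass_action(model)
        t_conc = traj.final("T")
        tp_conc = traj.final("Tp")
        ratios.append(tp_conc / t_conc if t_conc > 1e-12 else float("inf"))
    return ResponseCurve(
        input_values=np.asarray(list(x0_grid), dtype=float),
        ratio_values=np.asarray(ratios, dtype=float),
        context_label=context,
    )


def level_code_check(curve_c1: ResponseCurve, curve_c2: ResponseCurve, threshold: float) -> bool:
    """True iff thresholding the two response curves yields crossed
    high/low mappings: X0-low -> Tp-high / X0-high -> Tp-low under one
    context and the opposite under the other."""
    if not np.array_equal(curve_c1.input_values, curve_c2.input_values):
        raise ValidationError("response curves must share the same X0 grid")
    lo1, hi1 = curve_c1.ratio_values[0], curve_c1.ratio_values[-1]
    lo2, hi2 = curve_c2.ratio_values[0], curve_c2.ratio_values[-1]
    mapping1 = (lo1 > threshold, hi1 > threshold)  # (X0-low level, X0-high level)
    mapping2 = (lo2 > threshold, hi2 > threshold)
    crossed = mapping1 == (True, False) and mapping2 == (False, True)
    crossed_rev = mapping1 == (False, True) and mapping2 == (True, False)
    return bool(crossed or crossed_rev)
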