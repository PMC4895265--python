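"""Temperate-phage processes: invasion, infection, lysis, lysogeny.

A single generic phage population infects cells able to utilize the S1
substrate.  Infection proceeds in three stages — adsorption of free phage
to healthy susceptible cells, intracellular replication, and burst after
lysis.  Whether a new infection commits to the lytic or the lysogenic
pathway depends on the host deme's well-being at the moment of
infestation: favorable conditions (high per-cell resource gain and/or a
growing census) route infections lytically; starving, shrinking demes are
lysogenized.  Lysogens carry the prophage, are immune to superinfection,
and reproduce; when their conditions improve, a fraction is induced back
to the lytic pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .community import S1, HabitatGrid, NodeState, PopulationDeme
from .randomness import draw_binomial, draw_count, largest_remainder


@dataclass(frozen=True)
class PhageParams:
    """Phage life-history constants.

    adsorption_a  per-generation encounter rate (per phage per cell,
                  normalized to the node volume)
    burst_B       phage particles released per lysed cell
    latency_L     generations from lytic commitment to lysis
    decay_delta_p per-generation free-phage decay fraction
    induction_pi  per-generation fraction of lysogens induced when
                  conditions are favorable
    favorable_g   per-cell resource-gain threshold defining "favorable"
    inoculum      free phage added at an invasion event
    """

    adsorption_a: float = 1e-3
    burst_B: float = 50.0
    latency_L: int = 2
    decay_delta_p: float = 0.1
    induction_pi: float = 0.005
    favorable_g: float = 0.06
    inoculum: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.adsorption_a, self.burst_B, self.latency_L,
               self.inoculum, self.favorable_g) < 0:
            raise ValueError("phage parameters must be nonnegative")
        if not (0 <= self.decay_delta_p <= 1 and 0 <= self.induction_pi <= 1):
            raise ValueError("decay and induction fractions must be in [0,1]")


@dataclass(frozen=True)
class InvasionEvent:
    """A scheduled release of free phage into one node."""

    generation: int
    node: tuple[int, int]
    inoculum: float = 1000.0

    def __post_init__(self) -> None:
        if self.generation < 1:
            raise ValueError("invasion generation must be >= 1")


def invade(grid: HabitatGrid, event: InvasionEvent) -> HabitatGrid:
    """Release the inoculum of free phage at the event's node."""
    if event.node not in grid:
        raise ValueError(f"invasion node {event.node} outside the grid")
    grid[event.node].free_phage += event.inoculum
    return grid


def deme_is_susceptible(deme: PopulationDeme) -> bool:
    """Host range: S1-utilizers; only healthy (non-lysogen) cells adsorb."""
    return S1 in deme.key.util_set


def choose_pathway(deme: PopulationDeme, last_gain_g: float,
                   params: PhageParams) -> str:
    """Lytic/lysogenic decision for this deme's new infections.

    Lytic iff conditions are favorable: per-cell resource gain at or above
    ``favorable_g``, or positive population dynamics (current healthy
    count above the previous generation's).  Otherwise lysogenic.
    """
    if last_gain_g >= params.favorable_g or deme.healthy > deme.last_total:
        return "lytic"
    return "lysogenic"


def _favorable(deme: PopulationDeme, params: PhageParams) -> bool:
    return choose_pathway(deme, deme.last_gain, params) == "lytic"


@dataclass
class InfectionResult:
    infections: int = 0
    lysed: int = 0
    burst_released: float = 0.0


def adsorb_and_infect(node: NodeState, params: PhageParams,
                      rng: Optional[np.random.Generator],
                      deterministic: bool = False) -> InfectionResult:
    """Adsorption of free phage to susceptible healthy cells in one node.

    Expected infections are adsorption_a * free_phage * susceptible cells,
    capped at both the free phage and the susceptible cell count (each
    infection consumes one phage and one cell).  Infections are
    apportioned across susceptible demes and classes proportionally to
    counts; each infected deme routes its infections via choose_pathway.
    """
    result = InfectionResult()
    susceptible = [(sid, d) for sid, d in sorted(node.demes.items())
                   if deme_is_susceptible(d) and d.healthy > 0]
    total_susceptible = sum(d.healthy for _, d in susceptible)
    if total_susceptible == 0 or node.free_phage < 1:
        return result
    cap = min(int(node.free_phage), total_susceptible)
    expected = params.adsorption_a * node.free_phage * total_susceptible
    if deterministic or rng is None:
        n_inf = min(cap, int(round(expected)))
    else:
        n_inf = min(cap, int(rng.poisson(expected)))
    if n_inf == 0:
        return result
    shares = largest_remainder(
        [n_inf * d.healthy / total_susceptible for _, d in susceptible],
        n_inf)
    for (sid, deme), n_deme in zip(susceptible, shares):
        n_deme = min(n_deme, deme.healthy)
        if n_deme == 0:
            continue
        pathway = choose_pathway(deme, deme.last_gain, params)
        classes = sorted(deme.classes.items())
        healthy = deme.healthy
        class_shares = largest_remainder(
            [n_deme * c / healthy for _, c in classes], n_deme)
        mean_before = deme.mean_alleles()
        taken = 0
        for (alleles, count), n_cls in zip(classes, class_shares):
            n_cls = min(n_cls, deme.classes.get(alleles, 0))
            if n_cls == 0:
                continue
            deme.classes[alleles] -= n_cls
            if deme.classes[alleles] == 0:
                del deme.classes[alleles]
            taken += n_cls
        if pathway == "lytic":
            deme.lytic_infected[params.latency_L] = (
                deme.lytic_infected.get(params.latency_L, 0) + taken)
        else:
            deme.add_lysogens(taken, mean_before)
        result.infections += taken
        node.free_phage -= taken
    node.free_phage = max(0.0, node.free_phage)
    return result


def induce_lysogens(node: NodeState, params: PhageParams,
                    rng: Optional[np.random.Generator],
                    deterministic: bool = False) -> int:
    """Switch a fraction of lysogens to the lytic pathway when conditions
    are favorable (same predicate as the infection-time decision)."""
    induced_total = 0
    for deme in node.demes.values():
        if deme.lysogen_count == 0 or not _favorable(deme, params):
            continue
        induced = draw_binomial(deme.lysogen_count, params.induction_pi,
                                rng, deterministic)
        if induced:
            deme.lysogen_count -= induced
            deme.lytic_infected[params.latency_L] = (
                deme.lytic_infected.get(params.latency_L, 0) + induced)
            induced_total += induced
    return induced_total


def progress_lytic(node: NodeState, params: PhageParams) -> InfectionResult:
    """Advance lytic latency clocks; lyse cells whose clock runs out.

    Every latency counter is decremented; cells reaching zero (or entering
    at latency 0) are removed and each releases ``burst_B`` free phage.
    """
    result = InfectionResult()
    for deme in node.demes.values():
        if not deme.lytic_infected:
            continue
        advanced: dict[int, int] = {}
        for lat, count in deme.lytic_infected.items():
            if lat <= 1:  # counter reaches 0 now (lat 0 = degenerate
                result.lysed += count  # same-generation lysis)
            else:
                advanced[lat - 1] = advanced.get(lat - 1, 0) + count
        deme.lytic_infected = advanced
    if result.lysed:
        result.burst_released = params.burst_B * result.lysed
        node.free_phage += result.burst_released
    return result


def decay_phage(node: NodeState, params: PhageParams,
                rng: Optional[np.random.Generator] = None,
                deterministic: bool = True) -> NodeState:
    """Free-phage decay: deterministic geometric loss or binomial thinning."""
    if params.decay_delta_p <= 0 or node.free_phage <= 0:
        return node
    if deterministic or rng is None:
        node.free_phage *= (1.0 - params.decay_delta_p)
    else:
        whole = int(np.floor(node.free_phage))
        frac = node.free_phage - whole
        survivors = whole - draw_binomial(whole, params.decay_delta_p, rng,
                                          False)
        node.free_phage = survivors + frac * (1.0 - params.decay_delta_p)
    return node


def phage_step_node(node: NodeState, params: PhageParams,
                    rng: Optional[np.random.Generator],
                    deterministic: bool = False) -> InfectionResult:
    """One generation of phage processes in a node, in the fixed order
    adsorption/infection -> induction -> lysis progression -> decay."""
    result = adsorb_and_infect(node, params, rng, deterministic)
    induce_lysogens(node, params, rng, deterministic)
    lysis = progress_lytic(node, params)
    result.lysed += lysis.lysed
    result.burst_released += lysis.burst_released
    decay_phage(node, params, rng, deterministic)
    return result
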