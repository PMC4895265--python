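"""Per-node substrate uptake, product synthesis, reproduction and death.

Each generation, every deme in a node demands up to ``demand_per_cell_q``
units of each substrate it can utilize.  Demands on a shared pool are
granted proportionally when the pool is oversubscribed (the node is a
well-mixed volume).  Per-cell resource gain drives births through a
yield/maintenance law; death is a constant per-capita hazard.  Cells
carrying synthesis genes secrete specific substrates in proportion to
their uptake; secretions are buffered and credited to the pools only after
every deme has fed, so results do not depend on deme order.

Infection sub-states matter here: lysogens feed, reproduce (offspring are
lysogens) and secrete like healthy cells; lytic-infected cells feed — the
resources go to phage replication — but produce no offspring and secrete
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .community import NodeState, PopulationDeme, key_indices
from .randomness import draw_binomial, draw_count


@dataclass(frozen=True)
class GrowthParams:
    """Demographic and metabolic constants.

    yield_Y          offspring per unit resource gained above maintenance
    death_rate_delta per-generation per-cell death probability
    demand_per_cell_q max uptake per cell per substrate per generation (units)
    synth_yield      secreted units per unit uptake per synthesis gene
    maintenance_m    resource units per cell per generation before reproduction
    """

    yield_Y: float = 5.0
    death_rate_delta: float = 0.05
    demand_per_cell_q: float = 0.1
    synth_yield: float = 0.5
    maintenance_m: float = 0.02

    def __post_init__(self) -> None:
        if min(self.yield_Y, self.death_rate_delta, self.demand_per_cell_q,
               self.synth_yield, self.maintenance_m) < 0:
            raise ValueError("growth parameters must be nonnegative")
        if not self.death_rate_delta < 1:
            raise ValueError("death_rate_delta must be < 1")


def allocate_uptake(demands: dict, pools: dict) -> dict:
    """Grant substrate demands against shared node pools.

    ``demands`` maps (requester, substrate) -> requested amount.  Per
    substrate, if the pool covers the summed demand every request is granted
    in full; otherwise grants are scaled proportionally so the pool is
    exactly drained.  ``pools`` is decremented in place by granted totals.
    """
    by_substrate: dict[str, float] = {}
    for (_, substrate), req in demands.items():
        if req < 0:
            raise ValueError("negative demand")
        by_substrate[substrate] = by_substrate.get(substrate, 0.0) + req
    grants: dict = {}
    granted_total: dict[str, float] = {}
    for key, req in demands.items():
        substrate = key[1]
        total = by_substrate[substrate]
        avail = pools.get(substrate, 0.0)
        if total <= avail or total == 0.0:
            g = req
        else:
            g = req * avail / total
        grants[key] = g
        granted_total[substrate] = granted_total.get(substrate, 0.0) + g
    for substrate, g in granted_total.items():
        pools[substrate] = max(0.0, pools[substrate] - g)
    return grants


@dataclass
class GrowthResult:
    births: int = 0
    deaths: int = 0
    secreted: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.secreted is None:
            self.secreted = {}


def grow_deme(deme: PopulationDeme, granted: dict, params: GrowthParams,
              rng: Optional[np.random.Generator],
              deterministic: bool = False) -> GrowthResult:
    """Apply one generation of feeding, birth and death to a deme.

    ``granted`` maps substrate -> amount granted to this deme as a whole;
    it is shared among all of the deme's cells (healthy, lysogen and
    lytic-infected) in proportion to head count, so per-cell uptake of
    substrate s is granted(s)/total_cells.  A class with allele vector e
    gains g = sum_s e(s) * uptake(s) per cell; expected births are
    cells * yield_Y * max(0, g - maintenance_m), expected deaths
    cells * death_rate_delta.  Stochastic mode draws Poisson births and
    binomial deaths; deterministic mode rounds expectations.

    Returns births, deaths and the secreted amounts (buffered by the
    caller until all demes in the node have fed).
    """
    for v in granted.values():
        if v < 0:
            raise ValueError("negative granted uptake")
    total = deme.total_cells
    result = GrowthResult()
    deme.last_total = deme.healthy
    if total == 0:
        deme.last_gain = 0.0
        return result
    uptake_per_cell = {s: amount / total for s, amount in granted.items()}
    u_total = sum(uptake_per_cell.values())
    _, util_idx, synth_idx = key_indices(deme.key)
    util_u = [(i, uptake_per_cell[s]) for i, s in util_idx
              if uptake_per_cell.get(s, 0.0) > 0.0]

    gain_weight = 0.0
    gain_cells = 0
    secreted = result.secreted

    def settle(count: int, eff_vec: tuple) -> tuple[int, int, float]:
        """(births, deaths, gain) for ``count`` reproducing cells."""
        g = 0.0
        for i, u in util_u:
            g += eff_vec[i] * u
        expected_births = count * params.yield_Y * max(
            0.0, g - params.maintenance_m)
        births = draw_count(expected_births, rng, deterministic)
        deaths = min(count, draw_binomial(count, params.death_rate_delta,
                                          rng, deterministic))
        if u_total > 0.0:
            for i, sub in synth_idx:
                amt = params.synth_yield * eff_vec[i] * u_total * count
                if amt > 0:
                    secreted[sub] = secreted.get(sub, 0.0) + amt
        return births, deaths, g

    new_classes: dict[tuple, int] = {}
    for alleles, count in deme.classes.items():
        births, deaths, g = settle(count, alleles)
        gain_weight += g * count
        gain_cells += count
        result.births += births
        result.deaths += deaths
        new_count = count + births - deaths
        if new_count > 0:
            new_classes[alleles] = new_count
    deme.classes = new_classes

    if deme.lysogen_count > 0:
        eff_vec = deme.lysogen_eff or deme.mean_alleles()
        if eff_vec is None:
            eff_vec = (0.0,) * len(deme.key.genes)
        births, deaths, g = settle(deme.lysogen_count, eff_vec)
        gain_weight += g * deme.lysogen_count
        gain_cells += deme.lysogen_count
        result.births += births
        result.deaths += deaths
        deme.lysogen_count += births - deaths

    # Lytic-infected cells feed (their share was granted) but neither
    # reproduce, die of old age, nor secrete: uptake fuels phage replication.
    if gain_cells > 0:
        deme.last_gain = gain_weight / gain_cells
    else:
        deme.last_gain = 0.0
    return result


def node_demands(node: NodeState, params: GrowthParams) -> dict:
    """Uptake demands of every deme in a node: cells * q per utilized gene."""
    demands: dict = {}
    for sid, deme in node.demes.items():
        cells = deme.total_cells
        if cells == 0:
            continue
        for sub in deme.key.util_set:
            demands[(sid, sub)] = cells * params.demand_per_cell_q
    return demands


def grow_node(node: NodeState, params: GrowthParams,
              rng: Optional[np.random.Generator],
              deterministic: bool = False) -> GrowthResult:
    """Feed and grow every deme in a node; secretions stay buffered.

    Returns the aggregate births/deaths and the node's total secreted
    amounts; the caller credits them to pools after all nodes have fed.
    """
    demands = node_demands(node, params)
    grants = allocate_uptake(demands, node.pools)
    result = GrowthResult()
    for sid, deme in node.demes.items():
        granted = {sub: grants.get((sid, sub), 0.0)
                   for sub in deme.key.util_set}
        r = grow_deme(deme, granted, params, rng, deterministic)
        result.births += r.births
        result.deaths += r.deaths
        for sub, amt in r.secreted.items():
            result.secreted[sub] = result.secreted.get(sub, 0.0) + amt
    return result
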