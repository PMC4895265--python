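"""Spatial transport: in-flow, directed flow, diffusion, chemotaxis.

The habitat is fed non-specific substrate (N1) through its upper row and
leftmost column.  A directed flow advects a fraction of every node's
transportable content toward the lower-right; content leaving the terminal
corner (height, width) exits the system.  Diffusion exchanges a symmetric
fraction with each orthogonal neighbor (reflecting boundaries).  When
chemotaxis is enabled, a fraction of each deme's motile cells (healthy and
lysogens) relocates to the most attractive neighboring node, attractiveness
being the efficiency-weighted sum of consumable substrate pools.

All updates are synchronous: exports are computed from the pre-step state
for every node, then applied at once, so results are independent of node
iteration order.  Fractional cell counts are resolved by largest-remainder
rounding in deterministic mode and multinomial draws in stochastic mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import N1, HabitatGrid, PopulationDeme, key_indices
from .randomness import (
    PHASE_CHEMOTAXIS,
    PHASE_DIFFUSION,
    PHASE_FLOW,
    split_counts,
    substream,
)


@dataclass(frozen=True)
class TransportParams:
    """Transport intensities (all per generation).

    inflow_rate   N1 units supplied to each in-flow node
    flow_phi      fraction of transportable content advected downstream
    diff_d        fraction exchanged with each orthogonal neighbor
    chemotaxis_enabled  whether cells actively relocate along gradients
    chemo_fraction      fraction of motile cells that relocate per move
    outflow_enabled     content past the terminal corner leaves the system
                        (disabled only for closed-system conservation tests)
    """

    inflow_rate: float = 5.0
    flow_phi: float = 0.1
    diff_d: float = 0.05
    chemotaxis_enabled: bool = False
    chemo_fraction: float = 0.2
    outflow_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.flow_phi < 1 and 0 <= self.diff_d < 1
                and 0 <= self.chemo_fraction < 1):
            raise ValueError("transport fractions must lie in [0, 1)")
        if self.flow_phi + 4 * self.diff_d >= 1:
            raise ValueError("stability requires flow_phi + 4*diff_d < 1")
        if self.inflow_rate < 0:
            raise ValueError("inflow_rate must be nonnegative")


def inflow_nodes(grid: HabitatGrid) -> list[tuple[int, int]]:
    """Nodes of the upper row and leftmost column ((1,1) counted once)."""
    coords = [(1, c) for c in range(1, grid.width + 1)]
    coords += [(r, 1) for r in range(2, grid.height + 1)]
    return coords


def apply_inflow(grid: HabitatGrid, params: TransportParams) -> HabitatGrid:
    """Supply N1 to every in-flow node; nothing else is touched."""
    for coords in inflow_nodes(grid):
        grid[coords].pools[N1] += params.inflow_rate
    return grid


def _flow_targets(grid: HabitatGrid, coords: tuple[int, int]) -> list:
    """Downstream targets and weights; target None = out of the system."""
    r, c = coords
    down = (r + 1, c) if r < grid.height else None
    right = (r, c + 1) if c < grid.width else None
    if down and right:
        return [(down, 0.5), (right, 0.5)]
    if right:  # last row: everything continues right
        return [(right, 1.0)]
    if down:  # last column: everything continues down
        return [(down, 1.0)]
    return [(None, 1.0)]  # terminal corner: out-flow


def _scatter_deme(deme: PopulationDeme, fractions: list, dests: list,
                  moves: list, rng, deterministic) -> int:
    """Split a deme's cells among [stay, dest_1, ...] fractions in place.

    Each allele class, the lysogen pool and each latency slot is
    apportioned independently (largest-remainder or multinomial), so the
    emigrating parcels preserve sub-state composition up to rounding.
    Emigrants are appended to ``moves`` as (dest, deme, kind, payload, n)
    records; a dest of None counts as out-flow.  Returns the number of
    cells that left through a None destination.
    """
    outflow = 0
    for alleles, count in list(deme.classes.items()):
        parts = split_counts(count, fractions, rng, deterministic)
        if parts[0] != count:
            deme.classes[alleles] = parts[0]
            for dest, n in zip(dests, parts[1:]):
                if n:
                    if dest is None:
                        outflow += n
                    else:
                        moves.append((dest, deme, "class", alleles, n))
    if deme.lysogen_count:
        parts = split_counts(deme.lysogen_count, fractions, rng,
                             deterministic)
        if parts[0] != deme.lysogen_count:
            deme.lysogen_count = parts[0]
            for dest, n in zip(dests, parts[1:]):
                if n:
                    if dest is None:
                        outflow += n
                    else:
                        moves.append((dest, deme, "lysogen", None, n))
    if deme.lytic_infected:
        for lat, count in list(deme.lytic_infected.items()):
            parts = split_counts(count, fractions, rng, deterministic)
            if parts[0] != count:
                deme.lytic_infected[lat] = parts[0]
                for dest, n in zip(dests, parts[1:]):
                    if n:
                        if dest is None:
                            outflow += n
                        else:
                            moves.append((dest, deme, "lytic", lat, n))
    return outflow


def _apply_moves(grid: HabitatGrid, moves: list) -> None:
    for dest, source, kind, payload, n in moves:
        target = grid[dest].get_or_create_deme(source.species_id, source.key)
        if kind == "class":
            target.add_cells(payload, n)
        elif kind == "lysogen":
            target.add_lysogens(n, source.lysogen_eff)
        else:
            target.lytic_infected[payload] = (
                target.lytic_infected.get(payload, 0) + n)


def _transport_step(grid: HabitatGrid, stencil, fraction_moved: float,
                    seed: int, phase: int, deterministic: bool) -> int:
    """Shared synchronous engine for flow and diffusion.

    ``stencil(coords)`` returns [(target_or_None, weight), ...] with
    weights summing to 1; ``fraction_moved`` of every transportable
    quantity leaves each node and is divided by those weights.  Returns
    the number of cells that left the system (out-flow).
    """
    if fraction_moved <= 0:
        return 0
    sub_moves: list = []   # (target, substrate, amount)
    phage_moves: list = []
    cell_moves: list = []
    outflow_cells = 0
    for idx, node in enumerate(grid.iter_nodes()):
        targets = stencil(node.coords)
        if not targets:
            continue
        for s, amount in node.pools.items():
            moved = amount * fraction_moved
            if moved > 0:
                node.pools[s] = amount - moved
                for tgt, w in targets:
                    if tgt is not None:
                        sub_moves.append((tgt, s, moved * w))
        if node.free_phage > 0:
            moved = node.free_phage * fraction_moved
            node.free_phage -= moved
            for tgt, w in targets:
                if tgt is not None:
                    phage_moves.append((tgt, moved * w))
        if node.demes:
            rng = None
            if not deterministic:
                rng = substream(seed, grid.generation, phase, idx)
            fractions = [1.0 - fraction_moved] + [
                fraction_moved * w for _, w in targets]
            dests = [tgt for tgt, _ in targets]
            for deme in node.demes.values():
                outflow_cells += _scatter_deme(deme, fractions, dests,
                                               cell_moves, rng,
                                               deterministic)
    for tgt, s, amount in sub_moves:
        grid[tgt].pools[s] += amount
    for tgt, amount in phage_moves:
        grid[tgt].free_phage += amount
    _apply_moves(grid, cell_moves)
    for node in grid.iter_nodes():
        node.prune()
    return outflow_cells


def apply_flow(grid: HabitatGrid, params: TransportParams, seed: int = 0,
               deterministic: bool = True) -> int:
    """Advect fraction ``flow_phi`` of every node's content downstream.

    Interior nodes split their export equally between the down and right
    neighbors; the last row forwards right, the last column down, and the
    terminal corner exports out of the system (unless out-flow is disabled
    for closed-system tests).  Returns the number of out-flowed cells.
    """

    def stencil(coords):
        targets = _flow_targets(grid, coords)
        if not params.outflow_enabled:
            targets = [(t, w) for t, w in targets if t is not None]
            if not targets:
                return []  # closed corner keeps its content
        return targets

    return _transport_step(grid, stencil, params.flow_phi, seed,
                           PHASE_FLOW, deterministic)


def apply_diffusion(grid: HabitatGrid, params: TransportParams,
                    seed: int = 0, deterministic: bool = True) -> HabitatGrid:
    """Symmetric exchange of ``diff_d`` per orthogonal neighbor.

    Boundaries reflect: a node only exports along links that exist, so a
    closed grid conserves every quantity exactly.
    """
    if params.diff_d <= 0:
        return grid

    # _transport_step moves a single global fraction; diffusion moves
    # diff_d per existing neighbor, so it is handled directly with the
    # same synchronous pattern.
    sub_moves: list = []
    phage_moves: list = []
    cell_moves: list = []
    neighbor_cache = {coords: grid.neighbors(coords) for coords in grid.nodes}
    for idx, node in enumerate(grid.iter_nodes()):
        neigh = neighbor_cache[node.coords]
        if not neigh:
            continue
        frac_out = params.diff_d * len(neigh)
        for s, amount in node.pools.items():
            moved = amount * params.diff_d
            if moved > 0:
                node.pools[s] = amount - moved * len(neigh)
                for tgt in neigh:
                    sub_moves.append((tgt, s, moved))
        if node.free_phage > 0:
            moved = node.free_phage * params.diff_d
            node.free_phage -= moved * len(neigh)
            for tgt in neigh:
                phage_moves.append((tgt, moved))
        if node.demes:
            rng = None
            if not deterministic:
                rng = substream(seed, grid.generation, PHASE_DIFFUSION, idx)
            fractions = [1.0 - frac_out] + [params.diff_d] * len(neigh)
            for deme in node.demes.values():
                _scatter_deme(deme, fractions, neigh, cell_moves, rng,
                              deterministic)
    for tgt, s, amount in sub_moves:
        grid[tgt].pools[s] += amount
    for tgt, amount in phage_moves:
        grid[tgt].free_phage += amount
    _apply_moves(grid, cell_moves)
    for node in grid.iter_nodes():
        node.prune()
    return grid


def node_attractiveness(node, deme: PopulationDeme,
                        eff: "tuple | None" = None) -> float:
    """Efficiency-weighted consumable substrate mass a deme senses."""
    if eff is None:
        eff = deme.mean_alleles()
    if eff is None:
        return 0.0
    total = 0.0
    for i, sub in key_indices(deme.key)[1]:
        total += eff[i] * node.pools.get(sub, 0.0)
    return total


def apply_chemotaxis(grid: HabitatGrid, params: TransportParams,
                     seed: int = 0, deterministic: bool = True
                     ) -> HabitatGrid:
    """Relocate motile cells toward the most attractive neighbor node.

    For each deme, attractiveness of a node is the sum over utilized
    substrates of mean efficiency times pool size.  If the best orthogonal
    neighbor strictly beats the current node (ties broken toward the
    lexicographically smallest coordinates), ``chemo_fraction`` of healthy
    cells and lysogens move there.  Lytic-infected cells are moribund and
    do not move; substrates and phage are unaffected.
    """
    if not params.chemotaxis_enabled or params.chemo_fraction <= 0:
        return grid
    moves: list = []
    for idx, node in enumerate(grid.iter_nodes()):
        if not node.demes:
            continue
        rng = None
        if not deterministic:
            rng = substream(seed, grid.generation, PHASE_CHEMOTAXIS, idx)
        neigh = grid.neighbors(node.coords)
        for deme in node.demes.values():
            movable = deme.healthy + deme.lysogen_count
            if movable == 0:
                continue
            eff = deme.mean_alleles()
            here = node_attractiveness(node, deme, eff)
            best_coords, best_value = None, here
            for tgt in neigh:  # lexicographic order => ties go to smallest
                value = node_attractiveness(grid[tgt], deme, eff)
                if value > best_value:
                    best_coords, best_value = tgt, value
            if best_coords is None:
                continue
            fractions = [1.0 - params.chemo_fraction, params.chemo_fraction]
            for alleles, count in list(deme.classes.items()):
                stay, go = split_counts(count, fractions, rng, deterministic)
                if go:
                    deme.classes[alleles] = stay
                    moves.append((best_coords, deme, "class", alleles, go))
            if deme.lysogen_count:
                stay, go = split_counts(deme.lysogen_count, fractions, rng,
                                        deterministic)
                if go:
                    deme.lysogen_count = stay
                    moves.append((best_coords, deme, "lysogen", None, go))
    _apply_moves(grid, moves)
    for node in grid.iter_nodes():
        node.prune()
    return grid
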