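"""Scenario configuration, initial community, scheduler and run loop.

A scenario fully parameterizes one run: grid size, transport, growth,
evolutionary and phage parameters, an optional invasion event, the
chemotaxis switch, seed, duration and logging stride.

The initial community is the three-species cyclic cross-feeding web: P1
utilizes {N1, S1} and synthesizes S2, P2 utilizes {N1, S2} and synthesizes
S3, P3 utilizes {N1, S3} and synthesizes S1.  Every population consumes
the externally supplied non-specific substrate N1; the specific substrates
close a trophic cycle P1 -> P2 -> P3 -> P1.  The community uniformly
inhabits the grid.

Each generation runs a fixed phase order: in-flow, scheduled invasion,
growth (uptake/birth/death/secretion), evolutionary events (mutation, HGT,
gene loss), phage processes, flow, diffusion, chemotaxis, extinction
bookkeeping.  Randomness is drawn from counter-based substreams keyed by
(seed, generation, phase, node), so node iteration order cannot leak
randomness and paired scenarios diverge only where their configurations
differ.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .community import (
    N1,
    S1,
    S2,
    S3,
    SUBSTRATES,
    Genotype,
    HabitatGrid,
    species_key,
)
from .evolution import (
    EvoRates,
    SpeciesRegistry,
    attempt_gene_loss,
    attempt_hgt,
    mutate_alleles,
    update_extinctions,
)
from .growth import GrowthParams, grow_node
from .phage import InvasionEvent, PhageParams, invade, phage_step_node
from .randomness import (
    PHASE_GROWTH,
    PHASE_HGT,
    PHASE_INFECTION,
    substream,
)
from .transport import (
    TransportParams,
    apply_chemotaxis,
    apply_diffusion,
    apply_flow,
    apply_inflow,
)

#: Founding genotypes of the cyclic cross-feeding community.  Efficiency
#: values are arbitrary but symmetric starting alleles: every population
#: utilizes N1 at 0.5 and its specific substrate at 0.4, and synthesizes
#: its product at 0.6.
FOUNDER_GENOTYPES = {
    "P1": Genotype(utilization={N1: 0.5, S1: 0.4}, synthesis={S2: 0.6}),
    "P2": Genotype(utilization={N1: 0.5, S2: 0.4}, synthesis={S3: 0.6}),
    "P3": Genotype(utilization={N1: 0.5, S3: 0.4}, synthesis={S1: 0.6}),
}


class InvariantError(RuntimeError):
    """A state invariant (nonnegativity, registry consistency) failed."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of a single run."""

    height: int = 5
    width: int = 5
    duration_generations: int = 10000
    transport: TransportParams = field(default_factory=TransportParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    evo: EvoRates = field(default_factory=EvoRates)
    phage: Optional[PhageParams] = field(default_factory=PhageParams)
    invasion: Optional[InvasionEvent] = None
    chemotaxis_enabled: bool = False
    seed: int = 0
    deterministic: bool = False
    log_every: int = 10
    initial_cells_per_species: int = 100
    initial_n1: float = 1.0

    def __post_init__(self) -> None:
        if self.invasion is not None:
            if self.duration_generations < self.invasion.generation:
                raise ValueError("duration must cover the invasion")
            if not (1 <= self.invasion.node[0] <= self.height
                    and 1 <= self.invasion.node[1] <= self.width):
                raise ValueError("invasion node outside the grid")
        # chemotaxis switch is mirrored into the transport parameters
        if self.transport.chemotaxis_enabled != self.chemotaxis_enabled:
            object.__setattr__(
                self, "transport",
                dataclasses.replace(
                    self.transport,
                    chemotaxis_enabled=self.chemotaxis_enabled))

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class StepLedger:
    """Per-generation cell bookkeeping, closed by
    delta_cells = births - deaths - lysed - outflow."""

    generation: int
    births: int = 0
    deaths: int = 0
    lysed: int = 0
    outflow: int = 0
    infections: int = 0
    burst_released: float = 0.0
    cells_before: int = 0
    cells_after: int = 0
    node_phage: list = field(default_factory=list)


@dataclass
class RunOutput:
    """Logs, registry and configuration echo of one completed run."""

    config: ScenarioConfig
    registry: SpeciesRegistry
    grid: HabitatGrid
    deme_log: pd.DataFrame
    substrate_log: pd.DataFrame
    phage_log: pd.DataFrame
    ledger: pd.DataFrame

    @property
    def seed(self) -> int:
        return self.config.seed

    def write(self, out_dir) -> None:
        """Emit TSV logs, the species registry and a config echo."""
        import json
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.deme_log.to_csv(out / "deme_log.tsv", sep="\t", index=False)
        self.substrate_log.to_csv(out / "substrate_log.tsv", sep="\t",
                                  index=False)
        self.phage_log.to_csv(out / "phage_log.tsv", sep="\t", index=False)
        self.ledger.to_csv(out / "ledger.tsv", sep="\t", index=False)
        self.registry.to_frame().to_csv(out / "species_registry.tsv",
                                        sep="\t", index=False)
        with open(out / "config.json", "w") as fh:
            json.dump(config_to_dict(self.config), fh, indent=2, default=str)


def config_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def build_initial_community(config: ScenarioConfig
                            ) -> tuple[HabitatGrid, SpeciesRegistry]:
    """Uniformly seed the founder community over a fresh grid.

    Registers P1, P2, P3 at generation 0 (no origin node, no parent) and
    places ``initial_cells_per_species`` cells of each in every node, with
    initial pools of N1 and empty specific-substrate pools.
    """
    grid = HabitatGrid(height=config.height, width=config.width)
    registry = SpeciesRegistry()
    founders = []
    for name in ("P1", "P2", "P3"):
        genotype = FOUNDER_GENOTYPES[name]
        key = species_key(genotype)
        sid = registry.register_origination(key, 0, None, None)
        alleles = tuple(
            genotype.utilization[s] for s in key.util_set) + tuple(
            genotype.synthesis[s] for s in key.synth_set)
        founders.append((sid, key, alleles))
    for node in grid.iter_nodes():
        node.pools[N1] = config.initial_n1
        for s in (S1, S2, S3):
            node.pools[s] = 0.0
        for sid, key, alleles in founders:
            deme = node.get_or_create_deme(sid, key)
            deme.add_cells(alleles, config.initial_cells_per_species)
            deme.last_total = config.initial_cells_per_species
    return grid, registry


def _check_nonnegative(grid: HabitatGrid, phase: str) -> None:
    for node in grid.iter_nodes():
        if node.free_phage < 0:
            raise InvariantError(
                f"negative phage at {node.coords} after {phase}")
        for s, amount in node.pools.items():
            if amount < -1e-12:
                raise InvariantError(
                    f"negative pool {s} at {node.coords} after {phase}")


def step(grid: HabitatGrid, registry: SpeciesRegistry,
         config: ScenarioConfig) -> StepLedger:
    """Advance the state by one generation through the fixed phase order."""
    gen = grid.generation
    det = config.deterministic
    seed = config.seed
    ledger = StepLedger(generation=gen, cells_before=grid.total_cells())

    # (1) in-flow of non-specific substrate
    apply_inflow(grid, config.transport)

    # (2) scheduled phage invasion
    if (config.invasion is not None and config.phage is not None
            and gen == config.invasion.generation):
        invade(grid, config.invasion)

    # (3) growth: demand -> proportional allocation -> birth/death;
    # secretions buffered so every node sees pre-generation pools
    secretion_buffer = []
    for idx, node in enumerate(grid.iter_nodes()):
        if not node.demes:
            continue
        rng = None if det else substream(seed, gen, PHASE_GROWTH, idx)
        result = grow_node(node, config.growth, rng, det)
        ledger.births += result.births
        ledger.deaths += result.deaths
        if result.secreted:
            secretion_buffer.append((node, result.secreted))
    for node, secreted in secretion_buffer:
        for s, amount in secreted.items():
            node.pools[s] += amount

    # (4) evolutionary events: mutation, then HGT, then gene loss.  The
    # substream also serves deterministic mode, where event *counts* are
    # rounded expectations but gene/deme choices still need a seeded draw.
    evo = config.evo
    if evo.mu > 0 or evo.hgt_rate > 0 or evo.loss_rate > 0:
        for idx, node in enumerate(grid.iter_nodes()):
            if not node.demes:
                continue
            rng = substream(seed, gen, PHASE_HGT, idx)
            for deme in list(node.demes.values()):
                mutate_alleles(deme, evo, rng, det)
            attempt_hgt(node, evo, rng, registry, gen, det)
            attempt_gene_loss(node, evo, rng, registry, gen, det)
            node.prune()

    # (5) phage processes
    if config.phage is not None:
        for idx, node in enumerate(grid.iter_nodes()):
            if node.free_phage <= 0 and not any(
                    d.lysogen_count or d.lytic_infected
                    for d in node.demes.values()):
                continue
            rng = None if det else substream(seed, gen, PHASE_INFECTION, idx)
            result = phage_step_node(node, config.phage, rng, det)
            ledger.infections += result.infections
            ledger.lysed += result.lysed
            ledger.burst_released += result.burst_released
            ledger.node_phage.append(
                (node.coords, result.lysed, result.burst_released))
            node.prune()

    # (6)-(8) transport: directed flow, diffusion, chemotaxis
    ledger.outflow = apply_flow(grid, config.transport, seed, det)
    apply_diffusion(grid, config.transport, seed, det)
    apply_chemotaxis(grid, config.transport, seed, det)

    # (9) extinction bookkeeping, (10) clock
    update_extinctions(registry, grid)
    grid.generation += 1
    _check_nonnegative(grid, f"generation {gen}")
    ledger.cells_after = grid.total_cells()
    return ledger


def run_scenario(config: ScenarioConfig) -> RunOutput:
    """Execute a full scenario and collect analysis-ready logs."""
    grid, registry = build_initial_community(config)
    deme_rows: list = []
    substrate_rows: list = []
    phage_rows: list = []
    ledger_rows: list = []

    def log_state(node_phage=()) -> None:
        gen = grid.generation
        lysed_by_node = {coords: (lysed, burst)
                         for coords, lysed, burst in node_phage}
        for node in grid.iter_nodes():
            r, c = node.coords
            for sid, deme in sorted(node.demes.items()):
                deme_rows.append((gen, r, c, sid, deme.healthy,
                                  deme.lysogen_count, deme.infected))
            substrate_rows.append(
                (gen, r, c) + tuple(node.pools.get(s, 0.0)
                                    for s in SUBSTRATES))
            lysed, burst = lysed_by_node.get((r, c), (0, 0.0))
            if node.free_phage > 0 or lysed or any(
                    d.lysogen_count or d.infected
                    for d in node.demes.values()):
                phage_rows.append((
                    gen, r, c, node.free_phage,
                    sum(d.lysogen_count for d in node.demes.values()),
                    sum(d.infected for d in node.demes.values()),
                    lysed, burst))

    log_state()
    for _ in range(config.duration_generations):
        ledger = step(grid, registry, config)
        ledger_rows.append((
            ledger.generation, ledger.cells_before, ledger.cells_after,
            ledger.births, ledger.deaths, ledger.lysed, ledger.outflow,
            ledger.infections, ledger.burst_released))
        if (grid.generation % config.log_every == 0
                or grid.generation == config.duration_generations):
            log_state(ledger.node_phage)

    deme_log = pd.DataFrame(
        deme_rows, columns=["generation", "row", "col", "species_id",
                            "healthy", "lysogens", "lytic_infected"])
    substrate_log = pd.DataFrame(
        substrate_rows,
        columns=["generation", "row", "col"] + list(SUBSTRATES))
    phage_log = pd.DataFrame(
        phage_rows, columns=["generation", "row", "col", "free_phage",
                             "lysogens", "lytic_infected", "lysed",
                             "burst_released"])
    ledger_df = pd.DataFrame(
        ledger_rows,
        columns=["generation", "cells_before", "cells_after", "births",
                 "deaths", "lysed", "outflow", "infections",
                 "burst_released"])
    return RunOutput(config=config, registry=registry, grid=grid,
                     deme_log=deme_log, substrate_log=substrate_log,
                     phage_log=phage_log, ledger=ledger_df)


# -- configuration files -----------------------------------------------------

_SECTION_TYPES = {
    "transport": TransportParams,
    "growth": GrowthParams,
    "evo": EvoRates,
    "phage": PhageParams,
    "invasion": InvasionEvent,
}


def config_from_dict(data: dict) -> ScenarioConfig:
    """Build a ScenarioConfig from a flat/nested mapping; unknown keys are
    rejected."""
    data = dict(data)
    kwargs: dict = {}
    top_fields = {f.name for f in dataclasses.fields(ScenarioConfig)}
    for key, value in data.items():
        if key not in top_fields:
            raise ValueError(f"unknown configuration key: {key!r}")
        if key in _SECTION_TYPES and value is not None:
            cls = _SECTION_TYPES[key]
            allowed = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - allowed
            if unknown:
                raise ValueError(
                    f"unknown keys in section {key!r}: {sorted(unknown)}")
            if key == "invasion" and "node" in value:
                value = dict(value, node=tuple(value["node"]))
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return ScenarioConfig(**kwargs)


def load_config(path) -> ScenarioConfig:
    """Load a scenario from a YAML document mirroring ScenarioConfig."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
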