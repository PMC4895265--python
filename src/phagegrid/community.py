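"""Core state of the habitat: genotypes, species keys, demes, nodes, grid.

The community is hierarchical: a habitat grid of well-mixed point
environments (nodes), each holding substrate pools, free phage particles,
and demes.  A deme is the super-individual record of one species' cells in
one node: identical cells are aggregated into allele classes rather than
tracked individually.

Species identity is the gene-presence set (which substrates a cell can
utilize and which it synthesizes); allele values are intra-species
polymorphism.  Horizontal gene transfer and gene loss change the presence
set and therefore found new species; point mutation only perturbs allele
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

# Canonical substrate universe of the default scenario.  N1 is the
# non-specific substrate supplied by in-flow and consumable by every
# population; S1..S3 are specific substrates synthesized and secreted by
# cells carrying the corresponding synthesis gene.
N1 = "N1"
S1 = "S1"
S2 = "S2"
S3 = "S3"
SUBSTRATES: tuple[str, ...] = (N1, S1, S2, S3)
SPECIFIC_SUBSTRATES: tuple[str, ...] = (S1, S2, S3)

_SUBSTRATE_ORDER = {s: i for i, s in enumerate(SUBSTRATES)}

#: Allele efficiencies are quantized to this many decimals when forming
#: class identity, so mutation creates finitely many classes.
ALLELE_DECIMALS = 6
#: Efficiencies are clamped to (EFF_MIN, 1.0] after mutation.
EFF_MIN = 0.001
EFF_MAX = 1.0


class InvalidGenotypeError(ValueError):
    """Raised for genotypes that violate viability invariants."""


def sorted_substrates(names) -> tuple[str, ...]:
    """Canonical ordering (N1, S1, S2, S3) for gene-presence sets."""
    return tuple(sorted(names, key=_SUBSTRATE_ORDER.__getitem__))


_sorted_substrates = sorted_substrates


@dataclass(frozen=True)
class Genotype:
    """A gene-network genome reduced to numeric parameters.

    ``utilization`` maps substrate -> uptake efficiency in (0, 1]; presence
    of the key means the gene is present.  ``synthesis`` maps a specific
    substrate -> synthesis efficiency.  ``prophage`` marks an integrated
    phage genome (lysogen).
    """

    utilization: dict
    synthesis: dict
    prophage: bool = False

    def __post_init__(self) -> None:
        if not self.utilization:
            raise InvalidGenotypeError(
                "genotype with no utilization gene is nonviable")
        if N1 in self.synthesis:
            raise InvalidGenotypeError(
                "the non-specific substrate N1 cannot be synthesized")
        for table in (self.utilization, self.synthesis):
            for s, eff in table.items():
                if s not in SUBSTRATES:
                    raise InvalidGenotypeError(f"unknown substrate {s!r}")
                if not (0.0 < eff <= EFF_MAX):
                    raise InvalidGenotypeError(
                        f"efficiency for {s} out of (0, 1]: {eff}")


@dataclass(frozen=True, order=True)
class SpeciesKey:
    """Species identity: the ordered gene-presence sets of a genotype.

    Allele values are deliberately dropped; two genotypes that differ only
    in efficiencies map to the same key.
    """

    util_set: tuple[str, ...]
    synth_set: tuple[str, ...]

    @property
    def genes(self) -> tuple[tuple[str, str], ...]:
        """Gene order used to align allele vectors: utilization genes first,
        then synthesis genes, each in canonical substrate order."""
        return key_indices(self)[0]

    def label(self) -> str:
        u = ",".join(self.util_set)
        s = ",".join(self.synth_set)
        return f"util{{{u}}}|synth{{{s}}}"


# The gene universe is tiny (<= 7 genes over 4 substrates), so gene-order
# and index lookups per key are memoized once instead of rebuilt in the
# per-generation hot loops.
_KEY_CACHE: dict = {}


def key_indices(key: SpeciesKey) -> tuple:
    """(genes, util_indices, synth_indices) for a species key, memoized.

    ``util_indices``/``synth_indices`` list (vector_position, substrate)
    pairs into allele vectors aligned to ``genes``.
    """
    cached = _KEY_CACHE.get(key)
    if cached is None:
        genes = tuple(("util", s) for s in key.util_set) + tuple(
            ("synth", s) for s in key.synth_set)
        util_idx = tuple((i, s) for i, (kind, s) in enumerate(genes)
                         if kind == "util")
        synth_idx = tuple((i, s) for i, (kind, s) in enumerate(genes)
                          if kind == "synth")
        cached = (genes, util_idx, synth_idx)
        _KEY_CACHE[key] = cached
    return cached


def species_key(genotype: Genotype) -> SpeciesKey:
    """Canonical, allele-blind species key of a genotype.

    Deterministic and order-independent: the key depends only on which
    genes are present, never on efficiency values or insertion order.
    """
    if not genotype.utilization:
        raise InvalidGenotypeError("empty utilization set")
    return SpeciesKey(
        util_set=_sorted_substrates(genotype.utilization),
        synth_set=_sorted_substrates(genotype.synthesis),
    )


def is_susceptible(genotype: Genotype) -> bool:
    """Whether the phage can adsorb to cells of this genotype.

    The phage host range is S1-utilizers; lysogens (prophage carriers)
    are immune to superinfection.
    """
    return S1 in genotype.utilization and not genotype.prophage


def quantize_allele(value: float) -> float:
    """Clamp an efficiency into (EFF_MIN, 1] and round to class precision."""
    return round(min(EFF_MAX, max(EFF_MIN, value)), ALLELE_DECIMALS)


@dataclass
class PopulationDeme:
    """All cells of one species in one node, as super-individual classes.

    ``classes`` maps an allele vector (efficiencies aligned to
    ``SpeciesKey.genes``) to a healthy-cell count.  Lysogens and
    lytic-infected cells are tracked separately from healthy counts;
    ``lytic_infected`` maps remaining latency in generations to a count.
    ``lysogen_eff`` is the representative allele vector used for lysogen
    metabolism (count-weighted mean at infection time).
    """

    species_id: int
    key: SpeciesKey
    node: tuple[int, int]
    classes: dict = field(default_factory=dict)
    lysogen_count: int = 0
    lysogen_eff: Optional[tuple] = None
    lytic_infected: dict = field(default_factory=dict)
    last_total: int = 0
    last_gain: float = 0.0

    @property
    def healthy(self) -> int:
        return sum(self.classes.values())

    @property
    def infected(self) -> int:
        return sum(self.lytic_infected.values())

    @property
    def total_cells(self) -> int:
        return self.healthy + self.lysogen_count + self.infected

    def add_cells(self, alleles: tuple, count: int) -> None:
        if count:
            self.classes[alleles] = self.classes.get(alleles, 0) + count

    def mean_alleles(self) -> Optional[tuple]:
        """Count-weighted mean allele vector over healthy classes."""
        n = self.healthy
        if n == 0:
            return self.lysogen_eff
        k = len(self.key.genes)
        acc = [0.0] * k
        for alleles, count in self.classes.items():
            for i in range(k):
                acc[i] += alleles[i] * count
        return tuple(quantize_allele(a / n) for a in acc)

    def prune(self) -> None:
        """Drop empty classes and latency slots (end-of-generation tidy)."""
        self.classes = {a: c for a, c in self.classes.items() if c > 0}
        self.lytic_infected = {
            l: c for l, c in self.lytic_infected.items() if c > 0}

    def merge_from(self, other: "PopulationDeme") -> None:
        """Fold another deme of the same species into this one (immigration)."""
        for alleles, count in other.classes.items():
            self.add_cells(alleles, count)
        if other.lysogen_count:
            self._blend_lysogen_eff(other.lysogen_eff, other.lysogen_count)
            self.lysogen_count += other.lysogen_count
        for lat, count in other.lytic_infected.items():
            self.lytic_infected[lat] = self.lytic_infected.get(lat, 0) + count

    def _blend_lysogen_eff(self, eff: Optional[tuple], count: int) -> None:
        if eff is None:
            eff = self.mean_alleles()
        if self.lysogen_count == 0 or self.lysogen_eff is None:
            self.lysogen_eff = eff
        elif eff is not None:
            w0, w1 = self.lysogen_count, count
            self.lysogen_eff = tuple(
                quantize_allele((a * w0 + b * w1) / (w0 + w1))
                for a, b in zip(self.lysogen_eff, eff))

    def add_lysogens(self, count: int, eff: Optional[tuple] = None) -> None:
        if count:
            self._blend_lysogen_eff(eff, count)
            self.lysogen_count += count

    def efficiency_of(self, alleles: tuple, kind: str, substrate: str) -> float:
        for (g_kind, g_sub), value in zip(self.key.genes, alleles):
            if g_kind == kind and g_sub == substrate:
                return value
        return 0.0


@dataclass
class NodeState:
    """One point environment: a small well-mixed volume of the habitat."""

    coords: tuple[int, int]
    pools: dict = field(default_factory=lambda: {s: 0.0 for s in SUBSTRATES})
    free_phage: float = 0.0
    demes: dict = field(default_factory=dict)

    def total_cells(self) -> int:
        return sum(d.total_cells for d in self.demes.values())

    def get_or_create_deme(self, species_id: int, key: SpeciesKey
                           ) -> PopulationDeme:
        deme = self.demes.get(species_id)
        if deme is None:
            deme = PopulationDeme(species_id=species_id, key=key,
                                  node=self.coords)
            self.demes[species_id] = deme
        return deme

    def prune(self) -> None:
        for deme in self.demes.values():
            deme.prune()
        self.demes = {
            sid: d for sid, d in self.demes.items() if d.total_cells > 0}


@dataclass
class HabitatGrid:
    """Dense height x width lattice of nodes, 1-based (row, col) coordinates.

    Row 1 is the top of the habitat, column 1 the left; the flow runs from
    (1,1) toward (height, width).
    """

    height: int = 5
    width: int = 5
    nodes: dict = field(default_factory=dict)
    generation: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("grid dimensions must be positive")
        if not self.nodes:
            self.nodes = {
                (r, c): NodeState(coords=(r, c))
                for r in range(1, self.height + 1)
                for c in range(1, self.width + 1)}

    def __getitem__(self, coords: tuple[int, int]) -> NodeState:
        return self.nodes[coords]

    def __contains__(self, coords: tuple[int, int]) -> bool:
        return coords in self.nodes

    def iter_nodes(self) -> Iterator[NodeState]:
        """Row-major iteration, the canonical node order everywhere."""
        for r in range(1, self.height + 1):
            for c in range(1, self.width + 1):
                yield self.nodes[(r, c)]

    def neighbors(self, coords: tuple[int, int]) -> list[tuple[int, int]]:
        """Orthogonal neighbors, in lexicographic (row, col) order."""
        r, c = coords
        out = []
        for rr, cc in ((r - 1, c), (r, c - 1), (r, c + 1), (r + 1, c)):
            if 1 <= rr <= self.height and 1 <= cc <= self.width:
                out.append((rr, cc))
        return out

    def total_cells(self) -> int:
        return sum(n.total_cells() for n in self.nodes.values())

    def total_substrate(self, substrate: str) -> float:
        return sum(n.pools[substrate] for n in self.nodes.values())

    def total_phage(self) -> float:
        return sum(n.free_phage for n in self.nodes.values())

    def species_cell_counts(self) -> dict:
        """Grid-wide cell count per species (healthy + lysogen + infected)."""
        counts: dict[int, int] = {}
        for node in self.nodes.values():
            for sid, deme in node.demes.items():
                counts[sid] = counts.get(sid, 0) + deme.total_cells
        return counts
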