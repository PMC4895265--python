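"""Evolutionary events and the species registry.

Three event types operate on demes each generation:

* point mutation — perturbs one gene's efficiency in a few cells,
  creating a new allele class (intra-species polymorphism);
* horizontal gene transfer — a recipient cell embeds a gene it lacks,
  copied with the donor's efficiency, from a co-located donor of a
  different species;
* gene loss — a cell deletes one of its genes (never its last
  utilization gene, which would leave a nonviable genome).

HGT and gene loss change the gene-presence set and therefore the species:
the affected cells either join an extant species with the resulting key or
found a new one.  Every origination and extinction is appended to the
registry with node provenance — the substrate for the speciation-rate
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .community import (
    NodeState,
    PopulationDeme,
    SpeciesKey,
    quantize_allele,
    sorted_substrates,
)
from .randomness import draw_binomial, draw_count


@dataclass(frozen=True)
class EvoRates:
    """Event intensities.

    mu           per-cell per-generation allele-mutation probability
    hgt_rate     per-node per-generation expected gene-transfer events
    loss_rate    per-node per-generation expected gene-loss events
    mutation_sd  sigma of the lognormal allele perturbation factor
    n_transfer   founding cells per HGT/loss event
    """

    mu: float = 1e-3
    hgt_rate: float = 0.05
    loss_rate: float = 0.05
    mutation_sd: float = 0.1
    n_transfer: int = 1
    #: lysogens stay part of the horizontal gene pool as donors (their
    #: genomes are intact; only recipients must be healthy)
    lysogen_donors: bool = True

    def __post_init__(self) -> None:
        if min(self.mu, self.hgt_rate, self.loss_rate, self.mutation_sd) < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class SpeciesRecord:
    species_id: int
    key: SpeciesKey
    origin_generation: int
    origin_node: Optional[tuple[int, int]]
    parent_species: Optional[int]
    extinction_generation: Optional[int] = None

    @property
    def extant(self) -> bool:
        return self.extinction_generation is None


class ExtantKeyError(ValueError):
    """Attempt to register a key that already has an extant record."""


@dataclass
class SpeciesRegistry:
    """Append-only log of species origination and extinction events.

    At most one extant record exists per species key; a key re-emerging
    after extinction opens a fresh record (and so counts as a new
    origination event in rate analyses).
    """

    records: list = field(default_factory=list)
    _extant_by_key: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, species_id: int) -> SpeciesRecord:
        return self.records[species_id]

    def extant_id(self, key: SpeciesKey) -> Optional[int]:
        return self._extant_by_key.get(key)

    def extant_keys(self) -> set:
        return set(self._extant_by_key)

    def register_origination(self, key: SpeciesKey, generation: int,
                             node: Optional[tuple[int, int]],
                             parent_species: Optional[int]) -> int:
        if key in self._extant_by_key:
            raise ExtantKeyError(f"extant record exists for {key.label()}")
        sid = len(self.records)
        self.records.append(SpeciesRecord(
            species_id=sid, key=key, origin_generation=generation,
            origin_node=node, parent_species=parent_species))
        self._extant_by_key[key] = sid
        return sid

    def mark_extinct(self, species_id: int, generation: int) -> None:
        rec = self.records[species_id]
        if rec.extinction_generation is not None:
            return
        rec.extinction_generation = generation
        if self._extant_by_key.get(rec.key) == species_id:
            del self._extant_by_key[rec.key]

    def to_frame(self):
        """Registry as a DataFrame (TSV-ready; empty extinction = extant)."""
        import pandas as pd

        rows = []
        for r in self.records:
            rows.append({
                "species_id": r.species_id,
                "util_set": ";".join(r.key.util_set),
                "synth_set": ";".join(r.key.synth_set),
                "origin_generation": r.origin_generation,
                "origin_row": r.origin_node[0] if r.origin_node else "",
                "origin_col": r.origin_node[1] if r.origin_node else "",
                "parent_species": ("" if r.parent_species is None
                                   else r.parent_species),
                "extinction_generation": (
                    "" if r.extinction_generation is None
                    else r.extinction_generation),
            })
        return pd.DataFrame(rows)


def register_origination(registry: SpeciesRegistry, key: SpeciesKey,
                         generation: int, node: Optional[tuple[int, int]],
                         parent_species: Optional[int]) -> int:
    """Open a new species record; raises if the key is already extant."""
    return registry.register_origination(key, generation, node,
                                         parent_species)


def mutate_alleles(deme: PopulationDeme, rates: EvoRates,
                   rng: np.random.Generator,
                   deterministic: bool = False) -> PopulationDeme:
    """Perturb allele values in a binomial number of healthy cells.

    Each mutant moves from its class to a class with one uniformly chosen
    gene's efficiency multiplied by a lognormal(0, mutation_sd) factor,
    clamped and quantized.  Total cell count is conserved; a mutant whose
    quantized vector equals its parent's simply merges back.
    """
    n_genes = len(deme.key.genes)
    healthy = deme.healthy
    if healthy == 0 or rates.mu == 0 or n_genes == 0:
        return deme
    n_mut = draw_binomial(healthy, rates.mu, rng, deterministic)
    if n_mut == 0:
        return deme
    class_list = list(deme.classes.items())
    weights = np.array([c for _, c in class_list], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(class_list), size=n_mut, p=weights)
    for idx in picks:
        alleles, count = class_list[idx]
        if deme.classes.get(alleles, 0) <= 0:
            continue  # class emptied by an earlier mutant this generation
        gene = int(rng.integers(n_genes))
        factor = float(rng.lognormal(0.0, rates.mutation_sd))
        new = list(alleles)
        new[gene] = quantize_allele(alleles[gene] * factor)
        new_alleles = tuple(new)
        deme.classes[alleles] -= 1
        if deme.classes[alleles] == 0:
            del deme.classes[alleles]
        deme.classes[new_alleles] = deme.classes.get(new_alleles, 0) + 1
    return deme


def _weighted_deme_pick(demes: list, rng: np.random.Generator
                        ) -> PopulationDeme:
    weights = np.array([d.healthy for d in demes], dtype=float)
    weights /= weights.sum()
    return demes[int(rng.choice(len(demes), p=weights))]


def _move_cells_to_key(node: NodeState, source: PopulationDeme,
                       src_alleles: tuple, n: int, new_key: SpeciesKey,
                       new_alleles: tuple, registry: SpeciesRegistry,
                       generation: int) -> Optional[int]:
    """Move n cells from a source class into the deme of ``new_key``.

    Joins the extant species of that key, or registers a new origination.
    Returns the new species_id when an origination occurred, else None.
    """
    source.classes[src_alleles] -= n
    if source.classes[src_alleles] <= 0:
        del source.classes[src_alleles]
    sid = registry.extant_id(new_key)
    originated = None
    if sid is None:
        sid = registry.register_origination(
            new_key, generation, node.coords, source.species_id)
        originated = sid
    target = node.get_or_create_deme(sid, new_key)
    target.add_cells(new_alleles, n)
    return originated


def attempt_hgt(node: NodeState, rates: EvoRates, rng: np.random.Generator,
                registry: SpeciesRegistry, generation: int,
                deterministic: bool = False) -> list:
    """Horizontal gene transfer within one well-mixed node.

    Draws a Poisson number of events.  Per event, donor and recipient demes
    are chosen with probability proportional to healthy cells (distinct
    keys required); one gene present in the donor and absent in the
    recipient is embedded into ``n_transfer`` recipient cells with the
    donor's current efficiency.  Returns the species_ids of any new
    originations.
    """
    def donor_weight(d: PopulationDeme) -> int:
        return d.healthy + (d.lysogen_count if rates.lysogen_donors else 0)

    n_events = draw_count(rates.hgt_rate, rng, deterministic)
    events = []
    for _ in range(n_events):
        donors = [d for d in node.demes.values() if donor_weight(d) > 0]
        recipients = [d for d in node.demes.values() if d.healthy > 0]
        if not any(d.key != r.key for d in donors for r in recipients):
            break
        weights = np.array([donor_weight(d) for d in donors], dtype=float)
        weights /= weights.sum()
        donor = donors[int(rng.choice(len(donors), p=weights))]
        others = [d for d in recipients if d.key != donor.key]
        if not others:
            continue
        recipient = _weighted_deme_pick(others, rng)
        donor_genes = set(donor.key.genes)
        recipient_genes = set(recipient.key.genes)
        transferable = sorted(donor_genes - recipient_genes)
        if not transferable:
            continue
        kind, sub = transferable[int(rng.integers(len(transferable)))]
        # donor efficiency: from a donor class chosen by cell count, or
        # the lysogen pool's representative alleles
        d_classes = list(donor.classes.items())
        if rates.lysogen_donors and donor.lysogen_count:
            lys_eff = donor.lysogen_eff or donor.mean_alleles()
            if lys_eff is not None:
                d_classes.append((lys_eff, donor.lysogen_count))
        d_weights = np.array([c for _, c in d_classes], dtype=float)
        d_weights /= d_weights.sum()
        d_alleles = d_classes[int(rng.choice(len(d_classes), p=d_weights))][0]
        donor_eff = donor.efficiency_of(d_alleles, kind, sub)
        # recipient class chosen by cell count
        r_classes = list(recipient.classes.items())
        r_weights = np.array([c for _, c in r_classes], dtype=float)
        r_weights /= r_weights.sum()
        r_alleles, r_count = r_classes[
            int(rng.choice(len(r_classes), p=r_weights))]
        n = min(rates.n_transfer, r_count)
        if kind == "util":
            new_key = SpeciesKey(
                util_set=sorted_substrates(
                    set(recipient.key.util_set) | {sub}),
                synth_set=recipient.key.synth_set)
        else:
            new_key = SpeciesKey(
                util_set=recipient.key.util_set,
                synth_set=sorted_substrates(
                    set(recipient.key.synth_set) | {sub}))
        # align recipient alleles to the new gene order, inserting donor_eff
        mapping = dict(zip(recipient.key.genes, r_alleles))
        mapping[(kind, sub)] = quantize_allele(donor_eff)
        new_alleles = tuple(mapping[g] for g in new_key.genes)
        originated = _move_cells_to_key(
            node, recipient, r_alleles, n, new_key, new_alleles,
            registry, generation)
        if originated is not None:
            events.append(originated)
    return events


def attempt_gene_loss(node: NodeState, rates: EvoRates,
                      rng: np.random.Generator, registry: SpeciesRegistry,
                      generation: int, deterministic: bool = False) -> list:
    """Gene deletion events within one node.

    Per Poisson event a deme is drawn proportionally to healthy cells and
    one gene — never the last remaining utilization gene — is deleted from
    ``n_transfer`` cells.  Resulting cells join the extant species of the
    reduced key or found a new one.
    """
    n_events = draw_count(rates.loss_rate, rng, deterministic)
    events = []
    for _ in range(n_events):
        candidates = [d for d in node.demes.values() if d.healthy > 0]
        losable = []
        for d in candidates:
            genes = list(d.key.genes)
            if len(d.key.util_set) <= 1:
                genes = [g for g in genes if g[0] != "util"]
            if genes:
                losable.append((d, genes))
        if not losable:
            break
        weights = np.array([d.healthy for d, _ in losable], dtype=float)
        weights /= weights.sum()
        deme, genes = losable[int(rng.choice(len(losable), p=weights))]
        kind, sub = genes[int(rng.integers(len(genes)))]
        r_classes = list(deme.classes.items())
        r_weights = np.array([c for _, c in r_classes], dtype=float)
        r_weights /= r_weights.sum()
        r_alleles, r_count = r_classes[
            int(rng.choice(len(r_classes), p=r_weights))]
        n = min(rates.n_transfer, r_count)
        if kind == "util":
            new_key = SpeciesKey(
                util_set=tuple(s for s in deme.key.util_set if s != sub),
                synth_set=deme.key.synth_set)
        else:
            new_key = SpeciesKey(
                util_set=deme.key.util_set,
                synth_set=tuple(s for s in deme.key.synth_set if s != sub))
        mapping = dict(zip(deme.key.genes, r_alleles))
        del mapping[(kind, sub)]
        new_alleles = tuple(mapping[g] for g in new_key.genes)
        originated = _move_cells_to_key(
            node, deme, r_alleles, n, new_key, new_alleles,
            registry, generation)
        if originated is not None:
            events.append(originated)
    return events


def update_extinctions(registry: SpeciesRegistry, grid) -> SpeciesRegistry:
    """Close the record of every extant species with zero cells grid-wide."""
    counts = grid.species_cell_counts()
    for key, sid in list(registry._extant_by_key.items()):
        if counts.get(sid, 0) <= 0:
            registry.mark_extinct(sid, grid.generation)
    return registry
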