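import numpy as np
import pytest

from phagegrid import (
    Genotype,
    HabitatGrid,
    NodeState,
    PopulationDeme,
    species_key,
)


def make_deme(genotype: Genotype, count: int, species_id: int = 0,
              node=(1, 1)) -> PopulationDeme:
    """Deme with one allele class taken from the genotype's efficiencies."""
    key = species_key(genotype)
    alleles = tuple(genotype.utilization[s] for s in key.util_set) + tuple(
        genotype.synthesis[s] for s in key.synth_set)
    deme = PopulationDeme(species_id=species_id, key=key, node=node)
    deme.add_cells(alleles, count)
    deme.last_total = count
    return deme


@pytest.fixture
def p1_genotype() -> Genotype:
    return Genotype(utilization={"N1": 0.5, "S1": 0.4}, synthesis={"S2": 0.6})


@pytest.fixture
def p2_genotype() -> Genotype:
    return Genotype(utilization={"N1": 0.5, "S2": 0.4}, synthesis={"S3": 0.6})


@pytest.fixture
def p3_genotype() -> Genotype:
    return Genotype(utilization={"N1": 0.5, "S3": 0.4}, synthesis={"S1": 0.6})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def empty_grid() -> HabitatGrid:
    return HabitatGrid(height=5, width=5)


@pytest.fixture
def single_node() -> NodeState:
    return NodeState(coords=(1, 1))
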