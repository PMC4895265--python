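"""Uptake allocation, the growth law, and secretion."""

import numpy as np
import pytest

from conftest import make_deme
from phagegrid import Genotype, GrowthParams, allocate_uptake, grow_deme


class TestAllocateUptake:
    def test_undersubscribed_grants_in_full(self):
        pools = {"N1": 10.0}
        grants = allocate_uptake({("a", "N1"): 2.0, ("b", "N1"): 2.0}, pools)
        assert grants == {("a", "N1"): 2.0, ("b", "N1"): 2.0}
        assert pools["N1"] == pytest.approx(6.0)

    def test_oversubscribed_scales_proportionally(self):
        pools = {"N1": 6.0}
        grants = allocate_uptake({("a", "N1"): 6.0, ("b", "N1"): 6.0}, pools)
        assert grants[("a", "N1")] == pytest.approx(3.0)
        assert grants[("b", "N1")] == pytest.approx(3.0)
        assert pools["N1"] == pytest.approx(0.0)

    def test_proportional_shares_match_micro_allocation(self):
        """Sequential micro-allocation in random order converges to the
        proportional-shares rule as the micro-step goes to zero."""
        demands = {("a", "N1"): 4.0, ("b", "N1"): 2.0}
        pools = {"N1": 3.0}
        grants = allocate_uptake(demands, dict(pools))
        # oracle: hand out the pool in tiny quanta to requesters chosen
        # proportionally to remaining demand
        rng = np.random.default_rng(7)
        remaining = dict(demands)
        taken = {k: 0.0 for k in demands}
        quantum = 3.0 / 30000
        for _ in range(30000):
            keys = list(remaining)
            weights = np.array([remaining[k] for k in keys])
            k = keys[rng.choice(len(keys), p=weights / weights.sum())]
            taken[k] += quantum
            remaining[k] = max(0.0, remaining[k] - quantum)
        assert grants[("a", "N1")] == pytest.approx(2.0)
        assert grants[("b", "N1")] == pytest.approx(1.0)
        assert taken[("a", "N1")] == pytest.approx(2.0, rel=0.05)
        assert taken[("b", "N1")] == pytest.approx(1.0, rel=0.05)

    def test_zero_pool_grants_nothing(self):
        grants = allocate_uptake({("a", "N1"): 5.0}, {"N1": 0.0})
        assert grants[("a", "N1")] == 0.0

    def test_negative_demand_rejected(self):
        with pytest.raises(ValueError):
            allocate_uptake({("a", "N1"): -1.0}, {"N1": 1.0})


class TestGrowDeme:
    def test_deterministic_arithmetic(self):
        """100 cells at gain 0.12: births 100*1*(0.12-0.02)=10, deaths 5."""
        genotype = Genotype(utilization={"N1": 1.0}, synthesis={})
        deme = make_deme(genotype, 100)
        params = GrowthParams(yield_Y=1.0, death_rate_delta=0.05,
                              maintenance_m=0.02)
        result = grow_deme(deme, {"N1": 12.0}, params, None,
                           deterministic=True)
        assert result.births == 10
        assert result.deaths == 5
        assert deme.healthy == 105

    def test_starvation_yields_no_births_or_secretion(self, p1_genotype,
                                                      rng):
        deme = make_deme(p1_genotype, 200)
        params = GrowthParams()
        result = grow_deme(deme, {"N1": 0.0, "S1": 0.0}, params, rng)
        assert result.births == 0
        assert result.secreted == {}
        # deaths binomial around 200 * 0.05 = 10
        assert 0 < result.deaths < 40

    def test_secretion_proportional_to_uptake(self, p1_genotype):
        deme = make_deme(p1_genotype, 100)
        params = GrowthParams(synth_yield=0.5)
        result = grow_deme(deme, {"N1": 10.0, "S1": 0.0}, params, None,
                           deterministic=True)
        # per-cell uptake 0.1; S2 secretion = 0.5 * 0.6 * 0.1 * 100 = 3.0
        assert result.secreted == {"S2": pytest.approx(3.0)}

    def test_births_monotone_in_uptake(self, p1_genotype):
        """More granted resource never means fewer expected births."""
        params = GrowthParams(yield_Y=2.0)
        births = []
        for n1 in (0.0, 2.0, 5.0, 10.0, 20.0):
            deme = make_deme(p1_genotype, 100)
            result = grow_deme(deme, {"N1": n1}, params, None,
                               deterministic=True)
            births.append(result.births)
        assert births == sorted(births)

    def test_lytic_infected_consume_but_do_not_reproduce(self, p1_genotype):
        deme = make_deme(p1_genotype, 50)
        deme.lytic_infected[2] = 50
        params = GrowthParams(yield_Y=1.0, death_rate_delta=0.0)
        result = grow_deme(deme, {"N1": 10.0}, params, None,
                           deterministic=True)
        # healthy cells see per-cell uptake 10/100 = 0.1 (infected share
        # the grant), gain 0.05: births = 50 * 1.0 * (0.05 - 0.02) = 1.5 -> 2
        assert deme.lytic_infected == {2: 50}  # untouched by growth
        assert result.births == 2
        assert deme.healthy == 52

    def test_negative_grant_rejected(self, p1_genotype):
        deme = make_deme(p1_genotype, 10)
        with pytest.raises(ValueError):
            grow_deme(deme, {"N1": -0.1}, GrowthParams(), None, True)


def test_deterministic_run_matches_per_cell_brute_force(p1_genotype,
                                                        p2_genotype):
    """Super-individual equivalence on a 1-node, 2-species, 10-cell,
    10-generation deterministic run.

    The oracle tracks every cell individually: same proportional uptake,
    same rounded expectations applied per species (rounding at the
    aggregate level, as the super-individual does).
    """
    params = GrowthParams(yield_Y=5.0)
    demes = [make_deme(p1_genotype, 5, species_id=0),
             make_deme(p2_genotype, 5, species_id=1)]
    # independent per-cell implementation: a list of (species, eff) cells
    cells = [("P1", 0.5, 0.4)] * 5 + [("P2", 0.5, 0.4)] * 5
    pools = {"N1": 2.0, "S1": 0.5, "S2": 0.25, "S3": 0.0}
    oracle_pools = dict(pools)
    for gen in range(10):
        # package path
        demands = {}
        for deme in demes:
            for s in deme.key.util_set:
                demands[(deme.species_id, s)] = (
                    deme.total_cells * params.demand_per_cell_q)
        from phagegrid import allocate_uptake as alloc
        grants = alloc(demands, pools)
        secreted_total = {}
        for deme in demes:
            granted = {s: grants.get((deme.species_id, s), 0.0)
                       for s in deme.key.util_set}
            r = grow_deme(deme, granted, params, None, deterministic=True)
            for s, a in r.secreted.items():
                secreted_total[s] = secreted_total.get(s, 0.0) + a
        for s, a in secreted_total.items():
            pools[s] = pools.get(s, 0.0) + a

        # oracle path: per-cell demand, proportional grant, per-species
        # aggregation with identical rounding
        by_species = {}
        for name, effn, effs in cells:
            by_species.setdefault(name, []).append((effn, effs))
        sub_of = {"P1": "S1", "P2": "S2"}
        synth_of = {"P1": "S2", "P2": "S3"}
        demand = {}
        for name, members in by_species.items():
            demand[(name, "N1")] = len(members) * params.demand_per_cell_q
            demand[(name, sub_of[name])] = (
                len(members) * params.demand_per_cell_q)
        granted = {}
        for s in ("N1", "S1", "S2", "S3"):
            total = sum(v for (n, ss), v in demand.items() if ss == s)
            avail = oracle_pools.get(s, 0.0)
            scale = 1.0 if total <= avail or total == 0 else avail / total
            for (n, ss), v in demand.items():
                if ss == s:
                    granted[(n, ss)] = v * scale
            oracle_pools[s] = avail - min(avail, total * scale)
        new_cells = []
        secret = {}
        for name, members in by_species.items():
            ncell = len(members)
            u_n1 = granted[(name, "N1")] / ncell
            u_s = granted[(name, sub_of[name])] / ncell
            g = members[0][0] * u_n1 + members[0][1] * u_s
            births = int(round(ncell * params.yield_Y
                               * max(0.0, g - params.maintenance_m)))
            deaths = min(ncell, int(round(ncell * params.death_rate_delta)))
            survivors = ncell + births - deaths
            new_cells += [(name, members[0][0], members[0][1])] * survivors
            secret[synth_of[name]] = (
                secret.get(synth_of[name], 0.0)
                + 0.5 * 0.6 * (u_n1 + u_s) * ncell)
        cells = new_cells
        for s, a in secret.items():
            oracle_pools[s] = oracle_pools.get(s, 0.0) + a

        # state-for-state comparison
        counts = {"P1": 0, "P2": 0}
        for name, *_ in cells:
            counts[name] += 1
        assert demes[0].healthy == counts["P1"], f"generation {gen}"
        assert demes[1].healthy == counts["P2"], f"generation {gen}"
        for s in ("N1", "S1", "S2", "S3"):
            assert pools[s] == pytest.approx(oracle_pools.get(s, 0.0),
                                             abs=1e-12)
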