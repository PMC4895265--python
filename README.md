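# phagegrid

Agent-based simulation of a microbial community evolving in a spatially
distributed, flowing habitat under temperate-bacteriophage infection, with
a Speciation Rate Index (SRI) analysis of how the phage reshapes the
community's evolution.

## The problem

Temperate phages are a major force in bacterial evolution: they kill hosts
(lytic pathway), hide in their genomes (lysogeny), and bias which lineages
persist.  Spatial structure — nutrient gradients, flow, diffusion,
chemotaxis — is a second major force.  `phagegrid` models both together:

* a 5×5 (configurable) grid of well-mixed *point environments* fed a
  non-specific substrate N1 through the top row and left column, with
  directed flow toward the opposite corner, diffusion, and optional
  chemotaxis;
* a three-species cyclic cross-feeding community — P1 utilizes {N1, S1}
  and secretes S2, P2 utilizes {N1, S2} and secretes S3, P3 utilizes
  {N1, S3} and secretes S1 — whose cells evolve by allele mutation,
  horizontal gene transfer (gene embedding) and gene loss.  A species is
  a gene-presence set; HGT and loss found new species;
* a temperate phage whose host range is the S1-utilizers: infections turn
  lytic when the host deme is doing well (high per-cell resource gain or
  a growing census) and lysogenic otherwise, with induction back to lysis
  when conditions improve.

Speciation is quantified by the SRI over a window `(a, b]`:

```
SRI = |{newly emerged viable populations}| / (b − a)
```

with a population *viable* if it survived at least `thres = 500`
generations.  Intended users: computational ecologists and
microbiologists studying phage–host eco-evolutionary dynamics who want a
small, fully reproducible, testable sandbox rather than a monolithic
simulator.

## Worked example

```python
from phagegrid import (InvasionEvent, ScenarioConfig, SriParams,
                       compute_sri, run_scenario)

base = ScenarioConfig(duration_generations=4400, seed=1001, log_every=20)
control = run_scenario(base)
invaded = run_scenario(base.replace(
    invasion=InvasionEvent(generation=2200, node=(1, 1), inoculum=1000.0)))

params = SriParams(thres=500, burn_in=1000)
for name, run in [("control", control), ("phage", invaded)]:
    sri = compute_sri(run.registry, (2200, 4400), 4400, params)
    print(f"{name}: SRI={sri.value:.2e} ({sri.n_viable} viable originations),"
          f" final cells={run.grid.total_cells()}")
```

Output (seed 1001):

```
control: SRI=1.82e-03 (4 viable originations), final cells=2693
phage: SRI=0.00e+00 (0 viable originations), final cells=2596
```

Both runs are bitwise identical until generation 2200 (paired seeds).  In
the control, four new species emerged after generation 2200 and survived
at least 500 generations (SRI 1.8×10⁻³ per generation).  In the invaded
run the phage swept the S1-utilizing matrix of the community — lysing
well-fed hosts, lysogenizing starving ones — and the surviving,
largely lysogenized community stopped producing viable new species
entirely, while its total size recovered to the habitat's carrying
capacity.  That is the headline effect: the phage suppresses speciation
by over an order of magnitude while stabilizing community size.

The same `RunOutput` object carries per-node time series
(`deme_log`, `substrate_log`, `phage_log`), a demographic ledger, and the
species registry used by the SRI.  A command-line interface wraps the
same machinery:

```
phagegrid run --config scenario.yaml --seed 7 --out-dir out/
phagegrid summary --run-dir out/ --invasion-generation 2200
phagegrid experiment --out-dir exp/ --replicates 10
```

The `experiment` subcommand runs the full factorial design (invasion time
× invasion node × chemotaxis, with paired no-phage controls) and writes a
checklist report of the qualitative outcomes (Q1 spatial gradient, Q2
phage suppression, Q3 chemotaxis contrast, Q4 node ranking).

## Layout

```
src/phagegrid/
  community.py   genotypes, species keys, demes, nodes, grid
  growth.py      uptake allocation, births/deaths, secretion
  evolution.py   mutation, HGT, gene loss, species registry
  transport.py   in-flow, flow, diffusion, chemotaxis
  phage.py       invasion, infection, lysis, lysogeny, induction
  engine.py      scenario config, initial community, scheduler, run loop
  metrics.py     SRI, per-node richness/biomass summaries, SRI tables
  experiment.py  factorial design, paired seeds, checklist report
  cli.py         command-line interface
docs/methods.md  model description, calibration rationale, limitations
```
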