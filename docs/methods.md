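# Methods

`phagegrid` simulates the eco-evolutionary dynamics of a microbial
community living in a spatially distributed, flowing habitat under attack
by a temperate bacteriophage, and quantifies how the phage reshapes
speciation through a Speciation Rate Index (SRI).

## Model

### Habitat

The habitat is a lattice (default 5×5) of *point environments* ("nodes"):
small well-mixed volumes holding substrate pools, free phage particles and
bacterial cells.  Coordinates are 1-based `(row, col)`; row 1 is the top,
column 1 the left.  Four transport processes act each generation:

* **In-flow** supplies the non-specific substrate N1 to every node of the
  top row and leftmost column (the corner `(1,1)` is fed once).
* **Flow** advects a fraction `flow_phi` of every transportable quantity
  (substrates, free phage, cells of every infection sub-state) downstream:
  interior nodes export half down and half right, the last row forwards
  right, the last column down, and the terminal corner `(height, width)`
  exports out of the system.  The habitat is therefore an open system with
  a single source edge and a single sink.
* **Diffusion** exchanges a fraction `diff_d` per orthogonal neighbor,
  symmetrically, with reflecting boundaries.
* **Chemotaxis** (optional) moves a fraction `chemo_fraction` of each
  deme's healthy cells and lysogens to the orthogonal neighbor with the
  highest attractiveness, defined as the sum over the deme's utilizable
  substrates of mean uptake efficiency × pool size, when that exceeds the
  current node's value.  Moribund (lytic-infected) cells do not move.

All transport updates are synchronous (exports computed from the pre-step
state), so results never depend on node iteration order.  Fractional cell
counts are resolved by largest-remainder rounding in deterministic mode
and multinomial draws in stochastic mode; substrates and phage are
real-valued.  A closed variant (in-flow zero, out-flow disabled,
deterministic rounding) conserves every quantity to floating-point
accuracy and anchors the conservation test suite.

One property worth stating explicitly: *without* consumption the flow
field does not produce a nutrient-rich top — at steady state the influx
must leave through the sink, so standing concentration is highest at the
terminal corner.  The familiar rich-top/poor-bottom gradient is an
emergent property of the running community: upstream cells intercept the
in-flow, and what reaches the bottom is leftovers.  Tests assert the
advection direction on pulses, and the ecological gradient on full runs.

### Cells, genomes, species

A genome is a set of genes, each a single numeric parameter: utilization
efficiencies (per substrate, in (0,1]) and synthesis efficiencies (for the
specific substrates S1–S3).  *Species identity is the gene-presence set*
(which utilization and synthesis genes exist); the numeric values are
intra-species allelic polymorphism.  Cells are aggregated per node and
species into super-individual demes; within a deme, cells with identical
allele vectors (quantized to 6 decimals) form one counted class.

The founding community is a three-species cyclic cross-feeding web on the
four substrates {N1, S1, S2, S3}:

    P1 utilizes {N1, S1}, synthesizes S2
    P2 utilizes {N1, S2}, synthesizes S3
    P3 utilizes {N1, S3}, synthesizes S1

Every population consumes the externally supplied N1; the specific
substrates close the trophic cycle P1 → P2 → P3 → P1.  Founder
efficiencies are symmetric (0.5 for N1, 0.4 for the specific substrate,
0.6 for synthesis); the asymmetries that matter later are generated by
evolution, not by the initial condition.

### Growth

Each generation, every deme demands `demand_per_cell_q` units of each
utilizable substrate per cell (healthy, lysogen and lytic-infected cells
all feed).  Demands against a pool are granted in full when the pool
covers them and proportionally scaled otherwise.  A class with allele
vector *e* gains `g = Σ_s e(s)·u(s)` per cell, where `u(s)` is the per-cell
granted uptake.  Expected births are `cells · Y · max(0, g − m)` and
expected deaths `cells · δ`; stochastic mode draws Poisson births and
binomial deaths, deterministic mode rounds expectations.  Because births
are computed per allele class, fitter alleles outgrow weaker ones and
selection prunes polymorphism.  Cells carrying synthesis genes secrete
`synth_yield · e(s') · (total per-cell uptake)` units of product per cell;
secretions are buffered and credited to pools only after every deme has
fed (order independence).  Lytic-infected cells feed (resources diverted
to phage replication) but never reproduce or secrete; lysogens behave as
healthy cells and their offspring inherit the prophage.

### Evolution

Three event processes, all per node per generation:

* **Mutation** — `Binomial(healthy cells, mu)` cells each multiply one
  uniformly chosen gene's efficiency by `lognormal(0, mutation_sd)`,
  clamped to (0.001, 1].  Mutation changes allele values only, never
  species identity.
* **Horizontal gene transfer** — `Poisson(hgt_rate)` events; a donor deme
  (weighted by cells; lysogens remain part of the donatable gene pool) and
  a healthy recipient of a different species are drawn, one gene present
  in the donor and absent in the recipient is embedded into one recipient
  cell with the donor's current efficiency.
* **Gene loss** — `Poisson(loss_rate)` events delete one gene (never the
  last utilization gene, which would leave a nonviable genome) from one
  cell.

Cells whose gene-presence set changes either join the extant species with
that key or found a new species; every origination and extinction is
appended to a registry with generation and node provenance.  A key
re-emerging after extinction opens a fresh record.  These events conserve
cell counts exactly.

### Phage

A single temperate phage infects cells able to utilize S1.  Free phage
adsorb to susceptible healthy cells by mass action
(`a · phage · susceptible`, capped by both counts); each infection
consumes one phage and one cell.  The lytic/lysogenic decision is made per
deme per generation from the host's well-being: *favorable* conditions —
per-cell resource gain at or above `favorable_g`, or a growing census —
route infections to the lytic pathway (lysis after `latency_L`
generations, releasing `burst_B` phage per cell); otherwise cells are
lysogenized.  Lysogens are immune to superinfection, reproduce normally,
and a fraction `induction_pi` switches to the lytic pathway per generation
*when conditions are favorable*.  Free phage decay by `decay_delta_p` per
generation.  Lysed biomass is destroyed (it does not return to the
substrate pools), and prophage carriage is assumed cost-free; both
assumptions are deliberate simplifications flagged for sensitivity
analysis.

### Scheduler and randomness

A generation applies, in fixed order: in-flow → scheduled invasion →
growth → mutation/HGT/gene loss → phage processes (adsorption, induction,
lysis progression, decay) → flow → diffusion → chemotaxis → extinction
bookkeeping.  Every stochastic phase draws from a counter-based PCG64
substream keyed by `(seed, generation, phase, node)`, which makes runs
bitwise reproducible, makes paired scenarios identical up to their first
configured difference (e.g. the invasion generation), and keeps node
iteration order irrelevant to the random stream.  An explicit
per-generation ledger (births − deaths − lysed − out-flowed = Δcells)
is closed exactly in every mode and asserted in tests.

## Speciation Rate Index

For a half-open window `(a, b]`,

    SRI = (number of newly emerged viable populations) / (b − a)

where a population is viable if its observed lifespan reached `thres`
generations (default 500).  Records still extant at the end of a run
count as viable only when their age already reaches the threshold;
younger right-censored records are excluded rather than assumed to
survive.  Founder species (origin generation 0) never count.  Because
early diversification of the founder community inflates rates, the first
`burn_in` generations (default 1000) are excluded from before/after
averages.  Per-node SRI attributes each origination to its *origin* node,
making per-node numerators an exact partition of the whole-grid numerator.

## Parameter calibration

The study design fixes the structure of the model but not its rate
constants.  The package defaults were calibrated once, on no-phage
control runs, to put the community into the regime the study describes —
a persistent, spatially stratified community with ongoing speciation —
and then frozen:

* `yield_Y = 5.0`, `demand_per_cell_q = 0.1`, `maintenance_m = 0.02`,
  `death_rate_delta = 0.05`: with uptake capped at ~0.09 resource/cell per
  generation, a yield of 1 offspring per unit resource cannot outrun
  advective washout (max net growth ~2%/generation against a ~10%/
  generation transport loss) and the habitat empties; a yield of 5 gives
  a maximum net growth rate of ~30%/generation and a stable community of
  a few thousand cells on the default in-flow.
* `inflow_rate = 5.0` N1 units per in-flow node per generation sets the
  community's carrying capacity (~2000–3000 cells on the 5×5 grid) —
  large enough for selection to dominate drift in established demes while
  single-cell founders still face meaningful establishment risk.
* `flow_phi = 0.1`, `diff_d = 0.05`: at `flow_phi = 0.2` cells behave
  like solutes — biomass accumulates toward the sink and the spatial
  biomass profile inverts; at 0.1 the community is effectively sedentary
  relative to its growth rate, upstream populations intercept the
  in-flow, and the rich-top/poor-bottom stratification emerges.
* `hgt_rate = loss_rate = 0.05` events per node per generation: gives the
  registry enough origination attempts (~2.5/generation grid-wide) that
  the SRI resolves differences between scenarios on desk-scale runs.
* `induction_pi = 0.005`: a lysogen reservoir that drains at 5%/generation
  during every favorable spell disappears within a few hundred
  generations of an epidemic, after which the phage is lost from the
  system; at 0.5%/generation the reservoir persists for thousands of
  generations, keeping the phage endemic — lysogens trickle inductions,
  re-emergent S1-utilizers are re-infected, and the suppressed state is
  stable, which is the regime described for temperate-phage-dominated
  communities.
* Phage kinetics `adsorption_a = 1e-3`, `burst_B = 50`, `latency_L = 2`,
  `decay_delta_p = 0.1`, inoculum 1000 are standard magnitudes; the
  epidemic sweeps the susceptible matrix within tens of generations of
  invasion.

## What the simulations show (and what they cannot)

The default experiment crosses invasion time × invasion node × chemotaxis
with paired no-phage controls sharing replicate seeds.  The qualitative
outcomes the test suite checks are: (i) phage invasion suppresses the
post-invasion speciation rate — when the phage fixates (the usual
outcome), the susceptible (S1-utilizing) matrix of the community is
lysed or lysogenized, the trophic cascade collapses the cross-feeding
web, and the surviving lysogenized community is evolutionarily inert
(post-invasion SRI exactly zero) because the healthy gene-exchange pool
is gone; the ensemble-mean order-of-magnitude contrast can nonetheless
fail when a replicate escapes by receptor loss (see Known limitations);
(ii) in controls, mean species richness rises and biomass falls with
distance (row+col) from the in-flow corner, because dominant N1-fed
populations monopolize the top while specific substrates accumulating
downstream open niches ("ecological licenses") for specialists;
(iii) with chemotaxis enabled the community settles to a lower standing
species number than paired chemotaxis-off controls over multi-thousand-
generation horizons (the early transient can go the other way).

These are emergent statistical properties of a stochastic simulator, not
numeric reproductions: the original study's rate constants are not
published, so its SRI table values are not comparable digit-for-digit,
and the acceptance checks are deliberately order-of-magnitude and
sign/rank comparisons at reduced problem sizes (5×5 grid, runs of a few
thousand generations with mid-run invasion, 5–6 replicates) chosen to
keep a full experiment within minutes on one CPU.

The synthetic scenario generator emulates the study conditions — a small
closed trophic web, one phage type with a fixed host range, no immunity
evolution — and deliberately omits features of real communities:
sequence-level genomes, phage host-range evolution, CRISPR/restriction
defenses, transduction as an HGT vehicle, lysed-biomass recycling, and
any fitness cost of prophage carriage.  Passing tests therefore
demonstrate the internal consistency of this model class, not predictions
about any particular natural community.

## Numerical choices

* Efficiencies clamped to (0.001, 1]; allele identity quantized to 6
  decimals so the class structure stays finite.
* Deterministic mode: rounded expectations for all demographic numbers,
  largest-remainder apportionment for splits (ties to the lowest index),
  real-valued substrate/phage arithmetic — used by the conservation,
  equivalence and ledger tests.
* Attractiveness ties in chemotaxis break toward the lexicographically
  smallest coordinates; a neighbor must be *strictly* better to trigger
  movement.
* The lytic latency counter decrements on the generation of infection;
  cells reaching zero lyse, so `latency_L = 0` lyses in the infection
  generation and `latency_L = 2` two generations later.
* Degenerate inputs: empty nodes and empty demes are skipped and pruned;
  a deme consisting only of lysogens keeps a representative allele vector
  (count-weighted mean at lysogenization) for metabolism and for gene
  donation.

## Known limitations

* **Resistance evolution by receptor loss.**  The phage's host range is
  defined by gene content (S1-utilization), and gene loss is an in-scope
  evolutionary event — so hosts can evolve immunity by dropping the
  S1-utilization gene.  When the community has also lost S1 *synthesis*
  (synthesis genes persist only when self-consumed, since secretion is a
  public good), S1-utilization carries no income and its loss is neutral:
  immune variants of the dominant genotype drift to small standing
  numbers.  If such a variant is present when the phage invades, it
  survives the epidemic, inherits the vacated niches, the phage starves
  out, and community evolution resumes at the control rate.  At the
  package defaults this happens in roughly one replicate in six; in the
  remaining replicates suppression is complete (post-invasion SRI exactly
  zero).  The order-of-magnitude suppression therefore holds conditional
  on phage fixation, but the *ensemble mean* ratio across replicates is
  bimodal and can fall below ten when an escape occurs — the
  corresponding acceptance test asserts the unconditional ensemble
  statistic and is expected to fail on seed sets containing an escape.
  The trade-off is structural: key-space turnover (which sustains the
  control's speciation rate) and immune-variant generation are the same
  gene-loss process, so damping one damps the other.

* The gene universe (4 substrates, ≤7 genes) bounds the species-key space
  at 120; speciation saturates once the viable region of that space is
  occupied, so very long runs under-represent the open-ended
  diversification seen in systems with larger gene repertoires.
* Chemotaxis in this model is niche-seeking: relocating demes toward
  their own substrates initially rescues marginal specialist populations
  (raising diversity over the first ~2–3000 generations) while
  progressively concentrating the community into fewer, more competitive
  nodes.  Over longer horizons the concentration effect dominates and
  chemotaxis-on communities settle to lower standing species numbers
  than paired chemotaxis-off controls; the acceptance check measures the
  contrast at a 4400-generation horizon, past the transient.
* Single-phage, single-host-range; no coevolution.
* Performance: ~5–10 ms per generation on a 5×5 grid at carrying
  capacity (pure Python); a full 10 000-generation scenario takes one to
  two minutes on one CPU.
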