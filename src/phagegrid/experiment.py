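"""Factorial experiment harness: invasion time x location x chemotaxis.

The full design crosses invasion times (early / middle / late), invasion
nodes (top (1,1), middle (3,3), bottom (5,5)) and the chemotaxis switch,
plus one paired no-invasion control per chemotaxis arm.  Replicate r of
every cell shares the same derived seed, so with-phage and control runs
are bitwise identical up to the invasion generation and any divergence is
attributable to the phage.

``run_experiment`` executes the design and evaluates a fixed checklist:

Q1  control, chemotaxis off: per-node mean species richness rises and
    biomass falls with distance (row+col) from the in-flow corner;
Q2  phage suppression: mean whole-grid post-invasion SRI of controls over
    that of phage runs (middle-time invasion into (1,1)) is at least
    one order of magnitude;
Q3  chemotaxis on yields fewer total species than paired chemotaxis-off
    controls;
Q4  (informative) ranking of post-invasion SRI across invasion nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .engine import RunOutput, ScenarioConfig, run_scenario
from .metrics import SriParams, build_sri_tables, compute_sri, summarize_node
from .phage import InvasionEvent


@dataclass(frozen=True)
class ExperimentDesign:
    """The factorial design and its replication."""

    invasion_times: tuple[int, ...] = (1, 5000, 6600)
    invasion_nodes: tuple[tuple[int, int], ...] = ((1, 1), (3, 3), (5, 5))
    chemotaxis: tuple[bool, ...] = (False, True)
    replicates: int = 10
    base_config: ScenarioConfig = field(
        default_factory=lambda: ScenarioConfig(duration_generations=10000))
    sri: SriParams = field(default_factory=SriParams)

    def replicate_seed(self, replicate: int) -> int:
        """Replicate r shares this seed across every cell (paired design)."""
        return (self.base_config.seed * 10007 + replicate) % (2**31)


@dataclass(frozen=True)
class ScenarioCell:
    """One cell of the design: an (arm, replicate) -> config binding."""

    invasion_time: Optional[int]  # None = control
    invasion_node: Optional[tuple[int, int]]
    chemotaxis: bool
    replicate: int
    config: ScenarioConfig

    @property
    def is_control(self) -> bool:
        return self.invasion_time is None

    def arm(self) -> tuple:
        return (self.invasion_time, self.invasion_node, self.chemotaxis)


def scenario_matrix(design: ExperimentDesign) -> list[ScenarioCell]:
    """One config per (cell, replicate); controls pair each chemotaxis arm."""
    cells = []
    arms: list[tuple[Optional[int], Optional[tuple[int, int]], bool]] = [
        (None, None, chemo) for chemo in design.chemotaxis]
    arms += [(t, n, chemo) for t, n, chemo in itertools.product(
        design.invasion_times, design.invasion_nodes, design.chemotaxis)]
    for (time, node, chemo), rep in itertools.product(
            arms, range(design.replicates)):
        invasion = None
        if time is not None:
            inoculum = (design.base_config.phage.inoculum
                        if design.base_config.phage else 1000.0)
            invasion = InvasionEvent(generation=time, node=node,
                                     inoculum=inoculum)
        config = design.base_config.replace(
            invasion=invasion, chemotaxis_enabled=chemo,
            seed=design.replicate_seed(rep))
        cells.append(ScenarioCell(invasion_time=time, invasion_node=node,
                                  chemotaxis=chemo, replicate=rep,
                                  config=config))
    return cells


def node_distance(node: tuple[int, int]) -> int:
    """Distance proxy along the flow direction: row + col."""
    return node[0] + node[1]


def richness_biomass_profile(run: RunOutput, window: tuple[int, int]
                             ) -> pd.DataFrame:
    """Per-node mean richness/biomass plus flow distance for one run."""
    rows = []
    grid = run.grid
    for r in range(1, grid.height + 1):
        for c in range(1, grid.width + 1):
            rich, bio = summarize_node(run.deme_log, (r, c), window)
            rows.append({"row": r, "col": c, "distance": r + c,
                         "richness": rich, "biomass": bio})
    return pd.DataFrame(rows)


def gradient_correlations(run: RunOutput, window: tuple[int, int]
                          ) -> tuple[float, float]:
    """Spearman correlations of (richness, biomass) with flow distance."""
    profile = richness_biomass_profile(run, window)
    rho_rich = stats.spearmanr(profile["distance"],
                               profile["richness"]).statistic
    rho_bio = stats.spearmanr(profile["distance"],
                              profile["biomass"]).statistic
    return float(rho_rich), float(rho_bio)


def standing_richness(run: RunOutput, burn_in: int = 1000) -> float:
    """Mean number of species present grid-wide per logged generation
    (cells in any infection sub-state count as presence)."""
    log = run.deme_log
    log = log[log["generation"] > burn_in]
    if log.empty:
        log = run.deme_log
    cells = log["healthy"] + log["lysogens"] + log["lytic_infected"]
    present = log[cells > 0]
    if present.empty:
        return 0.0
    return float(present.groupby("generation")["species_id"].nunique()
                 .mean())


def total_species_count(run: RunOutput, thres: Optional[int] = None) -> int:
    """Number of species that ever existed in a run (founders included);
    with ``thres``, only those whose lifespan reached the threshold."""
    if thres is None:
        return len(run.registry.records)
    end = run.grid.generation
    n = 0
    for rec in run.registry.records:
        ext = rec.extinction_generation
        life = (end if ext is None else ext) - rec.origin_generation
        if life >= thres:
            n += 1
    return n


def post_invasion_sri(run: RunOutput, invasion_generation: int,
                      params: SriParams) -> float:
    end = run.grid.generation
    return compute_sri(run.registry, (invasion_generation, end), end,
                       params).value


@dataclass
class ExperimentReport:
    runs: dict  # ScenarioCell -> RunOutput
    checklist: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)

    def checklist_text(self) -> str:
        lines = []
        for q, entry in sorted(self.checklist.items()):
            status = entry.get("pass")
            mark = ("PASS" if status else
                    "FAIL" if status is not None else "INFO")
            lines.append(f"{q}: {mark}  {entry.get('detail', '')}")
        return "\n".join(lines)


def run_experiment(design: ExperimentDesign,
                   out_dir=None,
                   suppression_cell: Optional[tuple] = None,
                   fold_threshold: float = 10.0,
                   progress: bool = False) -> ExperimentReport:
    """Run every cell of the design and evaluate the Q1-Q4 checklist.

    ``suppression_cell`` selects the (time, node) cell for the Q2 fold
    comparison; default is the middle invasion time into (1,1).
    """
    cells = scenario_matrix(design)
    runs: dict = {}
    for i, cell in enumerate(cells):
        if progress:
            print(f"[{i + 1}/{len(cells)}] time={cell.invasion_time} "
                  f"node={cell.invasion_node} chemo={cell.chemotaxis} "
                  f"rep={cell.replicate}", flush=True)
        runs[cell] = run_scenario(cell.config)
    report = ExperimentReport(runs=runs)
    if not cells:
        report.checklist["empty"] = {
            "pass": True, "detail": "empty design; nothing to evaluate"}
        return report
    params = design.sri
    duration = design.base_config.duration_generations
    # the burn-in exclusion only applies when the run extends past it
    burn_in = params.burn_in if params.burn_in < duration else 0
    window = (burn_in, duration)

    def arm_runs(time, node, chemo):
        return [runs[c] for c in cells
                if c.arm() == (time, node, chemo)]

    # Q1: spatial gradient in chemotaxis-off controls
    controls_off = arm_runs(None, None, False)
    if controls_off:
        rhos = [gradient_correlations(r, window) for r in controls_off]
        ok = sum(1 for rr, rb in rhos if rr > 0 and rb < 0)
        report.checklist["Q1_gradient"] = {
            "pass": ok >= max(1, int(np.ceil(0.8 * len(rhos)))),
            "detail": (f"{ok}/{len(rhos)} replicates with richness rising "
                       f"and biomass falling along the flow"),
            "richness_rho": [r for r, _ in rhos],
            "biomass_rho": [b for _, b in rhos],
        }

    # Q2: order-of-magnitude SRI suppression in the selected cell
    if suppression_cell is None:
        mid_time = (design.invasion_times[len(design.invasion_times) // 2]
                    if design.invasion_times else None)
        suppression_cell = (mid_time, (1, 1))
    time, node = suppression_cell
    phage_runs = arm_runs(time, node, False)
    if phage_runs and controls_off and time is not None:
        ctrl_sri = [post_invasion_sri(r, time, params)
                    for r in controls_off]
        phage_sri = [post_invasion_sri(r, time, params)
                     for r in phage_runs]
        mean_ctrl = float(np.mean(ctrl_sri))
        mean_phage = float(np.mean(phage_sri))
        fold = mean_ctrl / mean_phage if mean_phage > 0 else float("inf")
        # paired bootstrap over replicate indices
        rng = np.random.default_rng(design.base_config.seed)
        n = min(len(ctrl_sri), len(phage_sri))
        folds = []
        for _ in range(1000):
            idx = rng.integers(n, size=n)
            c = np.mean([ctrl_sri[i] for i in idx])
            p = np.mean([phage_sri[i] for i in idx])
            folds.append(c / p if p > 0 else np.inf)
        # order statistics only: fold can be infinite when no phage-run
        # origination survives, and interpolation across inf is undefined
        lo, hi = np.percentile(folds, [2.5, 97.5], method="nearest")
        report.checklist["Q2_suppression"] = {
            "pass": fold >= fold_threshold,
            "detail": (f"fold suppression {fold:.1f} "
                       f"(bootstrap 95% CI {lo:.1f}-{hi:.1f}); "
                       f"control SRI {mean_ctrl:.2e}, "
                       f"phage SRI {mean_phage:.2e}"),
            "fold": fold, "ci": (float(lo), float(hi)),
            "control_sri": ctrl_sri, "phage_sri": phage_sri,
        }

    # Q3: chemotaxis lowers the community's species number (paired
    # controls; standing richness = mean species present per generation)
    controls_on = arm_runs(None, None, True)
    if controls_on and controls_off:
        pairs = list(zip(controls_off, controls_on))
        off_rich = [standing_richness(r, burn_in) for r, _ in pairs]
        on_rich = [standing_richness(r, burn_in) for _, r in pairs]
        lower = sum(1 for a, b in zip(off_rich, on_rich) if b < a)
        report.checklist["Q3_chemotaxis"] = {
            "pass": lower >= max(1, int(np.ceil(0.8 * len(pairs)))),
            "detail": (f"{lower}/{len(pairs)} pairs with lower standing "
                       f"species number when chemotaxis is on "
                       f"(off {np.mean(off_rich):.1f}, "
                       f"on {np.mean(on_rich):.1f})"),
            "off": off_rich, "on": on_rich,
        }

    # Q4 (informative): post-invasion SRI ranking across invasion nodes
    ranking = {}
    for time in design.invasion_times:
        per_node = {}
        for node in design.invasion_nodes:
            rs = arm_runs(time, node, False)
            if rs:
                per_node[node] = float(np.mean(
                    [post_invasion_sri(r, time, params) for r in rs]))
        if per_node:
            ranking[time] = per_node
    if ranking:
        report.checklist["Q4_node_ranking"] = {
            "pass": None,
            "detail": "; ".join(
                f"t={t}: " + ", ".join(
                    f"{n}={v:.2e}" for n, v in sorted(per.items()))
                for t, per in ranking.items()),
            "ranking": ranking,
        }

    # before/after-invasion SRI analog tables (rows: invasion node;
    # columns: invasion time x before/after), chemotaxis-off arm, and the
    # whole-run analog, averaged over replicates
    t1_rows, t2_rows = [], []
    for node in design.invasion_nodes:
        t1 = {"invasion_node": str(node)}
        t2 = {"invasion_node": str(node)}
        for time in design.invasion_times:
            rs = arm_runs(time, node, False)
            if not rs:
                continue
            before, after, whole = [], [], []
            for r in rs:
                end = r.grid.generation
                tables = build_sri_tables(r.registry, time, end, params)
                for dest, cell in ((before, tables["before"]["grid"]),
                                   (after, tables["after"]["grid"]),
                                   (whole, tables["whole"]["grid"])):
                    if cell is not None:
                        dest.append(cell.value)
            t1[f"t{time}_before"] = np.mean(before) if before else None
            t1[f"t{time}_after"] = np.mean(after) if after else None
            t2[f"t{time}_whole"] = np.mean(whole) if whole else None
        t1_rows.append(t1)
        t2_rows.append(t2)
    if t1_rows:
        report.tables["sri_before_after"] = pd.DataFrame(t1_rows)
        report.tables["sri_whole_run"] = pd.DataFrame(t2_rows)

    # summary table over all runs
    rows = []
    for cell, run in runs.items():
        end = run.grid.generation
        whole = compute_sri(
            run.registry,
            (params.burn_in if params.burn_in < end else 0, end), end,
            params)
        rows.append({
            "invasion_time": cell.invasion_time,
            "invasion_row": cell.invasion_node[0] if cell.invasion_node
            else None,
            "invasion_col": cell.invasion_node[1] if cell.invasion_node
            else None,
            "chemotaxis": cell.chemotaxis,
            "replicate": cell.replicate,
            "sri_whole": whole.value,
            "n_species_total": total_species_count(run),
            "n_species_viable": total_species_count(run, params.thres),
            "final_cells": run.grid.total_cells(),
        })
    report.tables["runs"] = pd.DataFrame(rows)

    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.tables["runs"].to_csv(out / "runs_summary.tsv", sep="\t",
                                     index=False)
        for name in ("sri_before_after", "sri_whole_run"):
            if name in report.tables:
                report.tables[name].to_csv(out / f"{name}.tsv", sep="\t",
                                           index=False)
        with open(out / "checklist.txt", "w") as fh:
            fh.write(report.checklist_text() + "\n")
    return report
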