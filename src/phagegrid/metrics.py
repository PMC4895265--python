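"""Speciation Rate Index (SRI) and per-node community summaries.

The SRI over a time window is the number of newly emerged *viable*
populations divided by the window length:

    SRI = |{p : p newly emerged viable population}| / time_span

A population is viable if it survived at least ``thres`` generations
(default 500).  Species extant at the end of a run count as viable only if
their observed age already reaches the threshold; younger right-censored
records are excluded rather than assumed to survive.  The founder species
(origin generation 0) are never counted.  The first ``burn_in``
generations are excluded from before/after-invasion averages because
initial diversification inflates early rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .evolution import SpeciesRegistry


@dataclass(frozen=True)
class SriParams:
    """thres: viability threshold (generations); burn_in: generations
    excluded from before/after averages."""

    thres: int = 500
    burn_in: int = 1000

    def __post_init__(self) -> None:
        if self.thres <= 0:
            raise ValueError("thres must be positive")


@dataclass(frozen=True)
class SriResult:
    value: float
    n_viable: int
    time_span: int
    scope: Optional[tuple[int, int]] = None  # None = whole grid


def record_is_viable(origin: int, extinction: Optional[int],
                     run_end: int, thres: int) -> Optional[bool]:
    """Viability of one record; None when right-censored too young."""
    if extinction is not None:
        return extinction - origin >= thres
    if run_end - origin >= thres:
        return True
    return None  # censored: too young to call


def compute_sri(registry: SpeciesRegistry, window: tuple[int, int],
                run_end: int, params: SriParams = SriParams(),
                node_filter: Optional[tuple[int, int]] = None) -> SriResult:
    """SRI over the half-open window (start, end].

    Counts registry records whose origin generation falls in the window
    (founders at generation 0 never qualify), whose origin node matches
    ``node_filter`` when given, and whose observed lifespan reaches the
    viability threshold.
    """
    start, end = window
    if not start < end:
        raise ValueError("empty SRI window")
    n_viable = 0
    for rec in registry.records:
        g = rec.origin_generation
        if g == 0 or not (start < g <= end):
            continue
        if node_filter is not None and rec.origin_node != node_filter:
            continue
        if record_is_viable(g, rec.extinction_generation, run_end,
                            params.thres):
            n_viable += 1
    span = end - start
    return SriResult(value=n_viable / span, n_viable=n_viable,
                     time_span=span, scope=node_filter)


def summarize_node(deme_log: pd.DataFrame, node: tuple[int, int],
                   window: tuple[int, int]) -> tuple[float, float]:
    """Mean species richness and mean biomass of a node over a window.

    Richness per logged generation counts species with at least one cell
    (healthy + lysogen + lytic-infected) in the node; biomass is the total
    cell count.  Means are over the logged generations in (start, end].
    """
    start, end = window
    rows = deme_log[(deme_log["row"] == node[0])
                    & (deme_log["col"] == node[1])]
    gens = deme_log["generation"].unique()
    gens = sorted(g for g in gens if start < g <= end)
    if not gens:
        raise ValueError(f"no logged generations for node {node} in window")
    rows = rows[(rows["generation"] > start) & (rows["generation"] <= end)]
    cells = (rows["healthy"] + rows["lysogens"] + rows["lytic_infected"])
    present = rows[cells > 0]
    richness = present.groupby("generation")["species_id"].nunique()
    biomass = cells.groupby(rows["generation"]).sum()
    n = len(gens)
    return (float(richness.reindex(gens, fill_value=0).sum() / n),
            float(biomass.reindex(gens, fill_value=0).sum() / n))


def build_sri_tables(registry: SpeciesRegistry, invasion_generation: int,
                     run_end: int, params: SriParams = SriParams(),
                     nodes: Optional[list] = None) -> dict:
    """Before/after-invasion and whole-run SRI, whole-grid and per node.

    ``before`` spans (burn_in, invasion], ``after`` (invasion, run_end],
    ``whole`` (burn_in, run_end].  An invasion at or before the burn-in
    leaves the before cell empty (as an early-time invasion has no
    unbiased pre-invasion window).
    """
    if invasion_generation > run_end:
        raise ValueError("invasion after run end")
    out: dict = {"before": {}, "after": {}, "whole": {}}
    scopes: list = [None] + (nodes or [])

    def put(table: str, scope, window) -> None:
        key = "grid" if scope is None else scope
        if window[0] >= window[1]:
            out[table][key] = None
        else:
            out[table][key] = compute_sri(registry, window, run_end, params,
                                          scope)

    for scope in scopes:
        put("before", scope, (params.burn_in, invasion_generation))
        put("after", scope, (invasion_generation, run_end))
        put("whole", scope, (params.burn_in, run_end))
    return out


def sri_tables_frame(tables: dict) -> pd.DataFrame:
    """Flatten build_sri_tables output into a tidy frame (TSV-ready)."""
    rows = []
    for table, cells in tables.items():
        for scope, res in cells.items():
            rows.append({
                "window": table,
                "scope": "grid" if scope == "grid" else f"{scope}",
                "sri": "" if res is None else res.value,
                "n_viable": "" if res is None else res.n_viable,
                "time_span": "" if res is None else res.time_span,
            })
    return pd.DataFrame(rows)
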