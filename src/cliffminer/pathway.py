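"""Cliff utilization: time-resolved progression and optimization pathways.

Two questions are answered per target set. First, was a cliff acted upon —
did structural analogs of its highly potent partner appear in later years?
Second, do optimization paths that start from cliff compounds reach the
most potent compounds (the top potency decile) more often than paths from
compounds not involved in any cliff? Paths are sequences of pairwise
analogous compounds (size-restricted MMP relations) in the analog graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import networkx as nx

from .cliffs import ActivityCliff
from .mmp import MatchedMolecularPair
from .survey import TargetSet

ProgressionStatus = Literal["progressed", "not_progressed"]


def build_analog_graph(target_set: TargetSet, mmps: Sequence[MatchedMolecularPair]) -> nx.Graph:
    """Graph over all compounds of a target set with MMP relations as edges.

    Isolated nodes (compounds with no analog) are retained; the cliff
    network's node set is always a subset of this graph's.
    """
    g = nx.Graph()
    for cid in sorted(target_set.compounds):
        g.add_node(cid, pki=target_set.pki[cid], year=target_set.year.get(cid))
    for mmp in mmps:
        if mmp.id_a in g and mmp.id_b in g:
            g.add_edge(mmp.id_a, mmp.id_b, transformation=mmp.transformation)
    return g


@dataclass
class TopDecile:
    members: frozenset[str]
    cutoff_pki: float
    degenerate: bool  # all compounds share one pKi


def top_decile(target_set: TargetSet) -> TopDecile:
    """The 10% most potent compounds (ceil(0.1 N), ties at the cutoff included)."""
    n = target_set.size
    if n == 0:
        raise ValueError("empty target set")
    k = -(-n // 10)  # ceil(0.1 * n)
    ranked = sorted(target_set.pki.items(), key=lambda kv: (-kv[1], kv[0]))
    cutoff = ranked[k - 1][1]
    members = frozenset(cid for cid, p in ranked if p >= cutoff)
    return TopDecile(members=members, cutoff_pki=cutoff, degenerate=len(members) == n and n > 1)


@dataclass
class PathwayResult:
    start: str
    reached: bool
    path: list[str]  # witness (shortest) path; [start] when start is itself a target
    length: int

    @property
    def started_in_targets(self) -> bool:
        return self.reached and self.length == 0


def find_optimization_pathway(
    graph: nx.Graph, start: str, targets: Iterable[str]
) -> PathwayResult:
    """Shortest analog sequence from ``start`` to any target compound.

    ``reached`` is True iff some target is graph-reachable from the start; a
    start that is itself a target counts as reached with a length-0 path.
    """
    if start not in graph:
        raise KeyError(f"start compound {start!r} not in analog graph")
    target_set = {t for t in targets if t in graph}
    if start in target_set:
        return PathwayResult(start=start, reached=True, path=[start], length=0)
    best: list[str] | None = None
    # single BFS from start; pick the nearest target, ties by compound id
    lengths, paths = nx.single_source_shortest_path_length(graph, start), None
    hits = sorted((lengths[t], t) for t in target_set if t in lengths)
    if hits:
        _, tgt = hits[0]
        best = nx.shortest_path(graph, start, tgt)
    if best is None:
        return PathwayResult(start=start, reached=False, path=[], length=-1)
    return PathwayResult(start=start, reached=True, path=list(best), length=len(best) - 1)


def cliff_progression_status(
    cliff: ActivityCliff,
    graph: nx.Graph,
    years: dict[str, int],
    min_analog_pki: float | None = None,
) -> ProgressionStatus:
    """Did analogs of the highly potent cliff partner appear after the cliff?

    The cliff's year is when both partners were available (max of the two
    report years). The cliff counts as progressed iff the potent partner has
    at least one analog-graph neighbor reported strictly later — same-year
    analogs carry no temporal evidence. ``min_analog_pki`` optionally
    restricts the analogs considered to sufficiently potent ones.
    """
    for cid in cliff.pair:
        if cid not in years:
            raise KeyError(f"compound {cid!r} has no year")
    cliff_year = max(years[cliff.id_a], years[cliff.id_b])
    potent = cliff.potent_partner
    if potent not in graph:
        return "not_progressed"
    for nbr in graph.neighbors(potent):
        if nbr in cliff.pair or years.get(nbr) is None:
            continue
        if min_analog_pki is not None and graph.nodes[nbr].get("pki", float("-inf")) < min_analog_pki:
            continue
        if years[nbr] > cliff_year:
            return "progressed"
    return "not_progressed"


@dataclass
class SuccessRates:
    rate_cliff_pct: float | None
    rate_noncliff_pct: float | None
    n_cliff: int
    n_noncliff: int
    n_cliff_in_decile: int
    n_noncliff_in_decile: int


def pathway_success_rates(
    graph: nx.Graph,
    cliff_compounds: Iterable[str],
    non_cliff_compounds: Iterable[str],
    targets: Iterable[str],
) -> SuccessRates:
    """Fraction of each group whose pathway reaches a top-decile compound.

    The two groups must be disjoint. Rates are percentages; an empty group
    has an undefined (None) rate. Length-0 successes (start already in the
    decile) are tallied separately.
    """
    cliff_grp, noncliff_grp = sorted(set(cliff_compounds)), sorted(set(non_cliff_compounds))
    overlap = set(cliff_grp) & set(noncliff_grp)
    if overlap:
        raise ValueError(f"groups are not disjoint: {sorted(overlap)[:5]}")
    target_list = list(targets)

    def _rate(group: list[str]) -> tuple[float | None, int]:
        if not group:
            return None, 0
        reached = at_origin = 0
        for cid in group:
            res = find_optimization_pathway(graph, cid, target_list)
            reached += res.reached
            at_origin += res.started_in_targets
        return 100.0 * reached / len(group), at_origin
    rate_c, origin_c = _rate(cliff_grp)
    rate_n, origin_n = _rate(noncliff_grp)
    return SuccessRates(
        rate_cliff_pct=rate_c, rate_noncliff_pct=rate_n,
        n_cliff=len(cliff_grp), n_noncliff=len(noncliff_grp),
        n_cliff_in_decile=origin_c, n_noncliff_in_decile=origin_n,
    )
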