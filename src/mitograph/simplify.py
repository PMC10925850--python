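"""Assembly-graph recruitment and simplification.

From seed contigs the graph is first recruited by breadth-first search —
nothing reachable is dropped, so repeat-mediated branches survive intact.
Simplification then removes, iterated to a fixpoint:

1. nuclear-like contigs: depth at or below ``nuclear_mult`` x the nuclear
   background depth (readsize / genomesize);
2. full-path plastid contigs: depth above ``plastid_mult`` x the mitochondrial
   median *and* every linked neighbour likewise plastid-class — a
   plastid-class contig with a mito-class neighbour is a candidate
   mitochondrial plastid insertion (MTPT) and is reserved;
3. weak links: support below ``weak_ratio`` x the smaller end depth, or below
   the absolute ``min_link`` floor;
4. tip contigs: contigs linked to nothing and not circular via a self-link.

Seed contigs are exempt from every depth gate: they carry the defining genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import pandas as pd

from .core import HEAD, TAIL, AssemblyGraph, GraphError, Link, MitographError

logger = logging.getLogger(__name__)

NUCLEAR = "nuclear"
MITO = "mito"
PLASTID = "plastid"


@dataclass
class DepthModel:
    """Depth landmarks separating nuclear, mitochondrial and plastid contigs.

    ``nuclear_depth`` is the expected nuclear background coverage
    (readsize / genomesize); ``mito_median`` the median depth of seed-hit
    contigs.  Contigs at or below ``nuclear_mult`` x nuclear background are
    nuclear-class; above ``plastid_mult`` x the mito median, plastid-class.
    """

    nuclear_depth: float
    mito_median: float
    nuclear_mult: float = 2.0
    plastid_mult: float = 3.0

    def __post_init__(self) -> None:
        if min(self.nuclear_depth, self.mito_median, self.nuclear_mult, self.plastid_mult) <= 0:
            raise MitographError("all depth-model fields must be positive")


@dataclass
class PruneParams:
    """Weak-link pruning: relative ratio and absolute ``--minLink`` floor."""

    weak_ratio: float = 0.2
    min_link: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.weak_ratio < 1):
            raise MitographError("weak_ratio must be in (0, 1)")
        if self.min_link < 0:
            raise MitographError("min_link must be non-negative")


def estimate_nuclear_depth(genomesize: float, readsize: float) -> float:
    """Expected nuclear coverage: total read bases over nuclear genome size."""
    if genomesize <= 0:
        raise MitographError("genomesize must be positive")
    if readsize <= 0:
        raise MitographError("readsize must be positive")
    return readsize / genomesize


def extend_seeds_bfs(graph: AssemblyGraph, seeds: Set[str]) -> AssemblyGraph:
    """Induced subgraph on everything reachable from any seed via links.

    Breadth-first with lexicographic tie-break; no reachable contig or link
    is filtered.
    """
    missing = set(seeds) - graph.contigs.keys()
    if missing:
        raise GraphError(f"seed contigs not in graph: {sorted(missing)}")
    visited: Set[str] = set()
    frontier = sorted(seeds)
    while frontier:
        nxt: Set[str] = set()
        for cid in frontier:
            if cid in visited:
                continue
            visited.add(cid)
            for nb in graph.neighbors(cid):
                if nb not in visited:
                    nxt.add(nb)
        frontier = sorted(nxt)
    return graph.subgraph(visited)


def remove_nuclear_like(
    graph: AssemblyGraph, dm: DepthModel, protected: Set[str] = frozenset()
) -> AssemblyGraph:
    """Drop non-protected contigs at or below the nuclear depth gate."""
    gate = dm.nuclear_mult * dm.nuclear_depth
    drop = [
        cid
        for cid, c in graph.contigs.items()
        if cid not in protected and c.depth <= gate
    ]
    return graph.remove_contigs(drop) if drop else graph


def _plastid_class(graph: AssemblyGraph, dm: DepthModel) -> Set[str]:
    gate = dm.plastid_mult * dm.mito_median
    return {cid for cid, c in graph.contigs.items() if c.depth > gate}


def resolve_plastid_contigs(
    graph: AssemblyGraph, dm: DepthModel, protected: Set[str] = frozenset()
) -> AssemblyGraph:
    """Remove full-path plastid contigs; reserve MTPT-like bridges.

    Classes are evaluated simultaneously on the input graph: a plastid-class
    contig is removed only when every linked neighbour (at both ends) is also
    plastid-class; one mito-class neighbour is enough to reserve it as a
    candidate mitochondrial plastid insertion.
    """
    plastid = _plastid_class(graph, dm)
    drop = []
    for cid in plastid:
        if cid in protected:
            continue
        neighbours = {n for n in graph.neighbors(cid)}
        if graph.has_self_link(cid):
            neighbours.add(cid)
        if neighbours and all(n in plastid for n in neighbours):
            drop.append(cid)
    return graph.remove_contigs(drop) if drop else graph


def reserved_mtpt_contigs(graph: AssemblyGraph, dm: DepthModel) -> Set[str]:
    """Plastid-class contigs kept because a linked neighbour is mito-class."""
    plastid = _plastid_class(graph, dm)
    out = set()
    for cid in plastid:
        if any(n not in plastid for n in graph.neighbors(cid)):
            out.add(cid)
    return out


def prune_weak_links(graph: AssemblyGraph, pp: Optional[PruneParams] = None) -> AssemblyGraph:
    """Drop links with support below the relative or absolute floor.

    A link is weak when its support is under ``weak_ratio`` times the depth of
    the shallower of its two end contigs (the conservative reading of the
    one-fifth rule), or under the absolute ``min_link`` count.  Contigs are
    untouched; tips created here fall to the following tip pass.
    """
    pp = pp or PruneParams()
    drop: List[Link] = []
    for l in graph.links:
        floor = pp.weak_ratio * min(graph.contigs[l.a].depth, graph.contigs[l.b].depth)
        if l.support < floor or l.support < pp.min_link:
            drop.append(l)
    return graph.remove_links(drop) if drop else graph


def remove_tips(graph: AssemblyGraph, trim_dead_ends: bool = False) -> AssemblyGraph:
    """Remove isolated, non-circular contigs until fixpoint.

    A tip is a contig linked to no other contig and lacking a self-link.
    With ``trim_dead_ends`` (off by default) classic dead-end clipping is
    applied as well: contigs attached through exactly one end slot are also
    removed iteratively.
    """
    g = graph
    while True:
        drop = []
        for cid in g.contigs:
            links = g.links_of(cid)
            if not links:
                drop.append(cid)
            elif trim_dead_ends:
                if any(l.is_self() for l in links):
                    continue
                if len(links) == 1 and (
                    g.degree(cid, HEAD) == 0 or g.degree(cid, TAIL) == 0
                ):
                    drop.append(cid)
        if not drop:
            return g
        g = g.remove_contigs(drop)


def classify_by_depth(graph: AssemblyGraph, dm: DepthModel) -> Dict[str, str]:
    """Per-contig class from the depth landmarks.

    Nuclear at or below the nuclear gate (inclusive), plastid above the
    plastid gate, mitochondrial in between.
    """
    nuclear_gate = dm.nuclear_mult * dm.nuclear_depth
    plastid_gate = dm.plastid_mult * dm.mito_median
    out = {}
    for cid, c in graph.contigs.items():
        if c.depth <= nuclear_gate:
            out[cid] = NUCLEAR
        elif c.depth > plastid_gate:
            out[cid] = PLASTID
        else:
            out[cid] = MITO
    return out


def write_classification_tsv(graph: AssemblyGraph, classes: Dict[str, str], path) -> None:
    rows = [
        {
            "contig": cid,
            "length": graph.contigs[cid].length,
            "depth": graph.contigs[cid].depth,
            "class": classes[cid],
        }
        for cid in sorted(graph.contigs)
    ]
    pd.DataFrame(rows, columns=["contig", "length", "depth", "class"]).to_csv(
        path, sep="\t", index=False
    )


def simplify_graph(
    graph: AssemblyGraph,
    dm: DepthModel,
    pp: Optional[PruneParams] = None,
    protected: Set[str] = frozenset(),
    skip_plastid: bool = False,
    trim_dead_ends: bool = False,
    max_rounds: int = 100,
) -> Tuple[AssemblyGraph, Dict[str, int], Set[str]]:
    """Full simplification pass iterated to fixpoint.

    Order per round: nuclear gate, plastid resolution, weak links, tips.
    Returns the simplified graph, per-stage removal tallies, and the union of
    MTPT-like reserved contigs observed across rounds.
    """
    pp = pp or PruneParams()
    stats = {"nuclear_removed": 0, "plastid_removed": 0, "links_pruned": 0, "tips_removed": 0}
    reserved: Set[str] = set()
    g = graph
    for _ in range(max_rounds):
        before = (g.n_contigs, g.n_links)
        g2 = remove_nuclear_like(g, dm, protected)
        stats["nuclear_removed"] += g.n_contigs - g2.n_contigs
        if not skip_plastid:
            reserved |= reserved_mtpt_contigs(g2, dm)
            g3 = resolve_plastid_contigs(g2, dm, protected)
        else:
            g3 = g2
        stats["plastid_removed"] += g2.n_contigs - g3.n_contigs
        g4 = prune_weak_links(g3, pp)
        stats["links_pruned"] += g3.n_links - g4.n_links
        g = remove_tips(g4, trim_dead_ends)
        stats["tips_removed"] += g4.n_contigs - g.n_contigs
        if (g.n_contigs, g.n_links) == before:
            break
    reserved &= g.contigs.keys()
    logger.info(
        "simplified to %d contigs / %d links (%s)", g.n_contigs, g.n_links, stats
    )
    return g, stats, reserved
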