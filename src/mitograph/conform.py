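"""Copy-number estimation and enumeration of circular conformations.

Plant mitogenomes recombine across repeats, so one simplified graph supports
several arrangements of the same contigs.  "All possible conformations" is
formalised as the set of *cycle covers* of the copy-number multigraph: each
contig is traversed exactly ``copies[id]`` times, every adjacency is realised
by a graph link with compatible ends, and strand consistency follows from the
end semantics (leaving through the tail keeps the stored strand).  A direct
repeat yields the master circle plus the two-subcircle decomposition; an
inverted repeat yields the two single-circle isomers.

Cycles are circular DNA molecules: a cycle equals any rotation of itself and
its reverse complement, and a conformation is an unordered multiset of
cycles.  Enumeration is exhaustive with deterministic ordering and an output
cap against combinatorial explosion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .core import (
    HEAD,
    TAIL,
    AssemblyGraph,
    GraphError,
    MitographError,
    NoSeedsError,
)
from .seeds import SeedHit

logger = logging.getLogger(__name__)

Step = Tuple[str, str]          # (contig id, '+'|'-')
Cycle = Tuple[Step, ...]


@dataclass
class CopyNumberTable:
    """Per-contig copy numbers relative to a single-copy depth baseline."""

    copies: Dict[str, int]
    baseline: float

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise MitographError("baseline depth must be positive")
        if any(c < 1 for c in self.copies.values()):
            raise MitographError("every copy number must be >= 1")


@dataclass
class Conformation:
    """One realizable arrangement: a set of oriented closed walks."""

    cycles: List[List[Step]]
    circular: List[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.circular:
            self.circular = [True] * len(self.cycles)

    def contig_usage(self) -> Dict[str, int]:
        usage: Dict[str, int] = {}
        for cyc in self.cycles:
            for cid, _ in cyc:
                usage[cid] = usage.get(cid, 0) + 1
        return usage

    def canonical(self) -> Tuple[Cycle, ...]:
        return canonical_conformation(self.cycles)


# ---------------------------------------------------------------------------
# canonical forms
# ---------------------------------------------------------------------------

def _flip(step: Step) -> Step:
    return step[0], "-" if step[1] == "+" else "+"


def canonical_cycle(cycle: Sequence[Step]) -> Cycle:
    """Lexicographically minimal rotation over both strands of a cycle."""
    cyc = tuple(cycle)
    rc = tuple(_flip(s) for s in reversed(cyc))
    n = len(cyc)
    best = None
    for var in (cyc, rc):
        for i in range(n):
            rot = var[i:] + var[:i]
            if best is None or rot < best:
                best = rot
    assert best is not None
    return best


def canonical_conformation(cycles: Sequence[Sequence[Step]]) -> Tuple[Cycle, ...]:
    """Sorted tuple of canonical cycles: the dedup key of a conformation."""
    return tuple(sorted(canonical_cycle(c) for c in cycles))


# ---------------------------------------------------------------------------
# target selection and copy numbers
# ---------------------------------------------------------------------------

def select_target_contigs(
    graph: AssemblyGraph,
    hits: Sequence[SeedHit],
    spread: float = 4.0,
    protected: FrozenSet[str] = frozenset(),
) -> Tuple[AssemblyGraph, float]:
    """Median-depth noise gate around the gene-bearing contigs.

    The median depth of hit contigs anchors the expected single-copy
    mitochondrial coverage; non-hit, non-protected contigs more than
    ``spread``-fold away from it (either side) are treated as noise or
    non-target and removed.  Returns the filtered graph and the median.
    """
    if spread <= 1:
        raise MitographError("spread must exceed 1")
    hit_ids = {h.contig_id for h in hits} & graph.contigs.keys()
    if not hit_ids:
        raise NoSeedsError(
            "no gene-bearing contig present in the graph; "
            "rerun in graphBuild mode with manually chosen seeds"
        )
    med = float(median(graph.contigs[cid].depth for cid in sorted(hit_ids)))
    lo, hi = med / spread, med * spread
    keep = {
        cid
        for cid, c in graph.contigs.items()
        if cid in hit_ids or cid in protected or lo <= c.depth <= hi
    }
    dropped = graph.contigs.keys() - keep
    if dropped:
        logger.info("noise gate removed %d contigs (median %.1fx)", len(dropped), med)
    return graph.subgraph(keep), med


def estimate_copy_numbers(graph: AssemblyGraph, baseline: float) -> CopyNumberTable:
    """Copy numbers from depth ratios, refined by link degrees.

    The depth estimate is ``max(1, round(depth / baseline))``.  Connections
    then refine it: a contig whose link degree on one side exceeds the
    estimate is raised to that degree, and a contig without a self-link
    cannot be entered more often than its busiest end has distinct links, so
    the estimate is capped there.  Contigs with a self-link (tandem-repeat
    topology) keep the depth-driven estimate.
    """
    if baseline <= 0:
        raise MitographError("baseline depth must be positive")
    copies: Dict[str, int] = {}
    for cid, c in graph.contigs.items():
        raw = max(1, int(c.depth / baseline + 0.5))
        deg = max(graph.degree(cid, HEAD), graph.degree(cid, TAIL))
        if deg == 0:
            copies[cid] = raw
        elif graph.has_self_link(cid):
            copies[cid] = max(raw, deg)
        else:
            copies[cid] = deg
    return CopyNumberTable(copies, baseline)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _entry_end(orient: str) -> str:
    return HEAD if orient == "+" else TAIL

def _exit_end(orient: str) -> str:
    return TAIL if orient == "+" else HEAD

def _orient_for_entry(end: str) -> str:
    return "+" if end == HEAD else "-"


def pick_start_contig(graph: AssemblyGraph, cnt: CopyNumberTable) -> str:
    """Longest single-copy contig (ties by id); if every contig is
    multi-copy, the longest contig of the lowest copy number."""
    if not graph.contigs:
        raise GraphError("empty graph")
    best = min(
        graph.contigs.values(),
        key=lambda c: (cnt.copies.get(c.id, 1), -c.length, c.id),
    )
    return best.id


class _Budget:
    __slots__ = ("steps", "limit")

    def __init__(self, limit: int):
        self.steps = 0
        self.limit = limit

    def tick(self) -> bool:
        self.steps += 1
        return self.steps > self.limit


def enumerate_conformations(
    graph: AssemblyGraph,
    cnt: CopyNumberTable,
    max_out: int = 100,
    max_states: int = 2_000_000,
) -> List[Conformation]:
    """Exhaustively enumerate strand-consistent cycle covers.

    Deduplicated up to cycle rotation, cycle order and reverse complement;
    sorted with single-cycle ("master circle") solutions first, then by
    canonical form.  Truncated at ``max_out`` distinct conformations with a
    logged warning.  An empty list means no cycle cover exists and the caller
    should fall back to exporting the graph itself.
    """
    if not graph.contigs:
        return []
    for cid in cnt.copies:
        if cid not in graph.contigs:
            raise GraphError(f"copy table references unknown contig {cid!r}")
    start = pick_start_contig(graph, cnt)
    remaining = {cid: cnt.copies.get(cid, 1) for cid in graph.contigs}
    found: Dict[Tuple[Cycle, ...], Tuple[Cycle, ...]] = {}
    budget = _Budget(max_states)
    truncated = False

    def search(cycles_done: List[List[Step]], cycle: List[Step], cycle_start: Step) -> bool:
        """DFS; returns False when enumeration should stop entirely."""
        if budget.tick():
            return False
        cur_id, cur_o = cycle[-1]
        exit_slot_end = _exit_end(cur_o)
        want_close = (cycle_start[0], _entry_end(cycle_start[1]))
        for link in graph.links_at(cur_id, exit_slot_end):
            nxt_id, nxt_end = link.other(cur_id, exit_slot_end)
            # option 1: close the current cycle through this link
            if (nxt_id, nxt_end) == want_close:
                done = cycles_done + [list(cycle)]
                if all(v == 0 for v in remaining.values()):
                    key = canonical_conformation(done)
                    if key not in found:
                        found[key] = key
                        _record(done)
                        if len(found) >= max_out:
                            return False
                else:
                    nxt_start = min(cid for cid, v in remaining.items() if v > 0)
                    remaining[nxt_start] -= 1
                    ok = search(done, [(nxt_start, "+")], (nxt_start, "+"))
                    remaining[nxt_start] += 1
                    if not ok:
                        return False
            # option 2: extend the cycle into a fresh copy
            if remaining[nxt_id] > 0:
                orient = _orient_for_entry(nxt_end)
                remaining[nxt_id] -= 1
                cycle.append((nxt_id, orient))
                ok = search(cycles_done, cycle, cycle_start)
                cycle.pop()
                remaining[nxt_id] += 1
                if not ok:
                    return False
        return True

    results: List[Conformation] = []

    def _record(cycles: List[List[Step]]) -> None:
        results.append(Conformation([list(c) for c in cycles]))

    remaining[start] -= 1
    completed = search([], [(start, "+")], (start, "+"))
    remaining[start] += 1
    if not completed and len(found) >= max_out:
        truncated = True
        logger.warning("conformation enumeration truncated at %d solutions", max_out)
    elif not completed:
        truncated = True
        logger.warning(
            "conformation search budget exhausted after %d states; "
            "the graph is too repeat-dense to solve exhaustively", budget.steps
        )
    results.sort(key=lambda conf: (len(conf.cycles), conf.canonical()))
    if truncated and not results:
        logger.warning("no conformation recovered before truncation")
    return results


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def validate_conformation(conf: Conformation, graph: AssemblyGraph, cnt: Optional[CopyNumberTable] = None) -> None:
    """Check walk connectivity and (optionally) copy conservation."""
    for cyc in conf.cycles:
        for step in cyc:
            if step[0] not in graph.contigs:
                raise GraphError(f"conformation references missing contig {step[0]!r}")
        for i, (cid, o) in enumerate(cyc):
            nid, no = cyc[(i + 1) % len(cyc)]
            slot_a = (cid, _exit_end(o))
            slot_b = (nid, _entry_end(no))
            if not any(
                l.other(*slot_a) == slot_b for l in graph.links_at(*slot_a)
            ):
                raise GraphError(
                    f"steps {cid}{o} -> {nid}{no} are not joined by a link"
                )
    if cnt is not None:
        usage = conf.contig_usage()
        for cid, c in cnt.copies.items():
            if usage.get(cid, 0) != c:
                raise GraphError(
                    f"contig {cid} used {usage.get(cid, 0)} times, expected {c}"
                )


def cycle_sequence(cycle: Sequence[Step], graph: AssemblyGraph) -> str:
    """Blunt concatenation of oriented contig sequences along a cycle."""
    from .core import revcomp

    parts = []
    for cid, o in cycle:
        contig = graph.contigs.get(cid)
        if contig is None:
            raise GraphError(f"conformation references missing contig {cid!r}")
        if contig.seq is None:
            raise GraphError(f"contig {cid!r} has no sequence")
        parts.append(contig.seq if o == "+" else revcomp(contig.seq))
    return "".join(parts)


def export_conformations(
    conformations: List[Conformation],
    graph: AssemblyGraph,
    outdir,
    prefix: str = "conformation",
) -> "pd.DataFrame":
    """Write one FASTA + GFA per conformation plus a summary table.

    Each FASTA record is one cycle (blunt-joined oriented contig sequences;
    the header carries length and circular flag); the companion GFA restates
    the walk with P lines.  With no conformations the simplified graph itself
    is exported conservatively: contigs flagged circular only when
    self-linked, no cycle FASTA.
    """
    import pandas as pd
    from pathlib import Path

    from .io import write_gfa

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    if not conformations:
        logger.warning(
            "no cycle cover exists; exporting the simplified graph conservatively"
        )
        write_gfa(graph, outdir / "fallback_graph.gfa")
        for cid in sorted(graph.contigs):
            rows.append(
                {
                    "conformation": 0,
                    "cycle": cid,
                    "length": graph.contigs[cid].length,
                    "circular": graph.has_self_link(cid),
                }
            )
    for i, conf in enumerate(conformations, 1):
        validate_conformation(conf, graph)
        fasta = outdir / f"{prefix}_{i}.fasta"
        with open(fasta, "w") as fh:
            for j, cyc in enumerate(conf.cycles, 1):
                seq = cycle_sequence(cyc, graph)
                circ = conf.circular[j - 1]
                fh.write(
                    f">{prefix}_{i}_cycle_{j} length={len(seq)} "
                    f"circular={'true' if circ else 'false'}\n{seq}\n"
                )
                rows.append(
                    {
                        "conformation": i,
                        "cycle": f"cycle_{j}",
                        "length": len(seq),
                        "circular": circ,
                    }
                )
        used = sorted({cid for cyc in conf.cycles for cid, _ in cyc})
        sub = graph.subgraph(used)
        gfa = outdir / f"{prefix}_{i}.gfa"
        write_gfa(sub, gfa)
        with open(gfa, "a") as fh:
            for j, cyc in enumerate(conf.cycles, 1):
                walk = ",".join(f"{cid}{o}" for cid, o in cyc)
                fh.write(f"P\tcycle_{j}\t{walk}\t*\n")
    df = pd.DataFrame(rows, columns=["conformation", "cycle", "length", "circular"])
    df.to_csv(outdir / f"{prefix}_summary.tsv", sep="\t", index=False)
    return df
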