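"""Shared fixtures, strategies and independent oracles for the test suite."""

from __future__ import annotations

import random
from typing import Dict, FrozenSet, List, Set, Tuple

import pytest
from hypothesis import HealthCheck, settings

from mitograph.core import HEAD, TAIL, AssemblyGraph, Contig, Link, revcomp
from mitograph.conform import canonical_conformation

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = "ACGT"


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(n))


def make_graph(contigs, links=()) -> AssemblyGraph:
    """Build a graph from (id, length, depth[, seq]) and link tuples."""
    g = AssemblyGraph()
    for spec in contigs:
        g.add_contig(Contig(*spec))
    for l in links:
        g.add_link(*l)
    return g


def random_assembly_graph(rng: random.Random, max_contigs: int = 8, with_seq: bool = True) -> AssemblyGraph:
    """A random valid graph instance for round-trip properties."""
    n = rng.randint(1, max_contigs)
    g = AssemblyGraph()
    ids = [f"c{i}" for i in range(n)]
    for cid in ids:
        length = rng.randint(1, 80)
        seq = random_dna(rng, length) if with_seq else None
        depth = round(rng.uniform(0.5, 200.0), 3)
        g.add_contig(Contig(cid, length, depth, seq))
    ends = (HEAD, TAIL)
    for _ in range(rng.randint(0, 2 * n)):
        a, b = rng.choice(ids), rng.choice(ids)
        g.add_link(a, rng.choice(ends), b, rng.choice(ends), rng.randint(0, 500))
    return g


# ---------------------------------------------------------------------------
# independent cycle-cover oracle: perfect matchings of contig-copy end slots
# ---------------------------------------------------------------------------

def brute_force_cycle_covers(
    graph: AssemblyGraph, copies: Dict[str, int]
) -> Set[Tuple]:
    """All strand-consistent cycle covers, enumerated via slot matchings.

    Every contig copy is a segment with a head slot and a tail slot.  A cycle
    cover corresponds exactly to a perfect matching of all slots in which two
    slots may pair only when the graph holds a link between those contig ends.
    Matchings are enumerated by always pairing the lowest unmatched slot, and
    each matching is decomposed into closed walks and canonicalised, so the
    result is directly comparable with the walk-based enumerator.
    """
    slots: List[Tuple[str, int, str]] = []
    for cid in sorted(graph.contigs):
        for i in range(copies.get(cid, 1)):
            slots.append((cid, i, HEAD))
            slots.append((cid, i, TAIL))
    link_keys = {frozenset([(l.a, l.a_end), (l.b, l.b_end)]) for l in graph.links}

    def compatible(s1, s2) -> bool:
        return frozenset([(s1[0], s1[2]), (s2[0], s2[2])]) in link_keys

    covers: Set[Tuple] = set()
    n = len(slots)
    matched = [None] * n

    def decompose() -> Tuple:
        pair = {i: matched[i] for i in range(n)}
        seen_copies = set()
        cycles = []
        for i in range(n):
            cid, cp, end = slots[i]
            if (cid, cp) in seen_copies:
                continue
            cycle = []
            cur_copy = (cid, cp)
            enter_end = HEAD
            while cur_copy not in seen_copies:
                seen_copies.add(cur_copy)
                orient = "+" if enter_end == HEAD else "-"
                cycle.append((cur_copy[0], orient))
                exit_end = TAIL if orient == "+" else HEAD
                exit_idx = slots.index((cur_copy[0], cur_copy[1], exit_end))
                nxt_idx = pair[exit_idx]
                ncid, ncp, nend = slots[nxt_idx]
                cur_copy, enter_end = (ncid, ncp), nend
            cycles.append(cycle)
        return canonical_conformation(cycles)

    def backtrack(free: List[int]) -> None:
        if not free:
            covers.add(decompose())
            return
        first = free[0]
        for j in free[1:]:
            if compatible(slots[first], slots[j]):
                matched[first], matched[j] = j, first
                backtrack([x for x in free[1:] if x != j])
                matched[first] = matched[j] = None

    if n:
        backtrack(list(range(n)))
    return covers


def random_conformation_graph(
    rng: random.Random, max_contigs: int = 6, max_total_copies: int = 8
) -> Tuple[AssemblyGraph, Dict[str, int]]:
    """Small random multigraph instance for enumerator/oracle comparison."""
    n = rng.randint(1, max_contigs)
    g = AssemblyGraph()
    ids = [f"u{i}" for i in range(n)]
    for cid in ids:
        g.add_contig(Contig(cid, rng.randint(1, 50), rng.uniform(5, 50)))
    ends = (HEAD, TAIL)
    for _ in range(rng.randint(1, n + 3)):
        a, b = rng.choice(ids), rng.choice(ids)
        g.add_link(a, rng.choice(ends), b, rng.choice(ends), rng.randint(5, 50))
    copies = {}
    total = 0
    for cid in ids:
        c = rng.choices((1, 2, 3), weights=(0.6, 0.3, 0.1))[0]
        c = min(c, max(1, max_total_copies - total))
        copies[cid] = c
        total += c
    return g, copies


# ---------------------------------------------------------------------------
# session fixtures: one small end-to-end run shared by pipeline-level tests
# ---------------------------------------------------------------------------

# sized so the nuclear depth gate (2 x readsize/genomesize ~ 26x) stays below
# the 2-copy repeat depth (~40x) as it does at realistic genome proportions
SMALL_GENOME = dict(
    mito_len=30_000,
    repeat_len=1_500,
    n_genes=4,
    plastid_len=20_000,
    nuclear_n=8,
    nuclear_len=30_000,
)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """Reduced-size planted fixture with reads/db/truth written to disk."""
    from mitograph import io as mio
    from mitograph import synth

    d = tmp_path_factory.mktemp("small_fixture")
    spec = synth.GenomeSpec(**SMALL_GENOME)
    truth = synth.simulate_genomes(spec, seed=42)
    reads = synth.simulate_reads(truth, synth.ReadSimSpec(seed=42))
    mio.write_sequences(reads, d / "reads.fasta")
    mio.write_sequences(truth.pcg_database(), d / "pcg_db.fasta")
    mio.write_sequences([synth.SeqRecord("mito_truth", truth.mito)], d / "mito_truth.fasta")
    return {"dir": d, "truth": truth, "spec": spec, "reads": d / "reads.fasta", "db": d / "pcg_db.fasta"}


@pytest.fixture(scope="session")
def small_run(small_fixture, tmp_path_factory):
    """One autoMito run on the reduced fixture."""
    from mitograph import pipeline

    out = tmp_path_factory.mktemp("small_run")
    cfg = pipeline.RunConfig(
        reads=str(small_fixture["reads"]),
        pcg_db=str(small_fixture["db"]),
        genomesize=small_fixture["truth"].nuclear_genome_size,
        outdir=str(out),
        seed=42,
    )
    res = pipeline.run_automito(cfg)
    return {"cfg": cfg, "res": res, **small_fixture}
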