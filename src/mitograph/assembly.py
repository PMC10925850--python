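"""Contig-graph construction from prepared reads.

A compacted de Bruijn graph over canonical k-mers: maximal non-branching
k-mer paths become contigs, contig depth is the mean multiplicity of the
constituent k-mers, and a link is emitted wherever two contigs are adjacent
through a (k-1)-mer junction, with support equal to the number of read
occurrences spanning the junction.  Repeat-mediated branches are preserved,
never resolved — that contract (branches kept, depths recorded) is what the
downstream simplification and conformation stages rely on.

Blunt-join convention: every contig end that terminates at a junction is
trimmed by (k-1)/2 bases, so the shared (k-1)-mer of a junction is split
half-and-half between the two sides and a walk's sequence is the plain
concatenation of oriented contig sequences.  This makes an exported circular
walk reproduce the underlying genome exactly, with total length equal to the
sum of contig lengths.  ``k`` must be odd for the split to be symmetric, and
at most 31 so a k-mer packs into 64 bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .core import HEAD, TAIL, AssemblyGraph, Contig, MitographError, SeqRecord, revcomp

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


@dataclass
class AssemblyParams:
    """Tunables of the contig-graph engine.

    ``k`` is the k-mer size (odd, 15-31); ``min_kmer_count`` drops k-mers seen
    fewer times, removing singleton sequencing noise before compaction.
    """

    k: int = 31
    min_kmer_count: int = 2
    engine: str = "dbg"

    def __post_init__(self) -> None:
        if not (15 <= self.k <= 31):
            raise MitographError("k must be between 15 and 31")
        if self.k % 2 == 0:
            raise MitographError("k must be odd")
        if self.min_kmer_count < 1:
            raise MitographError("min_kmer_count must be >= 1")
        if self.engine != "dbg":
            raise MitographError(f"unknown assembly engine {self.engine!r}")


def _encode_seq(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(arr: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement codes of every k-window of ``arr``.

    Windows containing a non-ACGT base are dropped.  Codes pack bases 2 bits
    each, most significant first, so the integer order of codes is the
    lexicographic order of the k-mer strings.
    """
    m = len(arr) - k + 1
    if m <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, e
    bad = (arr > 3).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    safe = np.where(arr > 3, 0, arr).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    comp = np.uint64(3) - safe
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | safe[j : j + m]
    for j in range(k - 1, -1, -1):
        rev = (rev << np.uint64(2)) | comp[j : j + m]
    return fwd[valid], rev[valid]


def _count_canonical(reads: Iterable[SeqRecord], k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Sorted unique canonical k-mer codes and their occurrence counts."""
    chunks = []
    for rec in reads:
        fwd, rev = _window_codes(_encode_seq(rec.seq), k)
        if len(fwd):
            chunks.append(np.minimum(fwd, rev))
    if not chunks:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    allc = np.concatenate(chunks)
    return np.unique(allc, return_counts=True)


def _rc_codes_vec(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of packed k-mer codes."""
    x = (~codes).astype(np.uint64)  # complement every 2-bit base
    m2 = np.uint64(0x3333333333333333)
    m4 = np.uint64(0x0F0F0F0F0F0F0F0F)
    x = ((x & m2) << np.uint64(2)) | ((x >> np.uint64(2)) & m2)
    x = ((x & m4) << np.uint64(4)) | ((x >> np.uint64(4)) & m4)
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


class _Unit:
    __slots__ = (
        "first_fw", "first_rc", "last_fw", "last_rc",
        "seq", "depth", "n_kmers", "circular", "min_kmer",
    )

    def __init__(self, first, last, seq, depth, n_kmers, circular, min_kmer):
        self.first_fw, self.first_rc = first
        self.last_fw, self.last_rc = last
        self.seq = seq
        self.depth = depth
        self.n_kmers = n_kmers
        self.circular = circular
        self.min_kmer = min_kmer


def build_contig_graph(reads: List[SeqRecord], params: Optional[AssemblyParams] = None) -> AssemblyGraph:
    """Assemble reads into a contig graph with depths and branch links.

    Raises
    ------
    MitographError
        If ``reads`` is empty or no k-mer survives ``min_kmer_count``.
    """
    if params is None:
        params = AssemblyParams()
    if not reads:
        raise MitographError("cannot assemble an empty read set")
    k = params.k
    codes, counts = _count_canonical(reads, k)
    keep = counts >= params.min_kmer_count
    codes, counts = codes[keep], counts[keep]
    if len(codes) == 0:
        raise MitographError(
            f"no contigs: every k-mer fell below min_kmer_count={params.min_kmer_count}"
        )
    kmer_counts: Dict[int, int] = dict(zip(codes.tolist(), counts.tolist()))
    rc_arr = _rc_codes_vec(codes, k)
    rc_of: Dict[int, int] = dict(zip(codes.tolist(), rc_arr.tolist()))

    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    kmers = kmer_counts  # membership dict

    def fwd_neighbors(fw: int, rc: int) -> List[Tuple[int, int]]:
        out = []
        base = (fw << 2) & mask
        rshift = rc >> 2
        for b in range(4):
            nfw = base | b
            nrc = rshift | ((3 - b) << shift)
            if (nfw if nfw <= nrc else nrc) in kmers:
                out.append((nfw, nrc))
        return out

    def bwd_neighbors(fw: int, rc: int) -> List[Tuple[int, int]]:
        out = []
        fshift = fw >> 2
        base = (rc << 2) & mask
        for b in range(4):
            pfw = fshift | (b << shift)
            prc = base | (3 - b)
            if (pfw if pfw <= prc else prc) in kmers:
                out.append((pfw, prc))
        return out

    # --- compact maximal non-branching paths -------------------------------
    visited = set()
    units: List[_Unit] = []
    for c in codes.tolist():
        if c in visited:
            continue
        start = (c, rc_of[c])
        path = [start]
        path_can = {c}
        circular = False
        cur = start
        while True:
            ns = fwd_neighbors(*cur)
            if len(ns) != 1:
                break
            n = ns[0]
            if len(bwd_neighbors(*n)) != 1:
                break
            ncan = n[0] if n[0] <= n[1] else n[1]
            if ncan == c:
                circular = n[0] == path[0][0]
                break
            if ncan in path_can or ncan in visited:
                break
            path.append(n)
            path_can.add(ncan)
            cur = n
        if not circular:
            cur = path[0]
            left: List[Tuple[int, int]] = []
            while True:
                ps = bwd_neighbors(*cur)
                if len(ps) != 1:
                    break
                p = ps[0]
                if len(fwd_neighbors(*p)) != 1:
                    break
                pcan = p[0] if p[0] <= p[1] else p[1]
                if pcan in path_can or pcan in visited:
                    break
                left.append(p)
                path_can.add(pcan)
                cur = p
            if left:
                left.reverse()
                path = left + path
        visited.update(path_can)
        seq_parts = [_decode(path[0][0], k)]
        seq_parts.extend(_BASES[p[0] & 3] for p in path[1:])
        seq = "".join(seq_parts)
        depth = sum(kmers[p[0] if p[0] <= p[1] else p[1]] for p in path) / len(path)
        units.append(
            _Unit(path[0], path[-1], seq, depth, len(path), circular, min(path_can))
        )

    # --- adjacency through (k-1)-mer junctions ------------------------------
    head_entry: Dict[int, int] = {}
    tail_entry: Dict[int, int] = {}
    for uid, u in enumerate(units):
        head_entry[u.first_fw] = uid
        tail_entry[u.last_rc] = uid

    def locate(code: int) -> Optional[Tuple[int, str]]:
        uid = head_entry.get(code)
        if uid is not None:
            return uid, HEAD
        uid = tail_entry.get(code)
        if uid is not None:
            return uid, TAIL
        return None

    k1 = k + 1
    raw_links: Dict[Tuple[Tuple[int, str], Tuple[int, str]], int] = {}
    junction_codes: Dict[Tuple[Tuple[int, str], Tuple[int, str]], int] = {}
    for uid, u in enumerate(units):
        for exit_end, (efw, erc) in ((TAIL, (u.last_fw, u.last_rc)), (HEAD, (u.first_rc, u.first_fw))):
            for nfw, nrc in fwd_neighbors(efw, erc):
                hit = locate(nfw)
                if hit is None:
                    continue  # mid-unitig adjacency cannot occur; defensive
                vid, ventry = hit
                j_fw = (efw << 2) | (nfw & 3)
                j_rc = ((3 - (nfw & 3)) << (2 * k)) | erc
                jcode = j_fw if j_fw <= j_rc else j_rc
                slot_a, slot_b = (uid, exit_end), (vid, ventry)
                key = (slot_a, slot_b) if slot_a <= slot_b else (slot_b, slot_a)
                raw_links[key] = 0
                junction_codes[key] = jcode

    if raw_links:
        k1_codes, k1_counts = _count_canonical(reads, k1)
        k1_map = dict(zip(k1_codes.tolist(), k1_counts.tolist()))
        for key, jcode in junction_codes.items():
            raw_links[key] = int(k1_map.get(jcode, 0))

    # --- blunt trimming, strand canonicalisation, naming --------------------
    half = (k - 1) // 2
    linked_ends = set()
    for (sa, sb) in raw_links:
        linked_ends.add(sa)
        linked_ends.add(sb)

    blunt: Dict[int, str] = {}
    flipped: Dict[int, bool] = {}
    for uid, u in enumerate(units):
        if u.circular:
            s = u.seq[: u.n_kmers]
        else:
            lo = half if (uid, HEAD) in linked_ends else 0
            hi = len(u.seq) - (half if (uid, TAIL) in linked_ends else 0)
            s = u.seq[lo:hi]
        rc = revcomp(s)
        if rc < s:
            blunt[uid] = rc
            flipped[uid] = True
        else:
            blunt[uid] = s
            flipped[uid] = False

    order = sorted(range(len(units)), key=lambda uid: (units[uid].min_kmer, blunt[uid]))
    width = len(str(len(units)))
    names = {uid: f"ctg{i + 1:0{width}d}" for i, uid in enumerate(order)}

    graph = AssemblyGraph()
    for uid in order:
        u = units[uid]
        graph.add_contig(Contig(names[uid], len(blunt[uid]), u.depth, blunt[uid]))
    swap = {HEAD: TAIL, TAIL: HEAD}
    for ((ua, ea), (ub, eb)), support in raw_links.items():
        ea2 = swap[ea] if flipped[ua] else ea
        eb2 = swap[eb] if flipped[ub] else eb
        graph.add_link(names[ua], ea2, names[ub], eb2, support)
    logger.info(
        "assembled %d contigs, %d links from %d surviving k-mers",
        graph.n_contigs, graph.n_links, len(kmer_counts),
    )
    return graph
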