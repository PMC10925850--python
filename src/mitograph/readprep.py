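"""Read preparation: subsampling to a base budget and long-read fragmentation.

Long accurate reads above a length threshold (default 30 kb) are broken into
consecutive blunt pieces of a fixed step (default 20 kb) before contig-graph
construction; a trailing sliver shorter than ``min_tail`` is appended to the
previous piece instead of standing alone.  Subsampling draws whole reads
uniformly without replacement until a target base volume is reached, the way
coverage titrations sample a fixed data mass from a sequencing run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .core import MitographError, SeqRecord


@dataclass
class SamplingSpec:
    """Target base volume and RNG seed for read subsampling."""

    target_bases: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_bases < 1:
            raise MitographError("target_bases must be >= 1")


@dataclass
class FragmentationSpec:
    """Length threshold, cut step and minimum tail for read fragmentation."""

    threshold: int = 30_000
    step: int = 20_000
    min_tail: int = 1_000

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.step <= 0 or self.min_tail <= 0:
            raise MitographError("fragmentation parameters must be positive")
        if self.step > self.threshold:
            raise MitographError("step must not exceed threshold")
        if self.min_tail >= self.step:
            raise MitographError("min_tail must be smaller than step")


def subsample_reads(reads: List[SeqRecord], spec: SamplingSpec) -> List[SeqRecord]:
    """Uniformly sample whole reads until ``target_bases`` is reached.

    Reads are shuffled by a seeded RNG over the id-sorted read set, so the
    selection depends on the seed and the read ids but not on input order.
    The last selected read may overshoot the target; if the target is at or
    above the total base count, all reads are returned unchanged.
    """
    if not reads:
        raise MitographError("cannot subsample an empty read set")
    total = sum(len(r) for r in reads)
    if spec.target_bases >= total:
        return list(reads)
    ordered = sorted(reads, key=lambda r: r.id)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(ordered))
    out: List[SeqRecord] = []
    acc = 0
    for idx in perm:
        rec = ordered[idx]
        out.append(rec)
        acc += len(rec)
        if acc >= spec.target_bases:
            break
    return out


def fragment_long_reads(reads: List[SeqRecord], spec: FragmentationSpec) -> List[SeqRecord]:
    """Cut reads longer than ``threshold`` into blunt ``step``-sized pieces.

    Pieces are consecutive and non-overlapping, so the concatenation of a
    read's pieces reproduces the read exactly and total bases are conserved.
    A final remainder shorter than ``min_tail`` is appended to the previous
    piece.  Piece ids are suffixed ``/1``, ``/2``, ...
    """
    out: List[SeqRecord] = []
    for rec in reads:
        n = len(rec)
        if n <= spec.threshold:
            out.append(rec)
            continue
        starts = list(range(0, n, spec.step))
        if len(starts) > 1 and n - starts[-1] < spec.min_tail:
            starts.pop()
        bounds = starts[1:] + [n]
        prev = 0
        for i, end in enumerate(bounds, 1):
            qual = rec.qual[prev:end] if rec.qual is not None else None
            out.append(SeqRecord(f"{rec.id}/{i}", rec.seq[prev:end], qual))
            prev = end
    return out
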