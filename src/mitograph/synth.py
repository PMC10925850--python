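"""Synthetic planted genomes and simulated long accurate reads.

The generator emulates the mixture a whole-genome long-read run presents to
an organelle assembler: a circular mitogenome carrying conserved
protein-coding genes, one exact repeat pair (direct or inverted) and one
plastid-derived insertion (MTPT); a circular plastome at much higher depth;
and a linear nuclear background at low depth.  Every stage of the pipeline
can therefore be tested hermetically against planted truth.

Defaults: 60 kb mitogenome with one 2 kb direct repeat (two copies), four
planted 800 bp genes and a 1 kb MTPT shared exactly with the 30 kb plastome;
ten 50 kb nuclear sequences.  Read depths 2x nuclear / 20x mito / 100x
plastid with HiFi-like lengths (12 +/- 3 kb, min 1 kb) and substitution-only
errors (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import MitographError, SeqRecord, revcomp
from .seeds import CORE_MT_PCGS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeSpec:
    """Planted-genome layout parameters."""

    mito_len: int = 60_000
    repeat_len: int = 2_000
    repeat_orientation: str = "direct"  # or "inverted"
    n_genes: int = 4
    gene_len: int = 800
    mtpt_len: int = 1_000
    plastid_len: int = 30_000
    nuclear_n: int = 10
    nuclear_len: int = 50_000

    def __post_init__(self) -> None:
        if self.mito_len < 20_000:
            raise MitographError("mito_len must be >= 20 kb")
        if self.repeat_len >= self.mito_len / 4:
            raise MitographError("repeat unit must be shorter than mito_len / 4")
        if self.repeat_orientation not in ("direct", "inverted"):
            raise MitographError("repeat_orientation must be 'direct' or 'inverted'")
        if self.gene_len < 600:
            raise MitographError("planted genes must be >= 600 bp")
        if self.n_genes < 1 or self.n_genes > len(CORE_MT_PCGS):
            raise MitographError(f"n_genes must be in [1, {len(CORE_MT_PCGS)}]")
        if self.mtpt_len >= self.plastid_len:
            raise MitographError("MTPT must be shorter than the plastome")


@dataclass
class GenomeTruth:
    """Planted genomes plus the intervals needed to verify recovery."""

    mito: str
    plastid: str
    nuclear: List[str]
    gene_intervals: Dict[str, Tuple[int, int]]   # gene id -> [start, end) on mito
    repeat_intervals: List[Tuple[int, int, str]]  # (start, end, orientation)
    mtpt_interval: Tuple[int, int]
    expected_conformations: int
    genes: Dict[str, str] = field(default_factory=dict)

    def pcg_database(self) -> List[SeqRecord]:
        """The planted genes as a conserved-PCG database."""
        return [SeqRecord(gid, seq) for gid, seq in self.genes.items()]

    @property
    def nuclear_genome_size(self) -> int:
        return sum(len(s) for s in self.nuclear)


@dataclass
class ReadSimSpec:
    """Read-simulation parameters: per-source depths, lengths, error rate."""

    nuclear_depth: float = 2.0
    mito_depth: float = 20.0
    plastid_depth: float = 100.0
    read_len_mean: float = 12_000.0
    read_len_sd: float = 3_000.0
    read_len_min: int = 1_000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nuclear_depth, self.mito_depth, self.plastid_depth) <= 0:
            raise MitographError("all depths must be positive")
        if not (0 <= self.error_rate <= 0.02):
            raise MitographError("error_rate must be in [0, 0.02]")
        if self.read_len_min < 1 or self.read_len_mean <= 0 or self.read_len_sd < 0:
            raise MitographError("invalid read-length parameters")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def simulate_genomes(spec: Optional[GenomeSpec] = None, seed: int = 0) -> GenomeTruth:
    """Build the planted genome set, deterministically for a given seed.

    Mito layout (circular): ``arm1 . R . arm2 . R'`` where ``R' = R`` for a
    direct repeat and ``revcomp(R)`` for an inverted one.  Arm 1 carries half
    of the genes and the MTPT; arm 2 the remaining genes.  Planted segments
    keep a margin from every junction so gene hits survive blunt trimming.
    """
    spec = spec or GenomeSpec()
    rng = np.random.default_rng(seed)
    repeat = _random_seq(rng, spec.repeat_len)
    mtpt = _random_seq(rng, spec.mtpt_len)
    gene_ids = list(CORE_MT_PCGS[: spec.n_genes])
    genes = {gid: _random_seq(rng, spec.gene_len) for gid in gene_ids}

    arm_total = spec.mito_len - 2 * spec.repeat_len
    arm1_len = arm_total // 2
    arm2_len = arm_total - arm1_len
    n1 = (spec.n_genes + 1) // 2
    arm1_genes, arm2_genes = gene_ids[:n1], gene_ids[n1:]

    margin = 200

    def build_arm(length: int, inserts: List[Tuple[str, str]]) -> Tuple[str, List[Tuple[str, int, int]]]:
        insert_total = sum(len(s) for _, s in inserts)
        filler_total = length - insert_total
        n_gaps = len(inserts) + 1
        if filler_total < n_gaps * margin:
            raise MitographError("arm too short for the requested inserts")
        cuts = np.sort(rng.integers(0, filler_total - n_gaps * margin + 1, size=n_gaps - 1))
        gap_sizes = np.diff(np.concatenate(([0], cuts, [filler_total - n_gaps * margin]))) + margin
        parts: List[str] = []
        placed: List[Tuple[str, int, int]] = []
        pos = 0
        for gap, (name, seq) in zip(gap_sizes[:-1], inserts):
            parts.append(_random_seq(rng, int(gap)))
            pos += int(gap)
            parts.append(seq)
            placed.append((name, pos, pos + len(seq)))
            pos += len(seq)
        parts.append(_random_seq(rng, int(gap_sizes[-1])))
        return "".join(parts), placed

    inserts1 = [(g, genes[g]) for g in arm1_genes[: len(arm1_genes) // 2 + len(arm1_genes) % 2]]
    inserts1.append(("MTPT", mtpt))
    inserts1.extend((g, genes[g]) for g in arm1_genes[len(arm1_genes) // 2 + len(arm1_genes) % 2:])
    arm1, placed1 = build_arm(arm1_len, inserts1)
    arm2, placed2 = build_arm(arm2_len, [(g, genes[g]) for g in arm2_genes])

    second = repeat if spec.repeat_orientation == "direct" else revcomp(repeat)
    mito = arm1 + repeat + arm2 + second
    assert len(mito) == spec.mito_len

    gene_intervals: Dict[str, Tuple[int, int]] = {}
    mtpt_interval = (0, 0)
    for name, s, e in placed1:
        if name == "MTPT":
            mtpt_interval = (s, e)
        else:
            gene_intervals[name] = (s, e)
    off = arm1_len + spec.repeat_len
    for name, s, e in placed2:
        gene_intervals[name] = (s + off, e + off)
    repeat_intervals = [
        (arm1_len, arm1_len + spec.repeat_len, "forward"),
        (
            arm1_len + spec.repeat_len + arm2_len,
            spec.mito_len,
            "forward" if spec.repeat_orientation == "direct" else "reverse",
        ),
    ]

    # plastome: random backbone with the exact MTPT segment inserted mid-way
    p_fill = spec.plastid_len - spec.mtpt_len
    p_left = p_fill // 2
    plastid = _random_seq(rng, p_left) + mtpt + _random_seq(rng, p_fill - p_left)

    nuclear = [_random_seq(rng, spec.nuclear_len) for _ in range(spec.nuclear_n)]

    # one repeat pair gives exactly two conformations: for a direct repeat
    # the master circle plus the two-subcircle decomposition, for an
    # inverted repeat the two single-circle isomers
    expected = 2 if spec.repeat_len > 0 else 1

    return GenomeTruth(
        mito=mito,
        plastid=plastid,
        nuclear=nuclear,
        gene_intervals=gene_intervals,
        repeat_intervals=repeat_intervals,
        mtpt_interval=mtpt_interval,
        expected_conformations=expected,
        genes=genes,
    )


def _reads_from_source(
    rng: np.random.Generator,
    err_rng: np.random.Generator,
    name: str,
    seq: str,
    circular: bool,
    depth: float,
    spec: ReadSimSpec,
) -> List[SeqRecord]:
    # errors are drawn from a separate stream so the planted read structure
    # (lengths, positions, strands) is identical across error rates
    target = depth * len(seq)
    out: List[SeqRecord] = []
    acc = 0
    i = 0
    err = spec.error_rate
    while acc < target:
        length = int(rng.normal(spec.read_len_mean, spec.read_len_sd))
        length = max(spec.read_len_min, min(length, len(seq)))
        if circular:
            start = int(rng.integers(0, len(seq)))
            read = (seq + seq)[start : start + length]
        else:
            start = int(rng.integers(0, len(seq) - length + 1))
            read = seq[start : start + length]
        if err > 0:
            arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
            hit = np.nonzero(err_rng.random(len(arr)) < err)[0]
            if len(hit):
                # substitute with a different base: shift by 1-3 in base order
                base_idx = np.searchsorted(_BASES, arr[hit])
                arr[hit] = _BASES[(base_idx + err_rng.integers(1, 4, size=len(hit))) % 4]
                read = arr.tobytes().decode("ascii")
        if rng.random() < 0.5:
            read = revcomp(read)
        i += 1
        out.append(SeqRecord(f"{name}_r{i}", read))
        acc += len(read)
    return out


def simulate_reads(truth: GenomeTruth, spec: Optional[ReadSimSpec] = None) -> List[SeqRecord]:
    """Draw reads from every source at its depth; deterministic per seed."""
    spec = spec or ReadSimSpec()
    rng = np.random.default_rng(spec.seed)
    err_rng = np.random.default_rng((spec.seed, 1))
    reads: List[SeqRecord] = []
    reads += _reads_from_source(rng, err_rng, "mito", truth.mito, True, spec.mito_depth, spec)
    reads += _reads_from_source(rng, err_rng, "plastid", truth.plastid, True, spec.plastid_depth, spec)
    for j, chrom in enumerate(truth.nuclear, 1):
        reads += _reads_from_source(rng, err_rng, f"nuc{j}", chrom, False, spec.nuclear_depth, spec)
    return reads


def rotations_equal(a: str, b: str) -> bool:
    """True when circular sequences ``a`` and ``b`` are equal up to rotation
    and strand."""
    if len(a) != len(b):
        return False
    double = b + b
    return a in double or revcomp(a) in double
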