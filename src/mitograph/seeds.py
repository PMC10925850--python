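"""Seed contig selection from conserved organelle protein-coding genes.

Contigs are screened against a user-supplied (or synthetic) database of
conserved mitochondrial protein-coding genes (PCGs).  A hit records percent
identity and the fraction of the *gene* covered by the alignment; contigs
pass the seed gate when they carry at least one hit with contig length
> 500 bp, identity > 85% and gene coverage > 90% (strict inequalities, all
configurable).  Coverage is measured on the gene because contigs are
typically far longer than a single gene.

The search itself is a hermetic seed-and-extend aligner: exact word anchors
on both strands, diagonal clustering, then a global alignment of the
clustered span (edlib) to score identity.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import edlib

from .core import Contig, MitographError, SeqRecord, revcomp

#: The 24 conserved plant mitochondrial PCGs used to gate seed contigs.
CORE_MT_PCGS = (
    "atp1", "atp4", "atp6", "atp8", "atp9",
    "ccmB", "ccmC", "ccmFc", "ccmFn",
    "cob", "cox1", "cox2", "cox3",
    "matR", "mttB",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
)

#: Conserved plastid genes accepted when running in plastome (``pt``) mode.
CORE_PT_GENES = (
    "atpA", "atpB", "matK", "ndhF", "psaA", "psaB", "psbA", "psbB",
    "rbcL", "rpoB", "rpoC1", "rpoC2", "rrn16", "rrn23",
)

ANCHOR_WORD = 15
DIAG_BAND = 100
REPORT_MIN_IDENTITY = 50.0
REPORT_MIN_LEN = 100


@dataclass
class SeedHit:
    """Best local match of a contig to one conserved gene."""

    contig_id: str
    gene_id: str
    identity: float      # percent, matches / alignment columns
    gene_coverage: float  # percent of the gene spanned by the alignment
    aln_len: int          # alignment columns

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100) or not (0 <= self.gene_coverage <= 100):
            raise MitographError("identity and coverage must be percentages")


@dataclass
class SeedThresholds:
    """Seed gates: contig length, identity and gene coverage (all strict)."""

    min_len: int = 500
    min_identity: float = 85.0
    min_coverage: float = 90.0

    def __post_init__(self) -> None:
        if self.min_len <= 0 or self.min_identity <= 0 or self.min_coverage <= 0:
            raise MitographError("seed thresholds must be positive")


def _word_index(seq: str, w: int) -> Dict[str, List[int]]:
    idx: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(seq) - w + 1):
        idx[seq[i : i + w]].append(i)
    return idx


_CIG_RE = re.compile(r"(\d+)([MIDX=])")


def _identity_from_alignment(query: str, target: str) -> Tuple[float, int]:
    """Percent identity and column count of a global query/target alignment."""
    res = edlib.align(query, target, mode="NW", task="path")
    dist = res["editDistance"]
    cols = m_cols = 0
    for n, op in _CIG_RE.findall(res["cigar"] or ""):
        n = int(n)
        cols += n
        if op in "M=":
            m_cols += n
    indels = cols - m_cols
    subs = dist - indels
    matches = m_cols - subs
    if cols == 0:
        return 0.0, 0
    return 100.0 * matches / cols, cols


def _best_strand_hit(contig_seq: str, gene_seq: str) -> Optional[Tuple[float, float, int]]:
    """(identity, gene_coverage, aln_len) of the best anchored match, or None."""
    glen = len(gene_seq)
    best: Optional[Tuple[float, float, int]] = None
    for gseq in (gene_seq, revcomp(gene_seq)):
        if glen < ANCHOR_WORD or len(contig_seq) < ANCHOR_WORD:
            continue
        gidx = _word_index(gseq, ANCHOR_WORD)
        clusters: Dict[int, List[Tuple[int, int]]] = defaultdict(list)
        for c in range(len(contig_seq) - ANCHOR_WORD + 1):
            word = contig_seq[c : c + ANCHOR_WORD]
            for g in gidx.get(word, ()):
                clusters[(c - g) // DIAG_BAND].append((c, g))
        if not clusters:
            continue
        # merge adjacent diagonal buckets so a single indel cannot split a hit
        merged: Dict[int, List[Tuple[int, int]]] = {}
        for d in sorted(clusters):
            if d - 1 in merged:
                merged[d - 1].extend(clusters[d])
                merged[d] = merged[d - 1]
            else:
                merged[d] = list(clusters[d])
        seen = set()
        for anchors in merged.values():
            key = id(anchors)
            if key in seen:
                continue
            seen.add(key)
            g0 = min(a[1] for a in anchors)
            g1 = max(a[1] for a in anchors) + ANCHOR_WORD
            c0 = min(a[0] for a in anchors)
            c1 = max(a[0] for a in anchors) + ANCHOR_WORD
            identity, cols = _identity_from_alignment(gseq[g0:g1], contig_seq[c0:c1])
            coverage = 100.0 * (g1 - g0) / glen
            cand = (identity, coverage, cols)
            if best is None or (cand[0] * cand[1]) > (best[0] * best[1]):
                best = cand
    return best


def search_pcg_hits(contigs: Sequence[Contig], pcg_db: Sequence[SeqRecord]) -> List[SeedHit]:
    """Best hit per contig x gene pair, both strands.

    A pair is reported when its best anchored alignment reaches at least
    50% identity over at least 100 columns.

    Raises
    ------
    MitographError
        If the gene database is empty or a contig carries no sequence.
    """
    if not pcg_db:
        raise MitographError("the PCG database is empty")
    hits: List[SeedHit] = []
    for contig in contigs:
        if contig.seq is None:
            raise MitographError(f"contig {contig.id!r} carries no sequence")
        for gene in pcg_db:
            found = _best_strand_hit(contig.seq, gene.seq)
            if found is None:
                continue
            identity, coverage, cols = found
            if identity >= REPORT_MIN_IDENTITY and cols >= REPORT_MIN_LEN:
                hits.append(SeedHit(contig.id, gene.id, identity, coverage, cols))
    return hits


def filter_candidate_seeds(
    hits: Iterable[SeedHit],
    contigs: Dict[str, Contig],
    thresholds: Optional[SeedThresholds] = None,
) -> Set[str]:
    """Contig ids with >= 1 hit passing all three strict seed gates."""
    th = thresholds or SeedThresholds()
    out: Set[str] = set()
    for hit in hits:
        contig = contigs.get(hit.contig_id)
        if contig is None:
            raise MitographError(f"hit references unknown contig {hit.contig_id!r}")
        if (
            contig.length > th.min_len
            and hit.identity > th.min_identity
            and hit.gene_coverage > th.min_coverage
        ):
            out.add(hit.contig_id)
    return out


def validate_gene_names(pcg_db: Sequence[SeqRecord], genome_type: str = "mt") -> List[str]:
    """Names in the database absent from the conserved-gene manifest.

    Purely advisory: unknown names are legal (the database is user-supplied)
    but usually indicate the wrong ``--type`` was chosen.
    """
    manifest = CORE_MT_PCGS if genome_type == "mt" else CORE_PT_GENES
    known = {m.lower() for m in manifest}
    return [rec.id for rec in pcg_db if rec.id.split("_")[0].lower() not in known]
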