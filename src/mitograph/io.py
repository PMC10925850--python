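"""On-disk formats: FASTA/FASTQ reads, the contig-table dialect, and GFA 1.0.

Contig-table dialect (tab separated)::

    C  <id>  <length>  <depth>
    L  <id1> <head|tail> <id2> <head|tail> <support>

The table carries graph topology and depths; contig sequences travel in a
companion FASTA whose ids must match the ``C`` rows.  The dialect is this
package's own documented exchange format for externally built contig graphs.

GFA conventions: one ``S`` line per contig with its sequence, an ``LN:i:``
length tag and a ``dp:f:`` depth tag; one ``L`` line per link with a ``0M``
overlap (contigs abut bluntly, so an exported walk length is the plain sum of
contig lengths).  Orientation mapping: leaving a contig through its *tail* is
``+`` on the left side of an ``L`` line, entering a contig through its *head*
is ``+`` on the right side.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, List, Optional, TextIO, Tuple, Union

from Bio import SeqIO

from .core import (
    HEAD,
    TAIL,
    AssemblyGraph,
    Contig,
    MitographError,
    ParseError,
    SeqRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    suffix = Path(name).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna", ".ffn", ".frn"}:
        return "fasta"
    # fall back to content sniffing
    with _open_text(path) as fh:
        first = fh.readline().lstrip()
    if first.startswith("@"):
        return "fastq"
    return "fasta"


def read_sequences(path: PathLike, format: str = "auto") -> List[SeqRecord]:
    """Read FASTA or FASTQ records (gzip transparent), in file order.

    Duplicate ids are suffixed deterministically (``.2``, ``.3``, ...) so the
    returned ids are unique.

    Raises
    ------
    MitographError
        If the file holds no sequences.
    ParseError
        On malformed records, with a line number when determinable.
    """
    path = Path(path)
    if not path.exists():
        raise MitographError(f"no such file: {path}")
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt not in {"fasta", "fastq"}:
        raise MitographError(f"unknown sequence format {fmt!r}")
    records: List[SeqRecord] = []
    seen: dict = {}
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, fmt):
                rid = rec.id
                if rid in seen:
                    seen[rid] += 1
                    rid = f"{rid}.{seen[rec.id]}"
                else:
                    seen[rid] = 1
                qual = None
                if fmt == "fastq":
                    quals = rec.letter_annotations.get("phred_quality")
                    if quals is not None:
                        qual = "".join(chr(q + 33) for q in quals)
                records.append(SeqRecord(rid, str(rec.seq).upper(), qual))
    except ValueError as exc:  # Biopython parse failure
        raise ParseError(f"malformed {fmt} in {path}: {exc}") from exc
    if not records:
        raise MitographError(f"no sequences found in {path}")
    return records


def write_sequences(records: Iterable[SeqRecord], path: PathLike, format: str = "fasta") -> None:
    """Write records as FASTA (or FASTQ when qualities are present)."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            if format == "fastq":
                qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
            else:
                fh.write(f">{rec.id}\n{rec.seq}\n")


# ---------------------------------------------------------------------------
# contig-table dialect
# ---------------------------------------------------------------------------

def write_contig_table(graph: AssemblyGraph, table_path: PathLike, fasta_path: Optional[PathLike] = None) -> None:
    """Write a graph as C/L rows plus an optional companion contig FASTA."""
    with _open_text(table_path, "wt") as fh:
        for cid in sorted(graph.contigs):
            c = graph.contigs[cid]
            fh.write(f"C\t{c.id}\t{c.length}\t{c.depth!r}\n")
        for l in sorted(graph.links, key=lambda l: (l.a, l.a_end, l.b, l.b_end)):
            fh.write(f"L\t{l.a}\t{l.a_end}\t{l.b}\t{l.b_end}\t{l.support}\n")
    if fasta_path is not None:
        with _open_text(fasta_path, "wt") as fh:
            for cid in sorted(graph.contigs):
                c = graph.contigs[cid]
                if c.seq is None:
                    raise MitographError(f"contig {cid!r} has no sequence to export")
                fh.write(f">{c.id}\n{c.seq}\n")


def read_contig_table(table_path: PathLike, fasta_path: Optional[PathLike] = None) -> AssemblyGraph:
    """Parse the contig-table dialect into an :class:`AssemblyGraph`.

    When ``fasta_path`` is given every ``C`` row must have a matching FASTA
    record whose length equals the declared contig length; extra FASTA
    records are ignored with a warning.
    """
    seqs = {}
    if fasta_path is not None:
        for rec in read_sequences(fasta_path, "fasta"):
            seqs[rec.id] = rec.seq
    graph = AssemblyGraph()
    pending_links: List[Tuple[int, Tuple[str, str, str, str, int]]] = []
    with _open_text(table_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "C":
                if len(fields) != 4:
                    raise ParseError("C row needs: C <id> <length> <depth>", lineno)
                cid = fields[1]
                try:
                    length = int(fields[2])
                    depth = float(fields[3])
                except ValueError as exc:
                    raise ParseError(f"bad C row numbers: {exc}", lineno) from exc
                seq = seqs.get(cid)
                if fasta_path is not None and seq is None:
                    raise ParseError(f"contig {cid!r} missing from FASTA", lineno)
                if seq is not None and len(seq) != length:
                    raise ParseError(
                        f"contig {cid!r}: FASTA length {len(seq)} != table length {length}",
                        lineno,
                    )
                try:
                    graph.add_contig(Contig(cid, length, depth, seq))
                except MitographError as exc:
                    raise ParseError(str(exc), lineno) from exc
            elif kind == "L":
                if len(fields) != 6:
                    raise ParseError(
                        "L row needs: L <id1> <end1> <id2> <end2> <support>", lineno
                    )
                try:
                    support = int(fields[5])
                except ValueError as exc:
                    raise ParseError(f"bad L row support: {exc}", lineno) from exc
                pending_links.append((lineno, (fields[1], fields[2], fields[3], fields[4], support)))
            else:
                raise ParseError(f"unknown row type {kind!r}", lineno)
    for lineno, (a, a_end, b, b_end, support) in pending_links:
        for cid in (a, b):
            if cid not in graph.contigs:
                raise ParseError(f"L row references unknown contig {cid!r}", lineno)
        try:
            graph.add_link(a, a_end, b, b_end, support)
        except MitographError as exc:
            raise ParseError(str(exc), lineno) from exc
    unused = seqs.keys() - graph.contigs.keys()
    if unused:
        logger.warning("%d FASTA records without C rows ignored", len(unused))
    return graph


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------

def _gfa_left(end: str) -> str:
    # leaving through the tail keeps the stored strand
    return "+" if end == TAIL else "-"


def _gfa_right(end: str) -> str:
    # entering through the head keeps the stored strand
    return "+" if end == HEAD else "-"


def write_gfa(graph: AssemblyGraph, path: PathLike) -> None:
    """Write a graph as GFA 1.0 with blunt (``0M``) links and depth tags."""
    with _open_text(path, "wt") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for cid in sorted(graph.contigs):
            c = graph.contigs[cid]
            if c.seq is None:
                raise MitographError(f"contig {cid!r} has no sequence; cannot write GFA S line")
            fh.write(f"S\t{c.id}\t{c.seq}\tLN:i:{c.length}\tdp:f:{c.depth!r}\n")
        for l in sorted(graph.links, key=lambda l: (l.a, l.a_end, l.b, l.b_end)):
            fh.write(
                f"L\t{l.a}\t{_gfa_left(l.a_end)}\t{l.b}\t{_gfa_right(l.b_end)}"
                f"\t0M\tRC:i:{l.support}\n"
            )


def read_gfa(path: PathLike) -> AssemblyGraph:
    """Parse GFA 1.0 S/L lines; other record types are ignored with a warning."""
    graph = AssemblyGraph()
    pending: List[Tuple[int, Tuple[str, str, str, str, int]]] = []
    ignored = set()
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "H":
                continue
            if kind == "S":
                if len(fields) < 3:
                    raise ParseError("S line needs a name and a sequence", lineno)
                name, seq = fields[1], fields[2]
                if seq == "*" or not seq:
                    raise ParseError(f"S line for {name!r} carries no sequence", lineno)
                depth = 1.0
                length = len(seq)
                for tag in fields[3:]:
                    if tag.startswith("dp:f:"):
                        depth = float(tag[5:])
                    elif tag.startswith("LN:i:"):
                        length = int(tag[5:])
                if length != len(seq):
                    raise ParseError(
                        f"S line for {name!r}: LN tag {length} != sequence length {len(seq)}",
                        lineno,
                    )
                try:
                    graph.add_contig(Contig(name, length, depth, seq.upper()))
                except MitographError as exc:
                    raise ParseError(str(exc), lineno) from exc
            elif kind == "L":
                if len(fields) < 6:
                    raise ParseError("L line needs from/to segments and orientations", lineno)
                a, ao, b, bo = fields[1], fields[2], fields[3], fields[4]
                if ao not in "+-" or bo not in "+-":
                    raise ParseError("L line orientations must be + or -", lineno)
                support = 0
                for tag in fields[6:]:
                    if tag.startswith("RC:i:"):
                        support = int(tag[5:])
                a_end = TAIL if ao == "+" else HEAD
                b_end = HEAD if bo == "+" else TAIL
                pending.append((lineno, (a, a_end, b, b_end, support)))
            else:
                ignored.add(kind)
    for lineno, (a, a_end, b, b_end, support) in pending:
        for cid in (a, b):
            if cid not in graph.contigs:
                raise ParseError(f"L line references unknown segment {cid!r}", lineno)
        graph.add_link(a, a_end, b, b_end, support)
    if ignored:
        logger.warning("ignored GFA record types: %s", ", ".join(sorted(ignored)))
    return graph
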