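"""Core containers for organelle assembly graphs.

The central structure is the :class:`AssemblyGraph`: contigs (nodes carrying a
length, a read depth in x-coverage, and optionally a sequence) joined by
:class:`Link` objects between *oriented contig ends*.  ``head`` is the 5' end
of the stored strand, ``tail`` the 3' end; all coordinates are 0-based
half-open.  A link records how many reads span the junction.

Links are undirected junctions between two end slots, so a link is stored in a
canonical slot order and compares equal to its own end-swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

HEAD = "head"
TAIL = "tail"
_ENDS = (HEAD, TAIL)
OPPOSITE_END = {HEAD: TAIL, TAIL: HEAD}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MitographError(Exception):
    """Base class for all toolkit errors."""


class ParseError(MitographError):
    """Malformed on-disk input; carries a line number when known."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GraphError(MitographError):
    """Violation of an assembly-graph invariant."""


class NoSeedsError(MitographError):
    """No seed contig could be selected; manual seeding is required."""


@dataclass
class SeqRecord:
    """A sequencing read or reference sequence.

    Parameters
    ----------
    id : str
        Record identifier (unique within a file after deduplication).
    seq : str
        Sequence over ``{A, C, G, T, N}``.
    qual : str, optional
        Per-base quality string; must match ``seq`` in length.
    """

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise MitographError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise MitographError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Contig:
    """An assembled contig: a node of the assembly graph."""

    id: str
    length: int
    depth: float
    seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GraphError(f"contig {self.id!r}: length must be positive")
        if self.depth <= 0:
            raise GraphError(f"contig {self.id!r}: depth must be positive")
        if self.seq is not None and len(self.seq) != self.length:
            raise GraphError(
                f"contig {self.id!r}: sequence length {len(self.seq)} != "
                f"declared length {self.length}"
            )


@dataclass(frozen=True)
class Link:
    """A junction between two oriented contig ends.

    The two slots are interchangeable: ``Link('a', TAIL, 'b', HEAD)`` equals
    ``Link('b', HEAD, 'a', TAIL)`` because construction normalises slot order.
    ``support`` is the number of reads observed to span the junction; it does
    not participate in identity so a junction exists at most once per graph.
    """

    a: str
    a_end: str
    b: str
    b_end: str
    support: int = field(default=0, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.a_end not in _ENDS or self.b_end not in _ENDS:
            raise GraphError(f"invalid link end in {self}")
        if self.support < 0:
            raise GraphError("link support must be non-negative")
        if (self.b, self.b_end) < (self.a, self.a_end):
            a, a_end = self.a, self.a_end
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "a_end", self.b_end)
            object.__setattr__(self, "b", a)
            object.__setattr__(self, "b_end", a_end)

    def slots(self) -> Tuple[Tuple[str, str], Tuple[str, str]]:
        return (self.a, self.a_end), (self.b, self.b_end)

    def other(self, contig_id: str, end: str) -> Tuple[str, str]:
        """The slot opposite ``(contig_id, end)`` on this link.

        For a same-slot self-link (both slots identical) the same slot is
        returned, which is the traversal semantics of a hairpin junction.
        """
        if (contig_id, end) == (self.a, self.a_end):
            return (self.b, self.b_end)
        if (contig_id, end) == (self.b, self.b_end):
            return (self.a, self.a_end)
        raise GraphError(f"slot ({contig_id}, {end}) not on link {self}")

    def touches(self, contig_id: str) -> bool:
        return self.a == contig_id or self.b == contig_id

    def is_self(self) -> bool:
        return self.a == self.b


class AssemblyGraph:
    """Contigs plus canonical links, with end-indexed adjacency.

    Invariants: every link references existing contigs; no duplicate
    canonical links (enforced by set semantics of :class:`Link`).
    """

    def __init__(
        self,
        contigs: Optional[Iterable[Contig]] = None,
        links: Optional[Iterable[Link]] = None,
    ):
        self.contigs: Dict[str, Contig] = {}
        self.links: Set[Link] = set()
        self._by_slot: Dict[Tuple[str, str], Set[Link]] = {}
        for c in contigs or ():
            self.add_contig(c)
        for l in links or ():
            self.add_link(l.a, l.a_end, l.b, l.b_end, l.support)

    # -- construction -------------------------------------------------------

    def add_contig(self, contig: Contig) -> None:
        if contig.id in self.contigs:
            raise GraphError(f"duplicate contig id {contig.id!r}")
        self.contigs[contig.id] = contig

    def add_link(self, a: str, a_end: str, b: str, b_end: str, support: int = 0) -> Link:
        link = Link(a, a_end, b, b_end, support)
        for cid in (link.a, link.b):
            if cid not in self.contigs:
                raise GraphError(f"link references unknown contig {cid!r}")
        if link in self.links:
            return link
        self.links.add(link)
        for slot in link.slots():
            self._by_slot.setdefault(slot, set()).add(link)
        return link

    # -- queries ------------------------------------------------------------

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def links_at(self, contig_id: str, end: str) -> List[Link]:
        """Links incident to one contig end, in deterministic sorted order."""
        return sorted(
            self._by_slot.get((contig_id, end), ()),
            key=lambda l: (l.a, l.a_end, l.b, l.b_end),
        )

    def links_of(self, contig_id: str) -> List[Link]:
        out = set(self._by_slot.get((contig_id, HEAD), ()))
        out |= self._by_slot.get((contig_id, TAIL), set())
        return sorted(out, key=lambda l: (l.a, l.a_end, l.b, l.b_end))

    def degree(self, contig_id: str, end: str) -> int:
        """Number of end slots consumed at one contig end.

        A same-end self-link occupies two slots of that end and therefore
        counts twice; every other incident link counts once.
        """
        d = 0
        for l in self._by_slot.get((contig_id, end), ()):
            d += sum(1 for s in l.slots() if s == (contig_id, end))
        return d

    def neighbors(self, contig_id: str) -> List[str]:
        out = set()
        for l in self.links_of(contig_id):
            out.add(l.a)
            out.add(l.b)
        out.discard(contig_id)
        return sorted(out)

    def has_self_link(self, contig_id: str) -> bool:
        return any(l.is_self() for l in self.links_of(contig_id))

    # -- editing / derivation ------------------------------------------------

    def copy(self) -> "AssemblyGraph":
        g = AssemblyGraph()
        g.contigs = dict(self.contigs)
        for l in self.links:
            g.links.add(l)
            for slot in l.slots():
                g._by_slot.setdefault(slot, set()).add(l)
        return g

    def remove_contigs(self, ids: Iterable[str]) -> "AssemblyGraph":
        """New graph without ``ids`` and without their incident links."""
        drop = set(ids)
        g = AssemblyGraph()
        for cid, c in self.contigs.items():
            if cid not in drop:
                g.add_contig(c)
        for l in self.links:
            if l.a not in drop and l.b not in drop:
                g.add_link(l.a, l.a_end, l.b, l.b_end, l.support)
        return g

    def remove_links(self, links: Iterable[Link]) -> "AssemblyGraph":
        drop = set(links)
        g = AssemblyGraph()
        for c in self.contigs.values():
            g.add_contig(c)
        for l in self.links:
            if l not in drop:
                g.add_link(l.a, l.a_end, l.b, l.b_end, l.support)
        return g

    def subgraph(self, ids: Iterable[str]) -> "AssemblyGraph":
        """Induced subgraph on ``ids`` (links kept iff both ends kept)."""
        keep = set(ids)
        missing = keep - self.contigs.keys()
        if missing:
            raise GraphError(f"unknown contigs: {sorted(missing)}")
        g = AssemblyGraph()
        for cid in sorted(keep):
            g.add_contig(self.contigs[cid])
        for l in self.links:
            if l.a in keep and l.b in keep:
                g.add_link(l.a, l.a_end, l.b, l.b_end, l.support)
        return g

    def validate(self) -> None:
        for l in self.links:
            if l.a not in self.contigs or l.b not in self.contigs:
                raise GraphError(f"link {l} references a missing contig")

    # -- equality ------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssemblyGraph):
            return NotImplemented
        if self.contigs.keys() != other.contigs.keys():
            return False
        for cid, c in self.contigs.items():
            o = other.contigs[cid]
            if (c.length, c.depth, c.seq) != (o.length, o.depth, o.seq):
                return False
        if self.links != other.links:
            return False
        # support is excluded from Link identity; compare it explicitly
        sup = {l: l.support for l in self.links}
        for l in other.links:
            if sup[l] != l.support:
                return False
        return True

    def __repr__(self) -> str:
        return f"AssemblyGraph({self.n_contigs} contigs, {self.n_links} links)"

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs.values())
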