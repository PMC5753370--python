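"""Core value types for domain-architecture assignment.

Coordinates follow CATH chopping practice throughout: residue indices are
1-based and intervals are fully inclusive, so the segment ``122-208`` covers
residues 122 through 208 (87 residues).  A *chopping* is the textual encoding
of a domain's segments, e.g. ``"1-100_201-300"`` for a discontinuous domain
whose two segments flank an insertion.

A :class:`DomainHit` is one scored candidate assignment of a profile HMM to a
query protein; a hit with two or more segments is *discontinuous* (another
domain typically sits in the gap).  A :class:`ResolvedArchitecture` is the
final, mutually non-overlapping subset of hits selected for one query.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Segment",
    "DomainHit",
    "HitSet",
    "ResolvedArchitecture",
    "GoldAnnotation",
    "ChoppingError",
    "parse_chopping",
    "format_chopping",
    "hits_clash",
    "segments_clash",
    "covered_length",
    "residue_set",
]


class ChoppingError(ValueError):
    """Malformed chopping string or invalid segment list."""


@dataclass(frozen=True, order=True)
class Segment:
    """One contiguous residue interval, 1-based and inclusive at both ends."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if not (isinstance(self.start, int) and isinstance(self.stop, int)):
            raise ChoppingError(f"segment bounds must be integers: {self.start}-{self.stop}")
        if not 1 <= self.start <= self.stop:
            raise ChoppingError(f"invalid segment {self.start}-{self.stop}: need 1 <= start <= stop")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    def __str__(self) -> str:
        return f"{self.start}-{self.stop}"


def _validate_segments(segments: Sequence[Segment]) -> tuple[Segment, ...]:
    """Check the shared segment-list invariant: non-empty, ascending, with a
    gap of at least one residue between consecutive segments.

    Adjacent segments (e.g. 1-100 followed by 101-200) are rejected rather
    than merged: a discontinuous domain must encode a real insertion gap.
    """
    segs = tuple(segments)
    if not segs:
        raise ChoppingError("segment list is empty")
    for seg in segs:
        if not isinstance(seg, Segment):
            raise ChoppingError(f"not a Segment: {seg!r}")
    for prev, cur in zip(segs, segs[1:]):
        if cur.start <= prev.stop + 1:
            raise ChoppingError(
                f"segments {prev} and {cur} overlap, touch or are out of order; "
                "segments must be ascending with gaps >= 1 residue"
            )
    return segs


_CHOP_TOKEN = re.compile(r"^(\d+)-(\d+)$")


def parse_chopping(text: str) -> list[Segment]:
    """Parse a chopping string like ``"1-100_201-300"`` into segments.

    Raises :class:`ChoppingError` naming the offending token on malformed
    input, inverted ranges, or overlapping/touching segments.
    """
    if not isinstance(text, str) or not text.strip():
        raise ChoppingError(f"empty or non-string chopping: {text!r}")
    segments = []
    for token in text.strip().split("_"):
        m = _CHOP_TOKEN.match(token)
        if m is None:
            raise ChoppingError(f"malformed chopping token {token!r} in {text!r}")
        start, stop = int(m.group(1)), int(m.group(2))
        if not 1 <= start <= stop:
            raise ChoppingError(f"invalid range in token {token!r}: need 1 <= start <= stop")
        segments.append(Segment(start, stop))
    return list(_validate_segments(segments))


def format_chopping(segments: Iterable[Segment]) -> str:
    """Inverse of :func:`parse_chopping`: ``[Segment(1,100), Segment(201,300)]``
    becomes ``"1-100_201-300"``."""
    segs = _validate_segments(list(segments))
    return "_".join(str(s) for s in segs)


def segments_clash(a: Sequence[Segment], b: Sequence[Segment]) -> bool:
    """True iff some residue lies in a segment of *a* and a segment of *b*.

    Both lists must be sorted ascending (the segment-list invariant); runs a
    two-pointer sweep in O(len(a)+len(b)).
    """
    i = j = 0
    while i < len(a) and j < len(b):
        if a[i].stop < b[j].start:
            i += 1
        elif b[j].stop < a[i].start:
            j += 1
        else:
            return True
    return False


def covered_length(segments: Sequence[Segment]) -> int:
    """Total number of residues covered by a disjoint segment list."""
    return sum(s.length for s in segments)


def residue_set(segments: Sequence[Segment]) -> set[int]:
    """Explicit residue-index set; O(total length), intended for small inputs
    and cross-checks."""
    out: set[int] = set()
    for s in segments:
        out.update(range(s.start, s.stop + 1))
    return out


@dataclass(frozen=True)
class DomainHit:
    """A scored candidate assignment of one HMM to one or more segments of a
    query protein.

    ``bitscore`` is the HMMER log-odds score in bits (additive, database-size
    independent); ``cond_evalue``/``indp_evalue`` are HMMER's per-domain
    conditional and independent e-values; ``resolve_score`` is the positive
    score the resolver maximises (the bitscore by default).
    """

    query_id: str
    match_id: str
    segments: tuple[Segment, ...]
    bitscore: float = 0.0
    cond_evalue: float = 0.0
    indp_evalue: float = 0.0
    resolve_score: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", _validate_segments(self.segments))
        if self.cond_evalue < 0 or self.indp_evalue < 0:
            raise ValueError(f"negative e-value on hit {self.query_id}/{self.match_id}")

    @property
    def is_discontinuous(self) -> bool:
        return len(self.segments) >= 2

    @property
    def first_start(self) -> int:
        return self.segments[0].start

    @property
    def last_stop(self) -> int:
        return self.segments[-1].stop

    @property
    def covered_length(self) -> int:
        return covered_length(self.segments)

    @property
    def chopping(self) -> str:
        return format_chopping(self.segments)


def hits_clash(a: DomainHit, b: DomainHit) -> bool:
    """True iff hits *a* and *b* share at least one residue.

    Raises ``ValueError`` when the hits are on different query proteins, where
    the question is meaningless.
    """
    if a.query_id != b.query_id:
        raise ValueError(f"hits on different queries: {a.query_id!r} vs {b.query_id!r}")
    return segments_clash(a.segments, b.segments)


@dataclass
class HitSet:
    """All candidate hits for one query protein.

    ``query_length`` of 0 means unknown; when known, every segment must fit.
    """

    query_id: str
    hits: list[DomainHit] = field(default_factory=list)
    query_length: int = 0

    def __post_init__(self) -> None:
        for h in self.hits:
            if h.query_id != self.query_id:
                raise ValueError(
                    f"hit query {h.query_id!r} does not match set query {self.query_id!r}"
                )
            if self.query_length > 0 and h.last_stop > self.query_length:
                raise ValueError(
                    f"hit {h.match_id} extends to {h.last_stop} beyond "
                    f"query length {self.query_length}"
                )

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)


_TOTAL_RTOL = 1e-9


@dataclass
class ResolvedArchitecture:
    """The selected non-overlapping subset of hits for one query, ordered
    along the sequence by first-segment start."""

    query_id: str
    selected: list[DomainHit] = field(default_factory=list)
    total_score: float = 0.0

    def __post_init__(self) -> None:
        for h in self.selected:
            if h.query_id != self.query_id:
                raise ValueError("selected hit on wrong query")
        starts = [h.first_start for h in self.selected]
        if starts != sorted(starts):
            raise ValueError("selected hits not ordered by first-segment start")
        for i, a in enumerate(self.selected):
            for b in self.selected[i + 1:]:
                if hits_clash(a, b):
                    raise ValueError(
                        f"selected hits overlap: {a.match_id} {a.chopping} vs "
                        f"{b.match_id} {b.chopping}"
                    )
        expect = sum(h.resolve_score for h in self.selected)
        tol = _TOTAL_RTOL * max(1.0, abs(expect))
        if abs(self.total_score - expect) > tol:
            raise ValueError(
                f"total_score {self.total_score} != sum of member scores {expect}"
            )

    def __len__(self) -> int:
        return len(self.selected)


@dataclass(frozen=True)
class GoldAnnotation:
    """A reference domain (family id + chopping) used as the gold standard
    when benchmarking predictions."""

    query_id: str
    family_id: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", _validate_segments(self.segments))

    @property
    def is_discontinuous(self) -> bool:
        return len(self.segments) >= 2

    @property
    def covered_length(self) -> int:
        return covered_length(self.segments)

    @property
    def chopping(self) -> str:
        return format_chopping(self.segments)
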