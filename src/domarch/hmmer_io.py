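"""Reading and writing candidate hits and resolved architectures.

Supported formats:

* HMMER3 ``hmmsearch --domtblout`` per-domain tables (comment lines start with
  ``#``; 23 whitespace-separated fields per row, the last of which is a
  free-text description that may itself contain spaces).
* An internal tab-separated hits format with header
  ``query_id  match_id  resolve_score  cond_evalue  indp_evalue  chopping``.
* A resolved-architecture TSV with one selected hit per line.

Segments are taken from the envelope coordinates (``env from``/``env to``) by
default, HMMER's estimate of the full domain extent; alignment coordinates
(``ali from``/``ali to``) are available via ``coordinates="ali"``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import IO, Iterable

from .model import (
    ChoppingError,
    DomainHit,
    HitSet,
    ResolvedArchitecture,
    Segment,
    format_chopping,
    parse_chopping,
)

__all__ = [
    "DomtbloutRow",
    "DomtbloutParseError",
    "read_domtblout",
    "join_split_rows",
    "read_hits_tsv",
    "write_hits_tsv",
    "read_gold_tsv",
    "write_gold_tsv",
    "write_resolved",
    "read_resolved",
]

HITS_TSV_HEADER = ["query_id", "match_id", "resolve_score", "cond_evalue", "indp_evalue", "chopping"]
RESOLVED_TSV_HEADER = ["query_id", "match_id", "resolve_score", "chopping", "tier"]
GOLD_TSV_HEADER = ["query_id", "family_id", "chopping"]

# Field layout of HMMER3 domtblout (hmmsearch): 22 fixed columns + description.
_N_DOMTBLOUT_FIELDS = 23


class DomtbloutParseError(ValueError):
    """Raised with the 1-based line number of the offending row."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"domtblout line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class DomtbloutRow:
    """One per-domain row of an hmmsearch domtblout table.

    ``target_name`` is the sequence searched, ``query_name`` the profile HMM.
    ``c_evalue``/``i_evalue``/``bitscore`` are this domain's conditional
    e-value, independent e-value and bit score.
    """

    target_name: str
    query_name: str
    full_evalue: float
    dom_index: int
    dom_total: int
    c_evalue: float
    i_evalue: float
    bitscore: float
    ali_from: int
    ali_to: int
    env_from: int
    env_to: int
    description: str = "-"

    def __post_init__(self) -> None:
        if self.env_from > self.env_to:
            raise ValueError(f"envelope from {self.env_from} > to {self.env_to}")
        if min(self.full_evalue, self.c_evalue, self.i_evalue) < 0:
            raise ValueError("negative e-value")


def _parse_row(lineno: int, line: str) -> DomtbloutRow:
    fields = line.split(None, _N_DOMTBLOUT_FIELDS - 1)
    if len(fields) < _N_DOMTBLOUT_FIELDS - 1:
        raise DomtbloutParseError(
            lineno, f"expected >= {_N_DOMTBLOUT_FIELDS - 1} fields, got {len(fields)}"
        )
    try:
        return DomtbloutRow(
            target_name=fields[0],
            query_name=fields[3],
            full_evalue=float(fields[6]),
            dom_index=int(fields[9]),
            dom_total=int(fields[10]),
            c_evalue=float(fields[11]),
            i_evalue=float(fields[12]),
            bitscore=float(fields[13]),
            ali_from=int(fields[17]),
            ali_to=int(fields[18]),
            env_from=int(fields[19]),
            env_to=int(fields[20]),
            description=fields[22] if len(fields) > 22 else "-",
        )
    except (ValueError, IndexError) as exc:
        if isinstance(exc, DomtbloutParseError):
            raise
        raise DomtbloutParseError(lineno, str(exc)) from exc


def read_domtblout(stream: IO[str], coordinates: str = "env") -> list[HitSet]:
    """Read an hmmsearch domtblout table into one :class:`HitSet` per target.

    Each row becomes a single-segment hit; ``resolve_score`` is set to the
    domain bitscore.  Targets appear in first-seen order and input order is
    preserved within each set.  Malformed rows raise
    :class:`DomtbloutParseError` with the line number.
    """
    if coordinates not in ("env", "ali"):
        raise ValueError(f"coordinates must be 'env' or 'ali', got {coordinates!r}")
    by_target: dict[str, list[DomainHit]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        row = _parse_row(lineno, line)
        start, stop = (
            (row.env_from, row.env_to) if coordinates == "env" else (row.ali_from, row.ali_to)
        )
        hit = DomainHit(
            query_id=row.target_name,
            match_id=row.query_name,
            segments=(Segment(start, stop),),
            bitscore=row.bitscore,
            cond_evalue=row.c_evalue,
            indp_evalue=row.i_evalue,
            resolve_score=row.bitscore,
        )
        by_target.setdefault(row.target_name, []).append(hit)
    return [HitSet(query_id=t, hits=hs) for t, hs in by_target.items()]


def join_split_rows(hitset: HitSet, max_gap: int = 30) -> HitSet:
    """Merge per-row fragments of one domain into multi-segment hits.

    Standard single-domain HMMs often report a discontinuous domain as
    separate envelope rows, one per segment.  Rows sharing (query, match)
    whose envelopes are disjoint, ascending, and separated by gaps of
    1..``max_gap`` residues are merged into one multi-segment hit: bitscores
    (and resolve scores) sum, e-values take the minimum of the members.
    Overlapping or distant rows pass through unchanged.
    """
    if max_gap < 1:
        raise ValueError(f"max_gap must be >= 1, got {max_gap}")
    by_match: dict[str, list[DomainHit]] = {}
    order: list[str] = []
    for h in hitset.hits:
        if h.match_id not in by_match:
            order.append(h.match_id)
        by_match.setdefault(h.match_id, []).append(h)

    out: list[DomainHit] = []
    for match_id in order:
        group = sorted(by_match[match_id], key=lambda h: (h.first_start, h.last_stop))
        chain: list[DomainHit] = []
        for h in group:
            if chain:
                gap = h.first_start - chain[-1].last_stop - 1
                if 1 <= gap <= max_gap:
                    chain.append(h)
                    continue
                out.append(_merge_chain(chain))
                chain = []
            chain.append(h)
        if chain:
            out.append(_merge_chain(chain))
    return HitSet(query_id=hitset.query_id, hits=out, query_length=hitset.query_length)


def _merge_chain(chain: list[DomainHit]) -> DomainHit:
    if len(chain) == 1:
        return chain[0]
    segments = tuple(s for h in chain for s in h.segments)
    return DomainHit(
        query_id=chain[0].query_id,
        match_id=chain[0].match_id,
        segments=segments,
        bitscore=sum(h.bitscore for h in chain),
        cond_evalue=min(h.cond_evalue for h in chain),
        indp_evalue=min(h.indp_evalue for h in chain),
        resolve_score=sum(h.resolve_score for h in chain),
    )


def read_hits_tsv(stream: IO[str]) -> list[HitSet]:
    """Read the internal hits TSV (see :data:`HITS_TSV_HEADER`)."""
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        return []
    if header != HITS_TSV_HEADER:
        raise ValueError(f"unexpected hits TSV header: {header}")
    by_query: dict[str, list[DomainHit]] = {}
    for row in reader:
        if not row:
            continue
        if len(row) != len(HITS_TSV_HEADER):
            raise ValueError(f"hits TSV row has {len(row)} fields: {row}")
        query_id, match_id, score, cond, indp, chopping = row
        by_query.setdefault(query_id, []).append(
            DomainHit(
                query_id=query_id,
                match_id=match_id,
                segments=tuple(parse_chopping(chopping)),
                bitscore=float(score),
                cond_evalue=float(cond),
                indp_evalue=float(indp),
                resolve_score=float(score),
            )
        )
    return [HitSet(query_id=q, hits=hs) for q, hs in by_query.items()]


def write_hits_tsv(hitsets: Iterable[HitSet], stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(HITS_TSV_HEADER)
    for hs in hitsets:
        for h in hs.hits:
            writer.writerow(
                [
                    h.query_id,
                    h.match_id,
                    repr(h.resolve_score),
                    repr(h.cond_evalue),
                    repr(h.indp_evalue),
                    format_chopping(h.segments),
                ]
            )


def write_resolved(
    arch: ResolvedArchitecture,
    stream: IO[str],
    tiers: dict[int, str] | None = None,
    header: bool = False,
) -> None:
    """Write one line per selected hit: query, match, score, chopping, tier.

    ``tiers`` maps ``id(hit)`` to a tier label; hits default to
    ``"significant"``.
    """
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    if header:
        writer.writerow(RESOLVED_TSV_HEADER)
    for h in arch.selected:
        tier = (tiers or {}).get(id(h), "significant")
        writer.writerow([h.query_id, h.match_id, repr(h.resolve_score), h.chopping, tier])


def read_resolved(stream: IO[str]) -> list[ResolvedArchitecture]:
    """Read a resolved-architecture TSV (with header) back into architectures."""
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        return []
    if header != RESOLVED_TSV_HEADER:
        raise ValueError(f"unexpected resolved TSV header: {header}")
    by_query: dict[str, list[DomainHit]] = {}
    for row in reader:
        if not row:
            continue
        query_id, match_id, score, chopping, _tier = row
        by_query.setdefault(query_id, []).append(
            DomainHit(
                query_id=query_id,
                match_id=match_id,
                segments=tuple(parse_chopping(chopping)),
                bitscore=float(score),
                resolve_score=float(score),
            )
        )
    out = []
    for q, hits in by_query.items():
        hits.sort(key=lambda h: h.first_start)
        out.append(
            ResolvedArchitecture(
                query_id=q, selected=hits, total_score=sum(h.resolve_score for h in hits)
            )
        )
    return out


def write_gold_tsv(annotations, stream: IO[str]) -> None:
    """Write gold annotations as TSV: query_id, family_id, chopping."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(GOLD_TSV_HEADER)
    for ann in annotations:
        writer.writerow([ann.query_id, ann.family_id, ann.chopping])


def read_gold_tsv(stream: IO[str]):
    """Read gold annotations written by :func:`write_gold_tsv`."""
    from .model import GoldAnnotation

    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        return []
    if header != GOLD_TSV_HEADER:
        raise ValueError(f"unexpected gold TSV header: {header}")
    out = []
    for row in reader:
        if not row:
            continue
        query_id, family_id, chopping = row
        try:
            segments = tuple(parse_chopping(chopping))
        except ChoppingError as exc:
            raise ChoppingError(f"gold annotation {query_id}/{family_id}: {exc}") from exc
        out.append(GoldAnnotation(query_id=query_id, family_id=family_id, segments=segments))
    return out
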