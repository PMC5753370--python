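"""E-value filtering and maximum-score resolution of overlapping domain hits.

The resolver turns a set of scored, possibly overlapping (and possibly
discontinuous) candidate hits into a final domain architecture: the subset of
pairwise non-overlapping hits with maximal total ``resolve_score``.  For
single-segment hits this is weighted interval scheduling; discontinuous hits
generalise it, because another hit may legitimately sit inside a
discontinuous hit's gap while the two still share no residue.

The dynamic programme sweeps hits in order of first-segment start.  Its state
is the set of already-selected hits that are still "open" — whose coverage
extends past the current position and can therefore still clash with later
candidates.  At most one *continuous* hit can be open at a time (two open
continuous hits would cover the current position and hence each other), so
the state space is exponential only in the number of simultaneously open
discontinuous hits.  That number is capped by ``max_inflight``; beyond the
cap the result is a feasible (clash-free) but possibly sub-optimal
architecture and a warning is emitted.

Filtering precedes resolution.  Hits pass the *significant* tier on a strict
independent e-value cut (< 0.001 by default); hits failing that but passing
the conditional e-value cut form a *low-confidence* tier that joins
resolution only on request.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

from .model import (
    DomainHit,
    HitSet,
    ResolvedArchitecture,
    Segment,
    segments_clash,
)

__all__ = [
    "FilterPolicy",
    "ResolveOptions",
    "ResolverWarning",
    "rescale_evalue",
    "rescale_hitset",
    "filter_hits",
    "resolve",
    "resolve_brute_force",
    "trim_clashes",
]

DEFAULT_EVALUE_CUT = 1e-3
DEFAULT_Z = 10_000_000.0


class ResolverWarning(UserWarning):
    """Emitted when the open-hit cap forces an approximate resolution."""


@dataclass(frozen=True)
class FilterPolicy:
    """Significance policy for candidate hits.

    ``indp_threshold``: strict cut on the independent e-value for the
    significant tier.  ``cond_threshold``: strict cut on the conditional
    e-value for the low-confidence tier (hits failing the independent cut but
    passing this one).  ``z_current``/``z_target``: effective search-space
    sizes used to rescale e-values from the scan that produced them to a
    common reference database size.
    """

    indp_threshold: float = DEFAULT_EVALUE_CUT
    cond_threshold: float = DEFAULT_EVALUE_CUT
    z_current: float = DEFAULT_Z
    z_target: float = DEFAULT_Z

    def __post_init__(self) -> None:
        if min(self.indp_threshold, self.cond_threshold) <= 0:
            raise ValueError("e-value thresholds must be > 0")
        if min(self.z_current, self.z_target) <= 0:
            raise ValueError("search-space sizes must be > 0")


@dataclass(frozen=True)
class ResolveOptions:
    """Resolution knobs.

    ``max_inflight`` caps the number of discontinuous hits simultaneously
    open in the DP state (default 6, comfortably above observed insertion
    nesting depth).  ``trim`` allows shrinking the lower-scoring hit's
    segment ends by up to ``trim`` residues to clear marginal clashes before
    resolution (default 0: a single shared residue is a clash).
    """

    max_inflight: int = 6
    trim: int = 0

    def __post_init__(self) -> None:
        if self.max_inflight < 1:
            raise ValueError("max_inflight must be >= 1")
        if self.trim < 0:
            raise ValueError("trim must be >= 0")


def rescale_evalue(e: float, z_current: float, z_target: float) -> float:
    """Rescale an e-value between effective search-space sizes.

    E-values scale linearly with database size, so a hit with e-value *e*
    found in a search space of ``z_current`` sequences has e-value
    ``e * z_target / z_current`` in a space of ``z_target`` sequences.
    """
    if e <= 0 or z_current <= 0 or z_target <= 0:
        raise ValueError(f"all inputs must be > 0: e={e}, z_current={z_current}, z_target={z_target}")
    return e * z_target / z_current


def rescale_hitset(hitset: HitSet, policy: FilterPolicy) -> HitSet:
    """Rescale every hit's e-values from ``policy.z_current`` to
    ``policy.z_target``.  Zero e-values (underflow) are left as zero."""
    factor = policy.z_target / policy.z_current
    if factor == 1.0:
        return hitset
    hits = [
        DomainHit(
            query_id=h.query_id,
            match_id=h.match_id,
            segments=h.segments,
            bitscore=h.bitscore,
            cond_evalue=h.cond_evalue * factor,
            indp_evalue=h.indp_evalue * factor,
            resolve_score=h.resolve_score,
        )
        for h in hitset.hits
    ]
    return HitSet(query_id=hitset.query_id, hits=hits, query_length=hitset.query_length)


def filter_hits(hitset: HitSet, policy: FilterPolicy | None = None) -> tuple[HitSet, HitSet]:
    """Partition hits into (significant, low_confidence) tiers.

    Significant: ``indp_evalue < indp_threshold`` (strict).  Low confidence:
    fails that but ``cond_evalue < cond_threshold``.  Everything else is
    dropped.  E-values are assumed already rescaled.
    """
    policy = policy or FilterPolicy()
    significant, low = [], []
    for h in hitset.hits:
        if h.indp_evalue < policy.indp_threshold:
            significant.append(h)
        elif h.cond_evalue < policy.cond_threshold:
            low.append(h)
    return (
        HitSet(hitset.query_id, significant, hitset.query_length),
        HitSet(hitset.query_id, low, hitset.query_length),
    )


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------


def _tie_key(hit: DomainHit) -> tuple[int, str]:
    return (hit.first_start, hit.match_id)


def _subset_rank(score: float, hits: list[DomainHit]) -> tuple:
    """Total order on candidate subsets: maximal score first, then fewer
    hits, then lexicographically smallest sorted (start, match_id) list."""
    return (-score, len(hits), sorted(_tie_key(h) for h in hits))


def _check_scores(hits: list[DomainHit]) -> None:
    for h in hits:
        if h.resolve_score <= 0:
            raise ValueError(
                f"hit {h.query_id}/{h.match_id} has resolve_score {h.resolve_score}; "
                "only positive-score hits are eligible for resolution"
            )


def _architecture(query_id: str, chosen: list[DomainHit]) -> ResolvedArchitecture:
    ordered = sorted(chosen, key=lambda h: (h.first_start, h.match_id))
    return ResolvedArchitecture(
        query_id=query_id,
        selected=ordered,
        total_score=sum(h.resolve_score for h in ordered),
    )


def resolve(hitset: HitSet, options: ResolveOptions | None = None) -> ResolvedArchitecture:
    """Select the maximum-total-score subset of pairwise non-clashing hits.

    Exact (globally optimal) whenever no more than ``options.max_inflight``
    discontinuous hits are simultaneously open at any sweep position;
    otherwise a clash-free approximation is returned and a
    :class:`ResolverWarning` is emitted.  Deterministic, including ties.
    """
    options = options or ResolveOptions()
    hits = list(hitset.hits)
    _check_scores(hits)
    if options.trim > 0:
        hits = trim_clashes(hits, options.trim)
    if not hits:
        return ResolvedArchitecture(query_id=hitset.query_id, selected=[], total_score=0.0)

    # Stable, deterministic processing order: first start, then tie key.
    hits.sort(key=lambda h: (h.first_start, h.last_stop, h.match_id, -h.resolve_score))
    n = len(hits)
    clash = [
        [segments_clash(hits[i].segments, hits[j].segments) for j in range(n)] for i in range(n)
    ]
    truncated = False

    @lru_cache(maxsize=None)
    def best(i: int, alive: frozenset[int]) -> tuple[float, int, tuple, frozenset[int]]:
        """Best completion over hits[i:] given currently open selected hits.

        Returns (score, count, sorted tie-key tuple, chosen index set)."""
        nonlocal truncated
        if i == n:
            return (0.0, 0, (), frozenset())
        pos = hits[i].first_start
        alive = frozenset(k for k in alive if hits[k].last_stop >= pos)

        # Option 1: skip hits[i].
        sc, ct, key, chosen = best(i + 1, alive)
        candidates = [((-sc, ct, key), (sc, ct, key, chosen))]

        # Option 2: take hits[i] if it clears every open hit and the cap.
        if all(not clash[i][k] for k in alive):
            n_open = sum(
                1
                for k in (*alive, i)
                if hits[k].is_discontinuous and hits[k].last_stop > pos
            )
            if n_open <= options.max_inflight:
                sc2, ct2, key2, chosen2 = best(i + 1, alive | {i})
                sc2 += hits[i].resolve_score
                ct2 += 1
                key2 = tuple(sorted((*key2, _tie_key(hits[i]))))
                candidates.append(((-sc2, ct2, key2), (sc2, ct2, key2, chosen2 | {i})))
            else:
                truncated = True

        return min(candidates, key=lambda c: c[0])[1]

    _, _, _, chosen_idx = best(0, frozenset())
    best.cache_clear()
    if truncated:
        warnings.warn(
            f"query {hitset.query_id}: more than {options.max_inflight} discontinuous "
            "hits open simultaneously; result is feasible but may be sub-optimal",
            ResolverWarning,
            stacklevel=2,
        )
    return _architecture(hitset.query_id, [hits[k] for k in chosen_idx])


def resolve_brute_force(hitset: HitSet) -> ResolvedArchitecture:
    """Exhaustive-enumeration oracle: tries all 2^n subsets (n <= 20) and
    returns the best clash-free one under the same tie-break as
    :func:`resolve`."""
    hits = list(hitset.hits)
    _check_scores(hits)
    n = len(hits)
    if n > 20:
        raise ValueError(f"brute force refuses {n} hits (> 20)")
    clash = [
        [segments_clash(hits[i].segments, hits[j].segments) for j in range(n)] for i in range(n)
    ]
    # feasible[mask]: incremental check via the lowest set bit.
    feasible = [True] * (1 << n)
    best_rank = None
    best_subset: list[DomainHit] = []
    for mask in range(1 << n):
        if mask:
            low = (mask & -mask).bit_length() - 1
            rest = mask ^ (1 << low)
            if not feasible[rest] or any(
                clash[low][j] for j in range(n) if rest >> j & 1
            ):
                feasible[mask] = False
                continue
        subset = [hits[j] for j in range(n) if mask >> j & 1]
        rank = _subset_rank(sum(h.resolve_score for h in subset), subset)
        if best_rank is None or rank < best_rank:
            best_rank = rank
            best_subset = subset
    return _architecture(hitset.query_id, best_subset)


def trim_clashes(hits: list[DomainHit], trim: int) -> list[DomainHit]:
    """Shrink lower-scoring hits' segment ends by up to ``trim`` residues to
    clear marginal boundary overlaps with higher-scoring hits.

    Processes hits in descending score order against the already-kept set;
    a segment is trimmed only at its ends, never below one residue, and only
    when trimming actually removes the clash.  Hits whose clash cannot be
    cleared are left intact (the resolver treats them as clashing).
    """
    order = sorted(range(len(hits)), key=lambda i: (-hits[i].resolve_score, _tie_key(hits[i])))
    kept: list[DomainHit] = []
    out: list[DomainHit | None] = [None] * len(hits)
    for i in order:
        h = hits[i]
        for other in kept:
            if not segments_clash(h.segments, other.segments):
                continue
            trimmed = _trim_against(h, other, trim)
            if trimmed is not None:
                h = trimmed
        out[i] = h
        kept.append(h)
    return [h for h in out if h is not None]


def _trim_against(hit: DomainHit, other: DomainHit, trim: int) -> DomainHit | None:
    """Trim ``hit``'s segment ends (<= trim residues each) to clear overlap
    with ``other``; None when the clash is too deep to trim away."""
    new_segs: list[Segment] = []
    for seg in hit.segments:
        start, stop = seg.start, seg.stop
        for oseg in other.segments:
            if oseg.stop < start or oseg.start > stop:
                continue
            cut_left = oseg.stop - start + 1  # residues to drop from our left end
            cut_right = stop - oseg.start + 1  # residues to drop from our right end
            if 0 < cut_left <= trim and oseg.start <= start:
                start = oseg.stop + 1
            elif 0 < cut_right <= trim and oseg.stop >= stop:
                stop = oseg.start - 1
            else:
                return None  # overlap interior or deeper than trim
        if start > stop:
            return None
        new_segs.append(Segment(start, stop))
    try:
        return DomainHit(
            query_id=hit.query_id,
            match_id=hit.match_id,
            segments=tuple(new_segs),
            bitscore=hit.bitscore,
            cond_evalue=hit.cond_evalue,
            indp_evalue=hit.indp_evalue,
            resolve_score=hit.resolve_score,
        )
    except ValueError:
        return None
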