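"""HMM-library decision procedures and benchmark metrics.

Three pure-function pieces sit here:

* the iterative-search round-selection rule (keep the round-1 profile unless
  the round-2 profile strictly improves the benchmark: more true positives
  with no extra false positives, or fewer false positives with no lost true
  positives);
* construction of the contiguous sequence region spanning a discontinuous
  domain plus everything inserted into it, used to build additional HMMs
  that capture insertion architectures directly;
* true/false-positive benchmarking of resolved architectures against gold
  annotations, including the discontinuous-only accuracy.

Counting is per-domain.  A prediction is a true positive when an unconsumed
gold annotation shares at least ``min_overlap_fraction`` of BOTH the
prediction's and the gold domain's covered residues (and the family ids
match, when required); golds are consumed greedily by descending prediction
score so the matching is one-to-one and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    DomainHit,
    GoldAnnotation,
    ResolvedArchitecture,
    Segment,
)

__all__ = [
    "BenchmarkCounts",
    "MatchCriterion",
    "select_hmm_round",
    "build_discontinuous_region",
    "shared_residues",
    "match_predictions",
    "classify_hits",
    "discontinuous_accuracy",
    "overall_recovery",
]


@dataclass(frozen=True)
class BenchmarkCounts:
    tp: int
    fp: int

    def __post_init__(self) -> None:
        if not (isinstance(self.tp, int) and isinstance(self.fp, int)):
            raise ValueError("tp and fp must be integers")
        if self.tp < 0 or self.fp < 0:
            raise ValueError(f"negative counts: tp={self.tp}, fp={self.fp}")

    def __add__(self, other: "BenchmarkCounts") -> "BenchmarkCounts":
        return BenchmarkCounts(self.tp + other.tp, self.fp + other.fp)


@dataclass(frozen=True)
class MatchCriterion:
    """When does a prediction "correctly identify" a gold domain?

    ``min_overlap_fraction``: fraction of covered residues that must be
    shared, applied bidirectionally (to the prediction's length AND the
    gold's length).  ``require_family_match``: whether the family ids must
    also be equal.
    """

    min_overlap_fraction: float = 0.8
    require_family_match: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap_fraction <= 1:
            raise ValueError("min_overlap_fraction must be in (0, 1]")


def select_hmm_round(round1: BenchmarkCounts, round2: BenchmarkCounts) -> int:
    """Choose between the round-1 and round-2 iterative-search profiles.

    Round 1 is the default; round 2 wins iff true positives increase with no
    increase in false positives, or false positives decrease with no decrease
    in true positives.
    """
    r1, r2 = round1, round2
    if (r2.tp > r1.tp and r2.fp <= r1.fp) or (r2.fp < r1.fp and r2.tp >= r1.tp):
        return 2
    return 1


def build_discontinuous_region(outer: GoldAnnotation, full_sequence_length: int) -> Segment:
    """The single contiguous region spanning a discontinuous domain.

    Runs from the outer domain's first start to its last stop, thereby
    covering the outer domain AND whatever is inserted into its gaps — the
    region from which an insertion-aware HMM is built.
    """
    if not outer.is_discontinuous:
        raise ValueError(
            f"domain {outer.query_id}/{outer.family_id} is not discontinuous "
            f"({outer.chopping})"
        )
    span = Segment(outer.segments[0].start, outer.segments[-1].stop)
    if span.stop > full_sequence_length:
        raise ValueError(
            f"region {span} exceeds sequence length {full_sequence_length}"
        )
    return span


def shared_residues(a, b) -> int:
    """Number of residues covered by both segment lists (sorted, disjoint)."""
    total = 0
    i = j = 0
    sa, sb = a.segments, b.segments
    while i < len(sa) and j < len(sb):
        lo = max(sa[i].start, sb[j].start)
        hi = min(sa[i].stop, sb[j].stop)
        if lo <= hi:
            total += hi - lo + 1
        if sa[i].stop < sb[j].stop:
            i += 1
        else:
            j += 1
    return total


def _satisfies(pred: DomainHit, gold: GoldAnnotation, crit: MatchCriterion) -> bool:
    if crit.require_family_match and pred.match_id != gold.family_id:
        return False
    shared = shared_residues(pred, gold)
    return (
        shared >= crit.min_overlap_fraction * pred.covered_length
        and shared >= crit.min_overlap_fraction * gold.covered_length
    )


def match_predictions(
    predicted: ResolvedArchitecture,
    gold: list[GoldAnnotation],
    crit: MatchCriterion | None = None,
) -> list[tuple[DomainHit, GoldAnnotation]]:
    """Greedy one-to-one matching of predictions to gold annotations.

    Predictions are visited in descending resolve_score (ties by position and
    family for determinism); each claims the first unconsumed gold it
    satisfies, in gold input order.
    """
    crit = crit or MatchCriterion()
    for g in gold:
        if g.query_id != predicted.query_id:
            raise ValueError(
                f"gold query {g.query_id!r} does not match predictions "
                f"for {predicted.query_id!r}"
            )
    remaining = list(gold)
    pairs = []
    for pred in sorted(
        predicted.selected, key=lambda h: (-h.resolve_score, h.first_start, h.match_id)
    ):
        for g in remaining:
            if _satisfies(pred, g, crit):
                pairs.append((pred, g))
                remaining.remove(g)
                break
    return pairs


def classify_hits(
    predicted: ResolvedArchitecture,
    gold: list[GoldAnnotation],
    crit: MatchCriterion | None = None,
) -> BenchmarkCounts:
    """Count per-domain true and false positives for one query.

    tp + fp always equals the number of predictions; tp never exceeds the
    number of gold annotations (matching is one-to-one).
    """
    pairs = match_predictions(predicted, gold, crit)
    tp = len(pairs)
    return BenchmarkCounts(tp=tp, fp=len(predicted.selected) - tp)


def discontinuous_accuracy(
    results: list[tuple[ResolvedArchitecture, list[GoldAnnotation]]],
    crit: MatchCriterion | None = None,
) -> float:
    """Percentage of discontinuous gold domains correctly identified.

    A discontinuous gold domain counts as identified when the matching pairs
    it with a prediction that itself has >= 2 segments — the prediction must
    reproduce the discontinuity, not merely overlap the region.
    Returns a value in [0, 100]; raises on input with no discontinuous gold.
    """
    n_disc = 0
    n_found = 0
    for predicted, gold in results:
        pairs = match_predictions(predicted, gold, crit)
        matched = {id(g): pred for pred, g in pairs}
        for g in gold:
            if not g.is_discontinuous:
                continue
            n_disc += 1
            pred = matched.get(id(g))
            if pred is not None and pred.is_discontinuous:
                n_found += 1
    if n_disc == 0:
        raise ValueError("no discontinuous gold domains in input")
    return 100.0 * n_found / n_disc


def overall_recovery(
    results: list[tuple[ResolvedArchitecture, list[GoldAnnotation]]],
    crit: MatchCriterion | None = None,
) -> float:
    """Percentage of all gold domains matched by a prediction (planted-
    architecture recovery)."""
    n_gold = sum(len(gold) for _, gold in results)
    if n_gold == 0:
        raise ValueError("no gold domains in input")
    n_tp = sum(classify_hits(pred, gold, crit).tp for pred, gold in results)
    return 100.0 * n_tp / n_gold
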