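"""Seeded simulator of planted domain architectures and noisy candidate hits.

The generator plants a clash-free "gold" architecture per protein — a few
globular domains separated by short linkers, with occasional insertion
events producing a discontinuous outer domain wrapped around an inserted
inner domain — and then emits noisy candidate hits emulating a profile-HMM
scan: boundary jitter on true hits, Gaussian bitscores for true hits and
(much weaker) decoys, and e-values derived from the scores by an
exponential-tail map ``E = Z * 2**(-bitscore)``, the HMMER-like relation
under which one extra bit halves the e-value.

By default a discontinuous gold domain yields one multi-segment hit, as an
insertion-aware HMM built over the whole discontinuous region would produce.
With ``split_discontinuous=True`` it instead yields one single-segment hit
per segment (bitscore split pro rata), emulating a standard single-domain
HMM whose alignment envelope breaks across the insertion — the failure mode
that multi-segment joining (:func:`domarch.hmmer_io.join_split_rows`) and
insertion-aware HMMs exist to fix.

Everything is reproducible: one global seed drives a hierarchical
per-protein substream, so protein *i* is byte-identical regardless of
``n_proteins``, and true-hit draws precede decoy draws so changing the decoy
rate leaves the true hits untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .model import DomainHit, GoldAnnotation, HitSet, Segment

__all__ = [
    "SimConfig",
    "ProteinTruth",
    "generate_truth",
    "generate_hits",
    "evalue_from_score",
    "FAMILY_POOL",
]

# Deterministic pool of superfamily-style identifiers for planted domains.
FAMILY_POOL: tuple[str, ...] = tuple(
    f"{c}.{a}.{t}.{h}"
    for c in (1, 2, 3)
    for a in (10, 20, 40, 60)
    for t in (50, 170, 505)
    for h in (10, 30)
)  # 72 codes

_MIN_LINKER, _MAX_LINKER = 5, 25
_MIN_OUTER_ARM = 20  # shortest allowed segment of a split (discontinuous) domain
_EVALUE_FLOOR = 1e-300
_COND_FACTOR = 50.0  # conditional e-value = independent e-value / factor
# Planted domains model confidently detectable homology: their bitscores are
# truncated at 40 bits, safely above the ~33-bit score at which the default
# e-value cut (0.001 at Z = 10^7) bites, so recovery benchmarks measure
# resolution rather than filter misses.  Sub-threshold true homology is a
# filtering concern and is exercised separately.
_TRUE_SCORE_FLOOR = 40.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Lengths are residues.  ``insertion_prob`` is the per-domain probability
    of an insertion event (outer domain split in two, inner domain planted
    in the gap).  ``decoy_rate`` is the Poisson mean of spurious hits per
    protein.  ``jitter_sd`` is the s.d. (residues) of Gaussian noise on true
    hit boundaries.  Score model: true hits ~ N(80, 15) bits, decoys
    ~ N(25, 8) bits, so decoys only occasionally clear the e-value filter at
    Z = 10^7 (the cut sits near 33 bits).
    """

    n_proteins: int = 100
    min_protein_length: int = 250
    max_protein_length: int = 800
    min_domain_length: int = 50
    max_domain_length: int = 200
    insertion_prob: float = 0.25
    decoy_rate: float = 2.0
    jitter_sd: float = 3.0
    true_score_mean: float = 80.0
    true_score_sd: float = 15.0
    decoy_score_mean: float = 25.0
    decoy_score_sd: float = 8.0
    z_target: float = 10_000_000.0
    split_discontinuous: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 1 <= self.min_protein_length <= self.max_protein_length:
            raise ValueError("invalid protein length range")
        if not 1 <= self.min_domain_length <= self.max_domain_length:
            raise ValueError("invalid domain length range")
        if not 0 <= self.insertion_prob <= 1:
            raise ValueError("insertion_prob must be in [0, 1]")
        if min(self.decoy_rate, self.jitter_sd) < 0:
            raise ValueError("rates must be >= 0")
        if self.z_target <= 0:
            raise ValueError("z_target must be > 0")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SimConfig":
        """Build from a flat key-value mapping (e.g. a loaded YAML file);
        unknown keys are rejected."""
        fields = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - fields
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ProteinTruth:
    """One simulated protein: its length and planted gold architecture."""

    query_id: str
    length: int
    domains: tuple[GoldAnnotation, ...]


def _rng(config: SimConfig, protein_index: int, phase: int) -> np.random.Generator:
    # spawn_key indexing keeps protein i's streams stable under n_proteins
    # changes and keeps truth (phase 0) independent of hit noise (phase 1).
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(protein_index, phase))
    )


def evalue_from_score(bitscore: float, z: float) -> float:
    """Exponential-tail score-to-e-value map, floored to avoid underflow."""
    return max(float(z) * 2.0 ** (-bitscore), _EVALUE_FLOOR)


def _plant_protein(query_id: str, rng: np.random.Generator, config: SimConfig) -> ProteinTruth:
    length = int(rng.integers(config.min_protein_length, config.max_protein_length + 1))
    families = list(FAMILY_POOL)
    rng.shuffle(families)
    fam_iter = iter(families)

    def draw_len() -> int:
        return int(rng.integers(config.min_domain_length, config.max_domain_length + 1))

    domains: list[GoldAnnotation] = []
    cursor = 1 + int(rng.integers(_MIN_LINKER, _MAX_LINKER + 1))
    while True:
        insert = rng.random() < config.insertion_prob
        if insert:
            outer_len = max(draw_len(), 2 * _MIN_OUTER_ARM + 1)
            inner_len = draw_len()
            span = outer_len + inner_len
        else:
            outer_len = draw_len()
            span = outer_len
        if cursor + span - 1 > length:
            break
        if insert:
            arm1 = int(rng.integers(_MIN_OUTER_ARM, outer_len - _MIN_OUTER_ARM + 1))
            outer = GoldAnnotation(
                query_id=query_id,
                family_id=next(fam_iter),
                segments=(
                    Segment(cursor, cursor + arm1 - 1),
                    Segment(cursor + arm1 + inner_len, cursor + outer_len + inner_len - 1),
                ),
            )
            inner = GoldAnnotation(
                query_id=query_id,
                family_id=next(fam_iter),
                segments=(Segment(cursor + arm1, cursor + arm1 + inner_len - 1),),
            )
            domains.extend([outer, inner])
        else:
            domains.append(
                GoldAnnotation(
                    query_id=query_id,
                    family_id=next(fam_iter),
                    segments=(Segment(cursor, cursor + outer_len - 1),),
                )
            )
        cursor += span + int(rng.integers(_MIN_LINKER, _MAX_LINKER + 1))
    if not domains:
        raise ValueError(
            f"{query_id}: no domain of length >= {config.min_domain_length} fits "
            f"in {length} residues"
        )
    return ProteinTruth(query_id=query_id, length=length, domains=tuple(domains))


def generate_truth(config: SimConfig) -> list[ProteinTruth]:
    """Plant a clash-free gold architecture for each protein.

    With probability ``insertion_prob`` a planted domain is split into two
    segments with a second, independent domain in the gap.  Raises when the
    configured domain lengths cannot fit the configured protein lengths
    (checked after a few re-draws of the protein length).
    """
    proteins = []
    for i in range(config.n_proteins):
        rng = _rng(config, i, phase=0)
        query_id = f"synth_{i:04d}"
        last_err: ValueError | None = None
        for _attempt in range(5):
            try:
                proteins.append(_plant_protein(query_id, rng, config))
                last_err = None
                break
            except ValueError as exc:
                last_err = exc
        if last_err is not None:
            raise ValueError(f"infeasible packing: {last_err}") from last_err
    return proteins


def _jitter_segments(
    segments: tuple[Segment, ...], length: int, rng: np.random.Generator, sd: float
) -> tuple[Segment, ...]:
    """Perturb each boundary by rounded N(0, sd); falls back to the exact
    truth segments if the perturbed list would violate segment invariants
    (inverted or touching segments), which is vanishingly rare at small sd."""
    offsets = [int(round(x)) for x in rng.normal(0.0, sd, size=2 * len(segments))] if sd > 0 else [
        0
    ] * (2 * len(segments))
    jittered = []
    for k, seg in enumerate(segments):
        start = min(max(1, seg.start + offsets[2 * k]), length)
        stop = max(1, min(length, seg.stop + offsets[2 * k + 1]))
        if start > stop:
            return segments
        jittered.append(Segment(start, stop))
    for prev, cur in zip(jittered, jittered[1:]):
        if cur.start <= prev.stop + 1:
            return segments
    return tuple(jittered)


def _true_hits(
    truth: ProteinTruth, rng: np.random.Generator, config: SimConfig
) -> list[DomainHit]:
    hits = []
    for ann in truth.domains:
        segments = _jitter_segments(ann.segments, truth.length, rng, config.jitter_sd)
        bits = max(
            _TRUE_SCORE_FLOOR, float(rng.normal(config.true_score_mean, config.true_score_sd))
        )
        if config.split_discontinuous and len(segments) >= 2:
            total = sum(s.length for s in segments)
            for seg in segments:
                part = max(1.0, bits * seg.length / total)
                indp = evalue_from_score(part, config.z_target)
                hits.append(
                    DomainHit(
                        query_id=truth.query_id,
                        match_id=ann.family_id,
                        segments=(seg,),
                        bitscore=part,
                        cond_evalue=indp / _COND_FACTOR,
                        indp_evalue=indp,
                        resolve_score=part,
                    )
                )
        else:
            indp = evalue_from_score(bits, config.z_target)
            hits.append(
                DomainHit(
                    query_id=truth.query_id,
                    match_id=ann.family_id,
                    segments=segments,
                    bitscore=bits,
                    cond_evalue=indp / _COND_FACTOR,
                    indp_evalue=indp,
                    resolve_score=bits,
                )
            )
    return hits


def _decoy_hits(
    truth: ProteinTruth, rng: np.random.Generator, config: SimConfig
) -> list[DomainHit]:
    hits = []
    n_decoys = int(rng.poisson(config.decoy_rate))
    for _ in range(n_decoys):
        dlen = min(
            int(rng.integers(config.min_domain_length, config.max_domain_length + 1)),
            truth.length,
        )
        start = int(rng.integers(1, truth.length - dlen + 2))
        family = str(rng.choice(FAMILY_POOL))
        bits = max(0.1, float(rng.normal(config.decoy_score_mean, config.decoy_score_sd)))
        indp = evalue_from_score(bits, config.z_target)
        hits.append(
            DomainHit(
                query_id=truth.query_id,
                match_id=family,
                segments=(Segment(start, start + dlen - 1),),
                bitscore=bits,
                cond_evalue=indp / _COND_FACTOR,
                indp_evalue=indp,
                resolve_score=bits,
            )
        )
    return hits


def generate_hits(truth: list[ProteinTruth], config: SimConfig) -> list[HitSet]:
    """Emit noisy candidate hits for planted truth, one HitSet per protein.

    Every gold domain yields a true hit (jittered boundaries, Gaussian
    bitscore, e-values from the exponential-tail map); decoy hits at random
    positions and families are added at Poisson(``decoy_rate``).  In the
    noise-free limit (``jitter_sd=0``, ``decoy_rate=0``) the hits reproduce
    the truth segments exactly.
    """
    hitsets = []
    for i, prot in enumerate(truth):
        rng = _rng(config, i, phase=1)
        hits = _true_hits(prot, rng, config)
        hits.extend(_decoy_hits(prot, rng, config))
        hitsets.append(HitSet(query_id=prot.query_id, hits=hits, query_length=prot.length))
    return hitsets
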