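"""Shared fixtures: random instance generators used across suites."""

from __future__ import annotations

import numpy as np
import pytest

from domarch.model import DomainHit, HitSet, Segment


def random_segments(rng: np.random.Generator, max_segments: int = 3, span: int = 400):
    """A valid ascending segment list with gaps >= 1 between segments."""
    n = int(rng.integers(1, max_segments + 1))
    cur = 0
    segs = []
    for _ in range(n):
        start = cur + int(rng.integers(1, 40))
        stop = start + int(rng.integers(0, span // (2 * n)))
        segs.append(Segment(start, stop))
        cur = stop + 1
    return tuple(segs)


def random_hitset(
    rng: np.random.Generator,
    query_id: str = "q",
    max_hits: int = 12,
    max_segments: int = 3,
) -> HitSet:
    n = int(rng.integers(1, max_hits + 1))
    hits = [
        DomainHit(
            query_id=query_id,
            match_id=f"m{k}",
            segments=random_segments(rng, max_segments),
            bitscore=float(rng.uniform(1, 100)),
            cond_evalue=float(rng.uniform(0, 1e-3)),
            indp_evalue=float(rng.uniform(0, 1e-2)),
            resolve_score=float(rng.uniform(1, 100)),
        )
        for k in range(n)
    ]
    return HitSet(query_id=query_id, hits=hits)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
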