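"""E-value rescaling/filtering and the maximum-score resolution DP."""

import numpy as np
import pytest

from domarch.model import DomainHit, HitSet, Segment, parse_chopping, residue_set
from domarch.resolver import (
    FilterPolicy,
    ResolveOptions,
    ResolverWarning,
    filter_hits,
    rescale_evalue,
    rescale_hitset,
    resolve,
    resolve_brute_force,
)

from conftest import random_hitset


def _hit(chopping, score, match="m", cond=1e-6, indp=1e-5):
    return DomainHit(
        query_id="q", match_id=match, segments=tuple(parse_chopping(chopping)),
        bitscore=score, cond_evalue=cond, indp_evalue=indp, resolve_score=score,
    )


class TestRescale:
    def test_doubling_search_space_doubles_evalue(self):
        assert rescale_evalue(1e-4, 5e6, 1e7) == pytest.approx(2e-4)

    def test_identity_when_spaces_equal(self):
        assert rescale_evalue(3.7e-8, 1e7, 1e7) == 3.7e-8

    def test_monotone_in_target_space(self, rng):
        for _ in range(200):
            e, zc = rng.uniform(1e-10, 1), rng.uniform(1e3, 1e9)
            z1, z2 = sorted(rng.uniform(1e3, 1e9, size=2))
            assert rescale_evalue(e, zc, z1) <= rescale_evalue(e, zc, z2)

    @pytest.mark.parametrize("args", [(0, 1e7, 1e7), (1e-4, 0, 1e7), (1e-4, 1e7, -1)])
    def test_rejects_nonpositive_inputs(self, args):
        with pytest.raises(ValueError):
            rescale_evalue(*args)

    def test_rescale_hitset_scales_both_evalues(self):
        hs = HitSet("q", [_hit("1-50", 10.0, cond=1e-6, indp=1e-4)])
        out = rescale_hitset(hs, FilterPolicy(z_current=5e6, z_target=1e7))
        assert out.hits[0].indp_evalue == pytest.approx(2e-4)
        assert out.hits[0].cond_evalue == pytest.approx(2e-6)


class TestFilterTiers:
    def test_six_hit_fixture_partitions_by_strict_cut(self):
        """Fixture spanning e-values {1e-5, 5e-4, 0.001, 0.01}: the strict
        < 0.001 rule sends two hits to each tier and drops two (values equal
        to the threshold fail the strict comparison)."""
        hits = [
            _hit("1-50", 10, match="sig_a", indp=1e-5, cond=1e-5),
            _hit("60-110", 10, match="sig_b", indp=5e-4, cond=5e-4),
            _hit("120-170", 10, match="low_a", indp=0.01, cond=5e-4),
            _hit("180-230", 10, match="low_b", indp=0.001, cond=1e-5),
            _hit("240-290", 10, match="drop_a", indp=0.01, cond=0.01),
            _hit("300-350", 10, match="drop_b", indp=0.001, cond=0.001),
        ]
        significant, low = filter_hits(HitSet("q", hits), FilterPolicy())
        assert {h.match_id for h in significant} == {"sig_a", "sig_b"}
        assert {h.match_id for h in low} == {"low_a", "low_b"}
        assert len(significant) + len(low) == 4  # two dropped, no hit in both tiers

    def test_empty_tiers_allowed(self):
        significant, low = filter_hits(HitSet("q", []), FilterPolicy())
        assert len(significant) == 0 and len(low) == 0


class TestResolve:
    def test_single_hit_selected(self):
        arch = resolve(HitSet("q", [_hit("10-90", 7.5)]))
        assert len(arch) == 1 and arch.total_score == pytest.approx(7.5)

    def test_higher_score_wins_pairwise_clash(self):
        a, b = _hit("1-100", 10, match="a"), _hit("50-150", 7, match="b")
        arch = resolve(HitSet("q", [a, b]))
        assert [h.match_id for h in arch.selected] == ["a"]
        assert arch.total_score == pytest.approx(10)

    def test_discontinuous_hit_accommodates_insertion(self):
        """A discontinuous hit plus the domain in its gap can beat a single
        continuous hit spanning both."""
        hits = [
            _hit("1-100_201-300", 12, match="A"),
            _hit("120-180", 5, match="B"),
            _hit("110-260", 14, match="C"),
        ]
        arch = resolve(HitSet("q", hits))
        assert {h.match_id for h in arch.selected} == {"A", "B"}
        assert arch.total_score == pytest.approx(17)
        oracle = resolve_brute_force(HitSet("q", hits))
        assert oracle.total_score == pytest.approx(arch.total_score)

    def test_empty_hitset_resolves_empty(self):
        arch = resolve(HitSet("q", []))
        assert len(arch) == 0 and arch.total_score == 0.0

    def test_rejects_nonpositive_resolve_score(self):
        bad = DomainHit("q", "m", (Segment(1, 10),), resolve_score=0.0)
        with pytest.raises(ValueError, match="resolve_score"):
            resolve(HitSet("q", [bad]))
        with pytest.raises(ValueError, match="resolve_score"):
            resolve_brute_force(HitSet("q", [bad]))

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(300):
            hs = random_hitset(rng)
            a, b = resolve(hs), resolve_brute_force(hs)
            assert a.total_score == pytest.approx(b.total_score, rel=1e-9)

    def test_selected_hits_pairwise_disjoint(self, rng):
        for _ in range(100):
            arch = resolve(random_hitset(rng))
            seen = set()
            for h in arch.selected:
                res = residue_set(h.segments)
                assert not (seen & res)
                seen |= res

    def test_deterministic_including_ties(self):
        hits = [
            _hit("1-100", 5.0, match="x"),
            _hit("1-100", 5.0, match="y"),
            _hit("150-200", 3.0, match="z"),
        ]
        first = resolve(HitSet("q", hits))
        again = resolve(HitSet("q", list(reversed(hits))))
        assert [h.match_id for h in first.selected] == [h.match_id for h in again.selected]
        # lexicographic tie-break on (start, match_id) picks "x" over "y"
        assert {h.match_id for h in first.selected} == {"x", "z"}

    def test_tie_prefers_fewer_hits(self):
        hits = [
            _hit("1-100", 10.0, match="whole"),
            _hit("1-50", 5.0, match="left"),
            _hit("52-100", 5.0, match="right"),
        ]
        arch = resolve(HitSet("q", hits))
        assert [h.match_id for h in arch.selected] == ["whole"]
        oracle = resolve_brute_force(HitSet("q", hits))
        assert [h.match_id for h in oracle.selected] == ["whole"]

    def test_scale_invariance_of_selection(self, rng):
        for _ in range(50):
            hs = random_hitset(rng, max_hits=8)
            base = resolve(hs)
            scaled = HitSet(
                "q",
                [
                    DomainHit(
                        "q", h.match_id, h.segments, bitscore=h.bitscore,
                        cond_evalue=h.cond_evalue, indp_evalue=h.indp_evalue,
                        resolve_score=h.resolve_score * 37.5,
                    )
                    for h in hs
                ],
            )
            out = resolve(scaled)
            assert [(h.match_id, h.segments) for h in out.selected] == [
                (h.match_id, h.segments) for h in base.selected
            ]

    def test_adding_a_hit_never_lowers_optimum(self, rng):
        for _ in range(50):
            hs = random_hitset(rng, max_hits=8)
            extra = random_hitset(rng, max_hits=1).hits[0]
            before = resolve(hs).total_score
            after = resolve(HitSet("q", hs.hits + [extra])).total_score
            assert after >= before - 1e-9

    def test_brute_force_refuses_large_inputs(self):
        big = HitSet("q", [_hit(f"{10 * k + 1}-{10 * k + 5}", 1.0, match=f"m{k}") for k in range(21)])
        with pytest.raises(ValueError, match="20"):
            resolve_brute_force(big)

    def test_inflight_cap_warns_and_stays_feasible(self):
        # three mutually compatible interleaved discontinuous hits but the
        # cap admits only one at a time
        hits = [
            _hit("1-10_100-110", 5, match="a"),
            _hit("20-30_120-130", 5, match="b"),
            _hit("40-50_140-150", 5, match="c"),
        ]
        with pytest.warns(ResolverWarning):
            arch = resolve(HitSet("q", hits), ResolveOptions(max_inflight=1))
        for i, x in enumerate(arch.selected):
            for y in arch.selected[i + 1:]:
                assert not (residue_set(x.segments) & residue_set(y.segments))
        full = resolve(HitSet("q", hits), ResolveOptions(max_inflight=6))
        assert full.total_score == pytest.approx(15)


class TestTrim:
    def test_marginal_clash_trimmed_from_lower_scorer(self):
        hits = [_hit("1-100", 10.0, match="big"), _hit("98-200", 5.0, match="small")]
        arch = resolve(HitSet("q", hits), ResolveOptions(trim=3))
        assert {h.match_id for h in arch.selected} == {"big", "small"}
        small = next(h for h in arch.selected if h.match_id == "small")
        assert small.segments == (Segment(101, 200),)

    def test_deep_clash_not_trimmed(self):
        hits = [_hit("1-100", 10.0, match="big"), _hit("50-200", 5.0, match="small")]
        arch = resolve(HitSet("q", hits), ResolveOptions(trim=3))
        assert [h.match_id for h in arch.selected] == ["big"]

    def test_zero_trim_keeps_single_residue_clash(self):
        hits = [_hit("1-100", 10.0, match="big"), _hit("100-200", 5.0, match="small")]
        arch = resolve(HitSet("q", hits), ResolveOptions(trim=0))
        assert [h.match_id for h in arch.selected] == ["big"]
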