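import random

import pytest

from homoref.io_formats import Hit, SeqRecord
from homoref.msc import (
    CloseSet,
    MscConfig,
    build_close_set,
    filtered_hit_ratio,
    msc_evaluate,
)
from homoref.search import SearchParams, align_pair
from homoref.synthetic_fixtures import mutate_sequence

from oracles import counting_ratio

AA = "ACDEFGHIKLMNPQRSTVWY"
PARAMS = SearchParams()


def _hit(subject_id, coverage=95.0, e_value=1e-40):
    return Hit("q", subject_id, 90.0, coverage, e_value, 100.0, 100)


class TestBuildCloseSet:
    def test_all_passing_included(self):
        hits = [_hit(f"s{i}") for i in range(5)]
        cs = build_close_set(hits, "q")
        assert cs.member_ids == tuple(f"s{i}" for i in range(5))

    def test_low_coverage_excluded(self):
        hits = [_hit("good"), _hit("shallow", coverage=30.0)]
        assert build_close_set(hits, "q").member_ids == ("good",)

    def test_weak_evalue_excluded(self):
        hits = [_hit("good"), _hit("weak", e_value=1e-2)]
        assert build_close_set(hits, "q").member_ids == ("good",)

    def test_query_own_record_excluded(self):
        hits = [_hit("q"), _hit("s1")]
        assert build_close_set(hits, "q").member_ids == ("s1",)

    def test_cap_keeps_best_sorted(self):
        hits = [_hit(f"s{i:03d}") for i in range(300)]
        cs = build_close_set(hits, "q")
        assert cs.size == 250
        assert cs.member_ids[0] == "s000"
        assert cs.member_ids[-1] == "s249"


def _family(seed, identities, length=150):
    """A query-centred family: members mutated from the query sequence at
    the given identity targets."""
    rng = random.Random(seed)
    base = "".join(rng.choice(AA) for _ in range(length))
    members = {
        f"m{i}": SeqRecord(f"m{i}", mutate_sequence(base, ident, seed * 100 + i))
        for i, ident in enumerate(identities)
    }
    return SeqRecord("ref", base), members


class TestFilteredHitRatio:
    def test_identical_reference_ratio_one_everywhere(self):
        ref, members = _family(1, [100, 100, 100])
        cs = CloseSet(tuple(members))
        for cutoff in (60, 50, 40):
            assert filtered_hit_ratio(ref, cs, members, cutoff) == 1.0

    def test_four_of_five_is_point_eight(self):
        ref, members = _family(2, [95, 95, 95, 95, 30])
        cs = CloseSet(tuple(members))
        assert filtered_hit_ratio(ref, cs, members, 60) == pytest.approx(0.8)

    def test_designed_identity_ladder_matches_brute_force(self):
        """Ratios over a 6-member set at staggered identities equal a direct
        per-pair alignment count at every cutoff."""
        ref, members = _family(3, [65, 62, 55, 48, 45, 30])
        cs = CloseSet(tuple(members))
        stats = [
            (
                align_pair(ref, members[m], PARAMS).percent_identity,
                align_pair(ref, members[m], PARAMS).query_coverage,
            )
            for m in cs.member_ids
        ]
        for cutoff in (60, 50, 40):
            assert filtered_hit_ratio(ref, cs, members, cutoff) == pytest.approx(
                counting_ratio(stats, cutoff)
            )

    def test_empty_close_set_ratio_zero(self):
        ref, members = _family(4, [90])
        assert filtered_hit_ratio(ref, CloseSet(()), members, 60) == 0.0


class TestMscEvaluate:
    def test_ratio_exactly_point_eight_rejected(self):
        # acceptance is strictly greater than 0.8
        ref, members = _family(5, [95, 95, 95, 95, 30])
        cs = CloseSet(tuple(members))
        result = msc_evaluate(ref, cs, members)
        assert result.ratio_at[60.0] == pytest.approx(0.8)
        assert result.accepted_at[60.0] is False

    def test_acceptance_at_all_cutoffs(self):
        ref, members = _family(6, [95, 92, 90])
        result = msc_evaluate(ref, CloseSet(tuple(members)), members)
        assert all(result.accepted_at.values())
        assert result.n_accepted == 3

    def test_empty_close_set_all_zero(self):
        ref, members = _family(7, [90])
        result = msc_evaluate(ref, CloseSet(()), members)
        assert all(r == 0.0 for r in result.ratio_at.values())
        assert not any(result.accepted_at.values())

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_ratio_monotone_in_cutoff(self, seed):
        rng = random.Random(seed)
        idents = [rng.randint(25, 95) for _ in range(8)]
        ref, members = _family(seed, idents)
        result = msc_evaluate(ref, CloseSet(tuple(members)), members)
        assert result.ratio_at[40.0] >= result.ratio_at[50.0] >= result.ratio_at[60.0]
        assert all(0.0 <= r <= 1.0 for r in result.ratio_at.values())

    def test_acceptance_is_prefix_in_cutoff_order(self):
        ref, members = _family(14, [95, 90, 88, 85])
        result = msc_evaluate(ref, CloseSet(tuple(members)), members)
        accepted = [result.accepted_at[c] for c in (40.0, 50.0, 60.0)]
        # once rejected at a permissive cutoff, stricter ones reject too
        assert accepted == sorted(accepted, reverse=True)

    def test_equivalence_with_brute_force_on_fixture(self, default_fixture):
        """Pipeline MSC equals independent per-pair counting on the default
        synthetic collection (close set <= 10 members)."""
        from homoref.search import search_all

        collection = default_fixture.collection
        query = collection[default_fixture.query_id]
        hits = search_all(query, default_fixture.records, PARAMS)
        cs = build_close_set(hits, query.protein_id)
        assert 0 < cs.size <= 10
        for cand_id in ("f0_g1", "f0p_g1"):
            result = msc_evaluate(collection[cand_id], cs, collection, PARAMS)
            stats = [
                (
                    align_pair(collection[cand_id], collection[m], PARAMS).percent_identity,
                    align_pair(collection[cand_id], collection[m], PARAMS).query_coverage,
                )
                for m in cs.member_ids
            ]
            for cutoff in (60.0, 50.0, 40.0):
                assert result.ratio_at[cutoff] == pytest.approx(
                    counting_ratio(stats, cutoff)
                )
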