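import random

import pytest
from hypothesis import given, settings, strategies as st

from homoref.io_formats import GenomeTable, Hit, SeqRecord
from homoref.orthology import (
    UNRESOLVED,
    detect_query_taxon,
    precluster_genome,
    reciprocal_best_hit,
)
from homoref.orthology import _identity_and_short_coverage
from homoref.search import SearchParams
from homoref.synthetic_fixtures import mutate_sequence

from oracles import greedy_clusters

AA = "ACDEFGHIKLMNPQRSTVWY"
PARAMS = SearchParams()


def _random_seq(rng, length):
    return "".join(rng.choice(AA) for _ in range(length))


def _pair_stats(a, b):
    return _identity_and_short_coverage(a, b, PARAMS)


class TestPrecluster:
    def test_identical_pair_single_cluster_first_read_representative(self):
        seqs = [SeqRecord("a", "MKVLAEKVLA" * 6), SeqRecord("b", "MKVLAEKVLA" * 6)]
        cmap = precluster_genome(seqs)
        assert cmap.rep("a") == "a"
        assert cmap.rep("b") == "a"

    def test_divergent_pair_two_singletons(self):
        rng = random.Random(5)
        base = _random_seq(rng, 100)
        seqs = [
            SeqRecord("a", base),
            SeqRecord("b", mutate_sequence(base, 50, 1)),
        ]
        cmap = precluster_genome(seqs)
        assert cmap.rep("a") == "a"
        assert cmap.rep("b") == "b"

    def test_mixed_taxa_error(self):
        seqs = [
            SeqRecord("a", "MKVLA", taxon="t1"),
            SeqRecord("b", "MKVLA", taxon="t2"),
        ]
        with pytest.raises(ValueError):
            precluster_genome(seqs)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_greedy_oracle_on_small_genomes(self, seed):
        """Clustering of 6-sequence genomes equals a direct transliteration
        of the greedy longest-first rule."""
        rng = random.Random(seed)
        base = _random_seq(rng, 90)
        seqs = [
            SeqRecord("a", base),
            SeqRecord("b", mutate_sequence(base, 98, seed)),       # allele of a
            SeqRecord("c", mutate_sequence(base, 60, seed + 1)),   # distant
            SeqRecord("d", _random_seq(rng, 80)),
            SeqRecord("e", mutate_sequence(base, 99, seed + 2)),   # allele of a
            SeqRecord("f", _random_seq(rng, 90)),
        ]
        cmap = precluster_genome(seqs)
        oracle = greedy_clusters(seqs, _pair_stats)
        assert cmap.representative == oracle

    def test_matches_oracle_on_fixture_genomes(self, default_fixture):
        gt = default_fixture.genome_table
        collection = default_fixture.collection
        for taxon in gt.taxa():
            seqs = [collection[pid] for pid in sorted(gt.members(taxon))]
            assert len(seqs) <= 10
            cmap = precluster_genome(seqs)
            assert cmap.representative == greedy_clusters(seqs, _pair_stats)


def _hit(subject_id, identity, coverage):
    return Hit("q", subject_id, identity, coverage, 1e-30, 100.0, 100)


class TestDetectQueryTaxon:
    def test_first_qualifying_hit_wins(self):
        gt = GenomeTable({"T": {"s1"}, "U": {"s2"}})
        hits = [_hit("s1", 98.0, 95.0), _hit("s2", 99.0, 99.0)]
        assert detect_query_taxon(hits, gt) == "T"

    def test_below_threshold_unresolved(self):
        gt = GenomeTable({"T": {"s1"}})
        assert detect_query_taxon([_hit("s1", 96.9, 95.0)], gt) == UNRESOLVED

    def test_qualifying_hit_without_taxon_is_skipped(self):
        gt = GenomeTable({"T": {"s2"}})
        hits = [_hit("s1", 99.0, 99.0), _hit("s2", 98.0, 95.0)]
        assert detect_query_taxon(hits, gt) == "T"

    def test_manual_taxon_overrides_detection(self):
        gt = GenomeTable({"T": {"s1"}})
        hits = [_hit("s1", 99.0, 99.0)]
        assert detect_query_taxon(hits, gt, manual_taxon="Z") == "Z"


def _two_genome_setup(seed, with_paralog=False):
    """Two genomes, one family; optionally a paralog of the query planted
    in genome B at higher identity than the true ortholog."""
    rng = random.Random(seed)
    ancestor = _random_seq(rng, 150)
    qseq = mutate_sequence(ancestor, 92, seed * 7 + 1)
    records = {
        "q": SeqRecord("q", qseq, taxon="A"),
        "orthB": SeqRecord("orthB", mutate_sequence(ancestor, 92, seed * 7 + 2), taxon="B"),
        "otherA": SeqRecord("otherA", _random_seq(rng, 150), taxon="A"),
        "otherB": SeqRecord("otherB", _random_seq(rng, 150), taxon="B"),
    }
    if with_paralog:
        records["paraB"] = SeqRecord(
            "paraB", mutate_sequence(qseq, 99, seed * 7 + 3), taxon="B"
        )
    gt = GenomeTable({r.taxon: set() for r in records.values()})
    for r in records.values():
        gt.add(r.protein_id, r.taxon)
    cmaps = {
        t: precluster_genome([records[p] for p in sorted(gt.members(t))])
        for t in gt.taxa()
    }
    return records, gt, cmaps


class TestReciprocalBestHit:
    def test_mutual_best_hits_true_true(self):
        records, gt, cmaps = _two_genome_setup(seed=1)
        verdict = reciprocal_best_hit(
            records["q"], "orthB", "A", gt, cmaps, records
        )
        assert (verdict.q2h, verdict.h2q) == (True, True)

    def test_unresolved_query_taxon_gives_na_h2q(self):
        records, gt, cmaps = _two_genome_setup(seed=2)
        verdict = reciprocal_best_hit(
            records["q"], "orthB", UNRESOLVED, gt, cmaps, records
        )
        assert verdict.h2q is None
        assert verdict.q2h is True

    def test_closer_paralog_breaks_q2h(self):
        records, gt, cmaps = _two_genome_setup(seed=3, with_paralog=True)
        verdict = reciprocal_best_hit(
            records["q"], "orthB", "A", gt, cmaps, records
        )
        assert verdict.q2h is False

    def test_cluster_awareness(self):
        """An allele (>=97% identical variant) of the true ortholog gets the
        same verdict as the ortholog itself."""
        records, gt, cmaps = _two_genome_setup(seed=4)
        allele = SeqRecord(
            "alleleB", mutate_sequence(records["orthB"].residues, 99, 99), taxon="B"
        )
        records = dict(records, alleleB=allele)
        gt.add("alleleB", "B")
        cmaps["B"] = precluster_genome(
            [records[p] for p in sorted(gt.members("B"))]
        )
        v_orth = reciprocal_best_hit(records["q"], "orthB", "A", gt, cmaps, records)
        v_allele = reciprocal_best_hit(records["q"], "alleleB", "A", gt, cmaps, records)
        assert (v_orth.q2h, v_orth.h2q) == (True, True)
        assert (v_allele.q2h, v_allele.h2q) == (v_orth.q2h, v_orth.h2q)

    def test_missing_candidate_sequence_errors(self):
        records, gt, cmaps = _two_genome_setup(seed=5)
        with pytest.raises(KeyError):
            reciprocal_best_hit(records["q"], "ghost", "A", gt, cmaps, records)

    @settings(max_examples=8, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_mutual_unique_best_hits_property(self, seed):
        """Whenever query and candidate really are each other's unique best
        hits (verified by brute-force all-vs-all), the verdict is (true, true)."""
        records, gt, cmaps = _two_genome_setup(seed=seed)
        from homoref.search import align_pair

        # brute-force confirmation of mutual best-hit structure
        b_scores = {
            pid: align_pair(records["q"], records[pid], PARAMS).bit_score
            for pid in ("orthB", "otherB")
        }
        a_scores = {
            pid: align_pair(records["orthB"], records[pid], PARAMS).bit_score
            for pid in ("q", "otherA")
        }
        if max(b_scores, key=b_scores.get) != "orthB":
            return  # random decoy happened to win; property vacuous
        if max(a_scores, key=a_scores.get) != "q":
            return
        verdict = reciprocal_best_hit(records["q"], "orthB", "A", gt, cmaps, records)
        assert (verdict.q2h, verdict.h2q) == (True, True)
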