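"""Orthology assessment: genome preclustering, query-taxon detection, and
cluster-aware reciprocal best hits.

Reciprocal best hits (RBH) approximate orthology: two proteins in
different genomes that each find the other as top hit. Near-identical
variants of the same gene (alleles, strain variants) would break strict
RBH, so each genome is first clustered greedily at 97% identity / 90%
coverage of the shorter sequence, and best-hit equality is tested at the
cluster-representative level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Optional

from .io_formats import GenomeTable, Hit, SeqRecord
from .search import SearchParams, align_pair, search_all

__all__ = [
    "ClusterMap",
    "ReciprocalVerdict",
    "precluster_genome",
    "detect_query_taxon",
    "reciprocal_best_hit",
    "UNRESOLVED",
    "CLUSTER_IDENTITY_CUTOFF",
    "CLUSTER_COVERAGE_CUTOFF",
    "TAXON_IDENTITY_CUTOFF",
    "TAXON_COVERAGE_CUTOFF",
]

UNRESOLVED = "UNRESOLVED"

CLUSTER_IDENTITY_CUTOFF = 97.0   # % identity to join a cluster
CLUSTER_COVERAGE_CUTOFF = 90.0   # % coverage of the shorter sequence
TAXON_IDENTITY_CUTOFF = 97.0     # % identity to infer the query taxon
TAXON_COVERAGE_CUTOFF = 90.0     # % query coverage to infer the query taxon

Searcher = Callable[[SeqRecord, list[SeqRecord], SearchParams], list[Hit]]


@dataclass
class ClusterMap:
    """Protein id -> cluster representative id, for one genome."""

    taxon: str
    representative: dict[str, str]

    def rep(self, protein_id: str) -> str:
        # An id outside the map represents itself (e.g. the query protein
        # when it is not part of the clustered collection).
        return self.representative.get(protein_id, protein_id)


@dataclass(frozen=True)
class ReciprocalVerdict:
    """Outcome of the two reciprocal searches; ``None`` means the needed
    genome could not be resolved (scored as NA downstream)."""

    q2h: Optional[bool]
    h2q: Optional[bool]


def _identity_and_short_coverage(
    a: SeqRecord, b: SeqRecord, params: SearchParams
) -> tuple[float, float]:
    """Alignment identity and coverage of the shorter of the two sequences."""
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    hit = align_pair(shorter, longer, params)
    return hit.percent_identity, hit.query_coverage


def precluster_genome(
    seqs: list[SeqRecord],
    params: SearchParams | None = None,
    identity_cutoff: float = CLUSTER_IDENTITY_CUTOFF,
    coverage_cutoff: float = CLUSTER_COVERAGE_CUTOFF,
) -> ClusterMap:
    """Greedy incremental clustering of one genome's proteins.

    Sequences are processed longest-first (input order on ties); each
    joins the first existing cluster whose representative it matches at
    >= 97% identity with >= 90% coverage of the shorter sequence, else it
    founds a new cluster. This is the classic greedy identity-clustering
    scheme (CD-HIT style) at the thresholds used for allele collapsing.
    """
    params = params or SearchParams()
    taxa = {s.taxon for s in seqs}
    if len(taxa) > 1:
        raise ValueError(f"precluster_genome expects one taxon, got {sorted(taxa)}")
    taxon = next(iter(taxa)) if taxa else "UNKNOWN"

    ordered = sorted(
        range(len(seqs)), key=lambda i: (-len(seqs[i]), i)
    )
    representatives: list[SeqRecord] = []
    mapping: dict[str, str] = {}
    for idx in ordered:
        seq = seqs[idx]
        for rep in representatives:
            identity, coverage = _identity_and_short_coverage(seq, rep, params)
            if identity >= identity_cutoff and coverage >= coverage_cutoff:
                mapping[seq.protein_id] = rep.protein_id
                break
        else:
            representatives.append(seq)
            mapping[seq.protein_id] = seq.protein_id
    return ClusterMap(taxon=taxon, representative=mapping)


def detect_query_taxon(
    hits: list[Hit],
    genome_table: GenomeTable,
    manual_taxon: str | None = None,
    identity_cutoff: float = TAXON_IDENTITY_CUTOFF,
    coverage_cutoff: float = TAXON_COVERAGE_CUTOFF,
) -> str:
    """Infer the query's source organism from its best near-identical hit.

    Scans the (already sorted) hits for the first with >= 97% identity and
    >= 90% query coverage whose subject has a known taxon. A manually
    supplied taxon overrides detection; no qualifying hit yields
    ``UNRESOLVED``.
    """
    if manual_taxon:
        return manual_taxon
    for hit in hits:
        if (
            hit.percent_identity >= identity_cutoff
            and hit.query_coverage >= coverage_cutoff
        ):
            taxon = genome_table.taxon_of(hit.subject_id)
            if taxon is not None:
                return taxon
    return UNRESOLVED


def _top_hit_representative(
    query: SeqRecord,
    genome_seqs: list[SeqRecord],
    cluster_map: ClusterMap,
    params: SearchParams,
    searcher: Searcher,
) -> str | None:
    hits = searcher(query, genome_seqs, params)
    if not hits:
        return None
    return cluster_map.rep(hits[0].subject_id)


def reciprocal_best_hit(
    query: SeqRecord,
    candidate_id: str,
    query_taxon: str,
    genome_table: GenomeTable,
    cluster_maps: dict[str, ClusterMap],
    collection: dict[str, SeqRecord],
    params: SearchParams | None = None,
    searcher: Searcher = search_all,
) -> ReciprocalVerdict:
    """Assess both reciprocal-search directions for one candidate.

    q2h: the query searched against the candidate's genome is true iff
    the top hit's cluster representative equals the candidate's.
    h2q: the candidate searched against the query's genome is true iff
    the top hit's representative equals the query's representative in
    that genome (the query itself when it is a member, otherwise its
    >= 97%/90% match there). A direction is NA (None) when the needed
    genome cannot be resolved.
    """
    params = params or SearchParams()
    if candidate_id not in collection:
        raise KeyError(f"candidate sequence {candidate_id!r} not in collection")
    candidate = collection[candidate_id]

    # --- query -> candidate's genome ---
    cand_taxon = genome_table.taxon_of(candidate_id)
    q2h: Optional[bool]
    if cand_taxon is None or cand_taxon not in cluster_maps:
        q2h = None
    else:
        members = [
            collection[pid]
            for pid in sorted(genome_table.members(cand_taxon))
            if pid in collection and pid != query.protein_id
        ]
        if not members:
            q2h = None
        else:
            cmap = cluster_maps[cand_taxon]
            top_rep = _top_hit_representative(query, members, cmap, params, searcher)
            q2h = top_rep is not None and top_rep == cmap.rep(candidate_id)

    # --- candidate -> query's genome ---
    h2q: Optional[bool]
    if (
        query_taxon == UNRESOLVED
        or query_taxon not in genome_table
        or query_taxon not in cluster_maps
    ):
        h2q = None
    else:
        qmap = cluster_maps[query_taxon]
        members = [
            collection[pid]
            for pid in sorted(genome_table.members(query_taxon))
            if pid in collection
        ]
        if not members:
            h2q = None
        else:
            query_rep = _query_representative(query, members, qmap, params, searcher)
            if query_rep is None:
                h2q = None
            else:
                top_rep = _top_hit_representative(
                    candidate, members, qmap, params, searcher
                )
                h2q = top_rep is not None and top_rep == query_rep

    return ReciprocalVerdict(q2h=q2h, h2q=h2q)


def _query_representative(
    query: SeqRecord,
    genome_seqs: list[SeqRecord],
    cluster_map: ClusterMap,
    params: SearchParams,
    searcher: Searcher,
) -> str | None:
    """The query's stand-in in its own genome: itself when a member, else
    its near-identical (>= 97%/90%) match; None if no such match exists."""
    ids = {s.protein_id for s in genome_seqs}
    if query.protein_id in ids:
        return cluster_map.rep(query.protein_id)
    for hit in searcher(query, genome_seqs, params):
        if (
            hit.percent_identity >= TAXON_IDENTITY_CUTOFF
            and hit.query_coverage >= TAXON_COVERAGE_CUTOFF
        ):
            return cluster_map.rep(hit.subject_id)
    return None
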