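"""Flag which homology hits are reference proteins and attach their evidence.

A reference protein is one that has been experimentally studied, manually
curated, or reported in the literature — operationally, a hit with PubMed
links, Swiss-Prot membership, or a PDB structure. Publications linked to
more than 100 protein records (large-scale studies such as genome
sequencing papers) carry no specific functional information and are
excluded before the PubMed source is granted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AnnotationRecord, Hit, Publication

__all__ = [
    "ReferenceCandidate",
    "identify_references",
    "sort_publications",
    "LARGE_SCALE_PUBLICATION_CUTOFF",
]

# Publications linked to more than this many protein records are dropped.
LARGE_SCALE_PUBLICATION_CUTOFF = 100


@dataclass(frozen=True)
class ReferenceCandidate:
    """A hit granted at least one evidence source.

    ``pubmed_ids`` holds only the publications surviving the large-scale
    exclusion; ``sources`` is a subset of {pubmed, pdb, swissprot}.
    """

    hit: Hit
    sources: frozenset[str]
    pubmed_ids: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("a reference candidate must have at least one source")
        if "pubmed" in self.sources and not self.pubmed_ids:
            raise ValueError("pubmed source requires at least one surviving PubMed id")


def identify_references(
    hits: list[Hit],
    annotations: dict[str, AnnotationRecord],
    publications: dict[str, Publication],
    large_scale_cutoff: int = LARGE_SCALE_PUBLICATION_CUTOFF,
) -> list[ReferenceCandidate]:
    """Select the reference proteins among the hits, preserving hit order.

    Per hit: drop each linked publication with more than
    ``large_scale_cutoff`` linked protein records (strict inequality, so a
    publication linking exactly 100 proteins survives the default); grant
    the pubmed source iff at least one publication survives; grant pdb and
    swissprot from the annotation flags; keep the hit iff at least one
    source was granted. Hits without an annotation record are simply
    unannotated, never an error.
    """
    candidates: list[ReferenceCandidate] = []
    for hit in hits:
        ann = annotations.get(hit.subject_id)
        if ann is None:
            continue
        kept_pmids = frozenset(
            pmid
            for pmid in ann.pubmed_ids
            if publications[pmid].n_linked_proteins <= large_scale_cutoff
        )
        sources = set()
        if kept_pmids:
            sources.add("pubmed")
        if ann.in_pdb:
            sources.add("pdb")
        if ann.in_swissprot:
            sources.add("swissprot")
        if sources:
            candidates.append(
                ReferenceCandidate(
                    hit=hit,
                    sources=frozenset(sources),
                    pubmed_ids=kept_pmids,
                    description=ann.description,
                )
            )
    return candidates


def sort_publications(
    pubmed_ids, publications: dict[str, Publication]
) -> list[Publication]:
    """Order publications newest-first; equal dates break ties by pmid."""
    pubs = [publications[pmid] for pmid in pubmed_ids]
    return sorted(pubs, key=lambda p: (-p.date.toordinal(), p.pmid))
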