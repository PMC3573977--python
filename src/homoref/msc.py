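"""Multiple sequence comparison (MSC): rate a reference protein by how much
of the query's close neighbourhood it matches.

A single pairwise comparison between query and reference can mislead;
comparing the reference against the whole set of sequences closely related
to the query (the close sequence set, N) gives a more robust signal. For
each identity cutoff, the filtered hit ratio is the fraction of close-set
members the reference hits above the cutoff (with a coverage floor); the
reference is accepted at that cutoff when the ratio strictly exceeds 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import Hit, SeqRecord
from .search import SearchParams, align_pair

__all__ = [
    "MscConfig",
    "CloseSet",
    "MscResult",
    "build_close_set",
    "filtered_hit_ratio",
    "msc_evaluate",
]


@dataclass(frozen=True)
class MscConfig:
    """Filters of the MSC procedure.

    close_set_*: filters defining the close sequence set from the query's
    hits. hit_min_coverage: coverage floor (of the reference as query)
    when counting close-set members the reference matches.
    """

    close_set_min_coverage: float = 50.0
    close_set_max_evalue: float = 1e-3
    close_set_cap: int = 250
    hit_min_coverage: float = 50.0
    ratio_threshold: float = 0.8
    identity_cutoffs: tuple[float, ...] = (60.0, 50.0, 40.0)


@dataclass(frozen=True)
class CloseSet:
    """The query's close sequence set; member order follows the hit sort."""

    member_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class MscResult:
    reference_id: str
    ratio_at: dict[float, float]
    accepted_at: dict[float, bool]

    @property
    def n_accepted(self) -> int:
        return sum(self.accepted_at.values())


def build_close_set(
    query_hits: list[Hit],
    query_id: str,
    config: MscConfig | None = None,
) -> CloseSet:
    """Select the close sequence set from the query's sorted hits.

    Members need query coverage >= 50% and e-value <= 1e-3 (defaults);
    the query's own record is excluded so a reference can never inflate
    its ratio via the query itself; the best-sorted 250 are kept.
    An empty close set is legal — downstream MSC scores are then zero.
    """
    config = config or MscConfig()
    members = [
        h.subject_id
        for h in query_hits
        if h.subject_id != query_id
        and h.query_coverage >= config.close_set_min_coverage
        and h.e_value <= config.close_set_max_evalue
    ]
    return CloseSet(member_ids=tuple(members[: config.close_set_cap]))


def _member_matches(
    reference: SeqRecord,
    close_set: CloseSet,
    collection: dict[str, SeqRecord],
    params: SearchParams,
) -> list[tuple[float, float]]:
    """(identity, reference-coverage) of the reference against each member."""
    out = []
    for pid in close_set.member_ids:
        if pid not in collection:
            raise KeyError(f"close-set member {pid!r} missing from collection")
        hit = align_pair(reference, collection[pid], params)
        out.append((hit.percent_identity, hit.query_coverage))
    return out


def filtered_hit_ratio(
    reference: SeqRecord,
    close_set: CloseSet,
    collection: dict[str, SeqRecord],
    identity_cutoff: float,
    params: SearchParams | None = None,
    config: MscConfig | None = None,
) -> float:
    """Fraction of close-set members the reference hits above the filters."""
    config = config or MscConfig()
    params = params or SearchParams()
    if close_set.size == 0:
        return 0.0
    matches = _member_matches(reference, close_set, collection, params)
    count = sum(
        1
        for identity, coverage in matches
        if identity >= identity_cutoff and coverage >= config.hit_min_coverage
    )
    return count / close_set.size


def msc_evaluate(
    reference: SeqRecord,
    close_set: CloseSet,
    collection: dict[str, SeqRecord],
    params: SearchParams | None = None,
    config: MscConfig | None = None,
) -> MscResult:
    """Ratio and strict (> 0.8) acceptance at each identity cutoff.

    Alignments against the close set are computed once and reused across
    cutoffs, so ratios are monotone non-decreasing as the cutoff drops by
    construction.
    """
    config = config or MscConfig()
    params = params or SearchParams()
    if close_set.size == 0:
        ratios = {c: 0.0 for c in config.identity_cutoffs}
    else:
        matches = _member_matches(reference, close_set, collection, params)
        ratios = {}
        for cutoff in config.identity_cutoffs:
            count = sum(
                1
                for identity, coverage in matches
                if identity >= cutoff and coverage >= config.hit_min_coverage
            )
            ratios[cutoff] = count / close_set.size
    accepted = {c: r > config.ratio_threshold for c, r in ratios.items()}
    return MscResult(
        reference_id=reference.protein_id, ratio_at=ratios, accepted_at=accepted
    )
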