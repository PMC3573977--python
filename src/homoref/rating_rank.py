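"""The plurality rating: four homology features summed to a 1-6 score,
result ranking, and the detailed-panel display filter.

Feature maxima are 2 (reciprocal search, +1 per direction, +0.25 when a
direction is unassessable), 1.5 (MSC, +0.5 per accepted identity cutoff),
1.5 (pairwise identity, +0.5 per strict threshold >60/>50/>40 exceeded)
and 1 (reference-protein status). Only reference proteins are rated in the
pipeline, so pipeline totals range from 1 (both directions false, nothing
else) to 6 (everything true).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import Publication
from .msc import MscResult
from .orthology import ReciprocalVerdict
from .reference_identification import ReferenceCandidate

__all__ = [
    "RatingBreakdown",
    "RankedReference",
    "score_reference",
    "rank_results",
    "apply_display_filter",
    "PAIRWISE_IDENTITY_THRESHOLDS",
    "DISPLAY_MIN_SCORE",
]

PAIRWISE_IDENTITY_THRESHOLDS = (60.0, 50.0, 40.0)
DISPLAY_MIN_SCORE = 3.0

_DIRECTION_POINTS = {True: 1.0, False: 0.0, None: 0.25}


@dataclass(frozen=True)
class RatingBreakdown:
    """Per-feature contributions and their total (0.25 granularity, exact)."""

    rb_points: float
    msc_points: float
    pairwise_points: float
    ref_point: float

    @property
    def total(self) -> float:
        return self.rb_points + self.msc_points + self.pairwise_points + self.ref_point


@dataclass(frozen=True)
class RankedReference:
    candidate: ReferenceCandidate
    breakdown: RatingBreakdown
    publications: tuple[Publication, ...]
    rank: int
    verdict: ReciprocalVerdict | None = None


def score_reference(
    verdict: ReciprocalVerdict,
    msc_result: MscResult,
    pairwise_identity: float,
    is_reference: bool = True,
) -> RatingBreakdown:
    """Score one candidate from its four feature inputs.

    Reciprocal directions: true +1, false +0, unassessable (None) +0.25.
    MSC: +0.5 per accepted cutoff. Pairwise identity thresholds are strict
    and cumulative: 65% identity exceeds >60, >50 and >40 and earns all
    three half-points; exactly 60.0 earns only the lower two.
    """
    rb = _DIRECTION_POINTS[verdict.q2h] + _DIRECTION_POINTS[verdict.h2q]
    msc = 0.5 * sum(1 for accepted in msc_result.accepted_at.values() if accepted)
    pairwise = 0.5 * sum(
        1 for t in PAIRWISE_IDENTITY_THRESHOLDS if pairwise_identity > t
    )
    ref = 1.0 if is_reference else 0.0
    return RatingBreakdown(
        rb_points=rb, msc_points=msc, pairwise_points=pairwise, ref_point=ref
    )


def rank_results(scored) -> list[RankedReference]:
    """Order candidates by score (desc), then e-value (asc), then subject id,
    and assign consecutive ranks from 1.

    ``scored`` items are (candidate, breakdown, publications) tuples, with
    an optional fourth element carrying the reciprocal verdict.
    """
    ordered = sorted(
        scored,
        key=lambda item: (
            -item[1].total,
            item[0].hit.e_value,
            item[0].hit.subject_id,
        ),
    )
    out = []
    for i, item in enumerate(ordered, start=1):
        cand, breakdown, pubs = item[0], item[1], item[2]
        verdict = item[3] if len(item) > 3 else None
        out.append(
            RankedReference(
                candidate=cand,
                breakdown=breakdown,
                publications=tuple(pubs),
                rank=i,
                verdict=verdict,
            )
        )
    return out


def apply_display_filter(
    ranked: list[RankedReference], min_score: float = DISPLAY_MIN_SCORE
) -> list[RankedReference]:
    """Keep candidates with total >= min_score, preserving order.

    Scores below 3 indicate distant homologs whose functions may have
    diverged; by default they are omitted from the detailed panel (the
    unfiltered summary table is kept alongside by the caller).
    """
    return [r for r in ranked if r.breakdown.total >= min_score]
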