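"""Benchmark metrics: coverage and average accuracy of the rating system
against a labeled protein collection.

Labels follow the family/subgroup nesting of structure-function
classifications: members of one family share substrate specificity;
members of one subgroup share catalytic machinery, so family truth implies
subgroup truth. Per score cutoff, coverage is the percentage of queries
detecting at least one reference at or above the cutoff, and accuracy is
the mean per-query true-positive rate over exactly those covered queries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

__all__ = [
    "LabeledProtein",
    "BenchmarkRow",
    "read_labels",
    "true_positive_rate",
    "evaluate",
    "write_benchmark_table",
]

Context = Literal["family", "subgroup"]


@dataclass(frozen=True)
class LabeledProtein:
    protein_id: str
    family: str
    subgroup: str


def read_labels(path) -> dict[str, LabeledProtein]:
    """Read a labels TSV (protein_id, family, subgroup) and validate nesting."""
    labels: dict[str, LabeledProtein] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        needed = ["protein_id", "family", "subgroup"]
        missing = [c for c in needed if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
        for row in reader:
            lp = LabeledProtein(
                row["protein_id"].strip(), row["family"].strip(), row["subgroup"].strip()
            )
            labels[lp.protein_id] = lp
    _validate_nesting(labels.values())
    return labels


def _validate_nesting(labels: Iterable[LabeledProtein]) -> None:
    family_to_subgroup: dict[str, str] = {}
    for lp in labels:
        prior = family_to_subgroup.setdefault(lp.family, lp.subgroup)
        if prior != lp.subgroup:
            raise ValueError(
                f"family {lp.family!r} spans subgroups {prior!r} and "
                f"{lp.subgroup!r}; families must nest within subgroups"
            )


@dataclass(frozen=True)
class BenchmarkRow:
    cutoff: float
    coverage: float           # % of queries covered at this cutoff
    family_accuracy: float    # % mean TPR, same-family context
    subgroup_accuracy: float  # % mean TPR, same-subgroup context


def true_positive_rate(
    query_label: LabeledProtein,
    hits_above_cutoff: Sequence[str],
    labels: Mapping[str, LabeledProtein],
    context: Context,
) -> float:
    """Fraction of hits sharing the query's family (or subgroup)."""
    if not hits_above_cutoff:
        raise ValueError("true_positive_rate needs at least one hit")
    matched = 0
    for pid in hits_above_cutoff:
        if pid not in labels:
            raise KeyError(f"hit {pid!r} has no label; benchmark aborted")
        lp = labels[pid]
        if context == "family":
            matched += lp.family == query_label.family
        elif context == "subgroup":
            matched += lp.subgroup == query_label.subgroup
        else:
            raise ValueError(f"unknown context {context!r}")
    return matched / len(hits_above_cutoff)


def evaluate(
    per_query_results: Mapping[str, Sequence[tuple[str, float]]],
    labels: Mapping[str, LabeledProtein],
    cutoffs: Sequence[float],
) -> list[BenchmarkRow]:
    """Compute one benchmark row per score cutoff.

    ``per_query_results`` maps each tested query id to its scored
    reference hits as (subject_id, rating_score) pairs. The cutoff
    comparison is inclusive (score >= cutoff). Queries with no hit at or
    above a cutoff count against coverage but are excluded from the
    accuracy average at that cutoff.
    """
    if not per_query_results:
        raise ValueError("evaluate needs at least one query")
    for qid in per_query_results:
        if qid not in labels:
            raise KeyError(f"query {qid!r} has no label")

    rows: list[BenchmarkRow] = []
    n_queries = len(per_query_results)
    for cutoff in cutoffs:
        fam_rates: list[float] = []
        sub_rates: list[float] = []
        covered = 0
        for qid, scored_hits in per_query_results.items():
            above = [pid for pid, score in scored_hits if score >= cutoff]
            if not above:
                continue
            covered += 1
            qlabel = labels[qid]
            fam_rates.append(true_positive_rate(qlabel, above, labels, "family"))
            sub_rates.append(true_positive_rate(qlabel, above, labels, "subgroup"))
        rows.append(
            BenchmarkRow(
                cutoff=cutoff,
                coverage=100.0 * covered / n_queries,
                family_accuracy=100.0 * sum(fam_rates) / len(fam_rates)
                if fam_rates
                else 0.0,
                subgroup_accuracy=100.0 * sum(sub_rates) / len(sub_rates)
                if sub_rates
                else 0.0,
            )
        )
    return rows


def write_benchmark_table(rows: list[BenchmarkRow], path) -> None:
    """Write benchmark rows as a TSV shaped like the classic score/accuracy/coverage table."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["score", "subgroup_accuracy", "family_accuracy", "coverage"])
        for row in rows:
            writer.writerow(
                [
                    f"{row.cutoff:g}",
                    f"{row.subgroup_accuracy:.1f}",
                    f"{row.family_accuracy:.1f}",
                    f"{row.coverage:.1f}",
                ]
            )
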