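"""End-to-end orchestration: detect homologs, identify references, assess
orthology and MSC, score, rank, filter, and write reports."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .io_formats import (
    GenomeTable,
    SeqRecord,
    read_fasta,
    read_sidecar_tables,
    write_report,
)
from .msc import MscConfig, build_close_set, msc_evaluate
from .orthology import (
    UNRESOLVED,
    ClusterMap,
    detect_query_taxon,
    precluster_genome,
    reciprocal_best_hit,
)
from .rating_rank import (
    DISPLAY_MIN_SCORE,
    RankedReference,
    apply_display_filter,
    rank_results,
    score_reference,
)
from .reference_identification import identify_references, sort_publications
from .search import SearchParams, search_all

__all__ = ["RunConfig", "PipelineResult", "run", "write_results_table"]

logger = logging.getLogger("homoref")

RESULTS_COLUMNS = [
    "rank",
    "subject_id",
    "rating_score",
    "rb_points",
    "msc_points",
    "pairwise_points",
    "ref_point",
    "q2h",
    "h2q",
    "e_value",
    "percent_identity",
    "query_coverage",
    "sources",
    "pubmed_ids",
]


@dataclass
class RunConfig:
    """Inputs and knobs of one pipeline run."""

    query_path: str
    collection_path: str
    links_path: str
    pubs_path: str
    genomes_path: str
    output_dir: str = "."
    backend: str = "builtin"
    manual_taxon: str | None = None
    search: SearchParams = field(default_factory=SearchParams)
    msc: MscConfig = field(default_factory=MscConfig)
    display_min_score: float = DISPLAY_MIN_SCORE
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "search" in data:
            data["search"] = SearchParams(**data["search"])
        if "msc" in data:
            msc = dict(data["msc"])
            if "identity_cutoffs" in msc:
                msc["identity_cutoffs"] = tuple(msc["identity_cutoffs"])
            data["msc"] = MscConfig(**msc)
        return cls(**data)


@dataclass
class PipelineResult:
    query: SeqRecord
    query_taxon: str
    ranked: list[RankedReference]        # full summary, sorted
    displayed: list[RankedReference]     # display-filtered detail view
    report_tsv: Path | None = None
    report_html: Path | None = None
    results_tsv: Path | None = None


def _verdict_str(value) -> str:
    return "na" if value is None else ("true" if value else "false")


def write_results_table(ranked: list[RankedReference], path) -> None:
    """Machine-readable per-candidate table with the full rating breakdown."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RESULTS_COLUMNS)
        for item in ranked:
            b = item.breakdown
            hit = item.candidate.hit
            writer.writerow(
                [
                    item.rank,
                    hit.subject_id,
                    f"{b.total:.2f}",
                    f"{b.rb_points:.2f}",
                    f"{b.msc_points:.2f}",
                    f"{b.pairwise_points:.2f}",
                    f"{b.ref_point:.2f}",
                    _verdict_str(item.verdict.q2h) if item.verdict else "",
                    _verdict_str(item.verdict.h2q) if item.verdict else "",
                    f"{hit.e_value:.6g}",
                    f"{hit.percent_identity:.2f}",
                    f"{hit.query_coverage:.2f}",
                    ",".join(sorted(item.candidate.sources)),
                    ";".join(p.pmid for p in item.publications),
                ]
            )


def run(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline and write the report files.

    Workflow: homolog search -> reference identification (step 1), then
    reciprocal-search and MSC evaluation feeding the rating system
    (step 2), ranking and the display filter, and finally report output.
    Zero homologs or zero references is a valid empty result.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    query = read_fasta(config.query_path)[0]
    records = read_fasta(config.collection_path)
    annotations, publications, genome_table = read_sidecar_tables(
        config.links_path, config.pubs_path, config.genomes_path
    )
    # the explicit genome table wins over any taxon= header key
    records = [
        rec
        if genome_table.taxon_of(rec.protein_id) is None
        else SeqRecord(
            rec.protein_id,
            rec.residues,
            rec.description,
            genome_table.taxon_of(rec.protein_id),
        )
        for rec in records
    ]
    collection = {r.protein_id: r for r in records}
    params = config.search

    # --- step 1: detect homologs, identify references ---
    hits = search_all(query, records, params)
    logger.info("step 1: homolog search found %d hits", len(hits))
    candidates = identify_references(hits, annotations, publications)
    logger.info("step 1: %d reference protein(s) identified", len(candidates))

    if config.manual_taxon:
        query_taxon = config.manual_taxon
        logger.info("query taxon set manually: %s (detection bypassed)", query_taxon)
    else:
        query_taxon = detect_query_taxon(hits, genome_table)
        logger.info("query taxon detected: %s", query_taxon)

    # --- step 2: homology evaluation ---
    needed_taxa = {query_taxon} if query_taxon != UNRESOLVED else set()
    for cand in candidates:
        taxon = genome_table.taxon_of(cand.hit.subject_id)
        if taxon is not None:
            needed_taxa.add(taxon)
    cluster_maps: dict[str, ClusterMap] = {}
    for taxon in sorted(needed_taxa):
        if taxon not in genome_table:
            continue
        seqs = [
            collection[pid]
            for pid in sorted(genome_table.members(taxon))
            if pid in collection
        ]
        cluster_maps[taxon] = precluster_genome(seqs, params)
        logger.info(
            "preclustered genome %s: %d sequence(s), %d cluster(s)",
            taxon,
            len(seqs),
            len(set(cluster_maps[taxon].representative.values())),
        )

    close_set = build_close_set(hits, query.protein_id, config.msc)
    logger.info("step 2: close sequence set N=%d", close_set.size)

    scored = []
    verdicts = {}
    for cand in candidates:
        sid = cand.hit.subject_id
        verdict = reciprocal_best_hit(
            query,
            sid,
            query_taxon,
            genome_table,
            cluster_maps,
            collection,
            params,
        )
        msc_result = msc_evaluate(
            collection[sid], close_set, collection, params, config.msc
        )
        breakdown = score_reference(
            verdict, msc_result, cand.hit.percent_identity, is_reference=True
        )
        pubs = tuple(sort_publications(cand.pubmed_ids, publications))
        scored.append((cand, breakdown, pubs, verdict))
        verdicts[sid] = verdict

    ranked = rank_results(scored)
    displayed = apply_display_filter(ranked, config.display_min_score)
    logger.info(
        "step 2: %d candidate(s) scored, %d above display threshold",
        len(ranked),
        len(displayed),
    )
    if not ranked:
        logger.warning("no reference proteins found for %s", query.protein_id)

    report_tsv = outdir / "report.tsv"
    report_html = outdir / "report.html"
    results_tsv = outdir / "results.tsv"
    write_report(ranked, report_tsv, "tsv")
    write_report(ranked, report_html, "html", detail=displayed)
    write_results_table(ranked, results_tsv)

    return PipelineResult(
        query=query,
        query_taxon=query_taxon,
        ranked=ranked,
        displayed=displayed,
        report_tsv=report_tsv,
        report_html=report_html,
        results_tsv=results_tsv,
    )
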