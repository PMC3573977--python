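"""Readers and writers for the formats the pipeline consumes and emits.

Sequences travel as FASTA; pairwise hits as BLAST tabular (outfmt 6, or a
14-column extension appending qlen and slen); per-protein annotation
evidence as three TSV sidecar tables (literature links, publication
metadata, genome membership); results as a TSV summary table plus an HTML
report with per-protein rating detail.
"""

from __future__ import annotations

import csv
import datetime
import html as _html
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "Hit",
    "AnnotationRecord",
    "Publication",
    "GenomeTable",
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "read_sidecar_tables",
    "write_report",
    "UNKNOWN_TAXON",
]

UNKNOWN_TAXON = "UNKNOWN"

# 20 standard residues plus X (unknown).
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_RESIDUES = AMINO_ACIDS | {"X"}


@dataclass(frozen=True)
class SeqRecord:
    """A protein sequence with its identifier, free-text description and taxon."""

    protein_id: str
    residues: str
    description: str = ""
    taxon: str = UNKNOWN_TAXON

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence for {self.protein_id!r} is empty")
        bad = set(self.residues) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"sequence for {self.protein_id!r} contains non-amino-acid "
                f"characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Hit:
    """One pairwise homology match between a query and a subject sequence.

    ``query_coverage`` is the percentage of the *query* sequence spanned by
    the local alignment; identity is per aligned column (gaps included in
    the denominator, the BLAST tabular convention).
    """

    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float
    e_value: float
    bit_score: float
    aln_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity out of range: {self.percent_identity}")
        if not 0.0 <= self.query_coverage <= 100.0:
            raise ValueError(f"query_coverage out of range: {self.query_coverage}")
        if self.e_value < 0:
            raise ValueError(f"e_value must be non-negative: {self.e_value}")


@dataclass(frozen=True)
class AnnotationRecord:
    """Evidence flags for one protein: literature links, Swiss-Prot and PDB membership."""

    protein_id: str
    pubmed_ids: frozenset[str] = frozenset()
    in_swissprot: bool = False
    in_pdb: bool = False
    description: str = ""


@dataclass(frozen=True)
class Publication:
    """Publication metadata: date and how many protein records cite it globally."""

    pmid: str
    date: datetime.date
    n_linked_proteins: int

    def __post_init__(self) -> None:
        if self.n_linked_proteins < 1:
            raise ValueError(f"n_linked_proteins must be >= 1 for {self.pmid}")


class GenomeTable:
    """Mapping from taxon to the set of protein ids it contains.

    Every protein belongs to at most one taxon; membership is queried in
    both directions (``members`` / ``taxon_of``).
    """

    def __init__(self, mapping: dict[str, set[str]] | None = None) -> None:
        self._by_taxon: dict[str, set[str]] = {}
        self._by_protein: dict[str, str] = {}
        if mapping:
            for taxon, ids in mapping.items():
                for pid in ids:
                    self.add(pid, taxon)

    def add(self, protein_id: str, taxon: str) -> None:
        prior = self._by_protein.get(protein_id)
        if prior is not None and prior != taxon:
            raise ValueError(
                f"protein {protein_id!r} assigned to two taxa: {prior!r} and {taxon!r}"
            )
        self._by_protein[protein_id] = taxon
        self._by_taxon.setdefault(taxon, set()).add(protein_id)

    def members(self, taxon: str) -> set[str]:
        return set(self._by_taxon.get(taxon, set()))

    def taxon_of(self, protein_id: str) -> str | None:
        return self._by_protein.get(protein_id)

    def taxa(self) -> list[str]:
        return sorted(self._by_taxon)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._by_taxon

    def __len__(self) -> int:
        return len(self._by_taxon)


def _parse_taxon(description: str) -> str:
    for token in description.split():
        if token.startswith("taxon="):
            value = token[len("taxon="):]
            if value:
                return value
    return UNKNOWN_TAXON


def read_fasta(path) -> list[SeqRecord]:
    """Read a protein FASTA file.

    The first whitespace-delimited header token is the protein id; an
    optional ``taxon=<name>`` key in the remaining description sets the
    taxon. Residues are uppercased; stop (``*``) and gap (``-``)
    characters are stripped; other non-amino-acid characters raise.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein_id in {path}: {pid!r}")
        seen.add(pid)
        description = rec.description[len(rec.id):].strip()
        residues = str(rec.seq).upper().replace("*", "").replace("-", "")
        records.append(
            SeqRecord(
                protein_id=pid,
                residues=residues,
                description=description,
                taxon=_parse_taxon(description),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = rec.description
            if rec.taxon != UNKNOWN_TAXON and "taxon=" not in desc:
                desc = (desc + f" taxon={rec.taxon}").strip()
            header = f">{rec.protein_id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def read_hit_table(path) -> list[Hit]:
    """Parse a BLAST tabular hit file (outfmt 6).

    Accepts the 12-column standard layout or a 14-column extension with
    qlen and slen appended. Query coverage is derived as
    100*(qend-qstart+1)/qlen (1-based inclusive coordinates), so 12-column
    input, which lacks qlen, is rejected.
    """
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 12:
                raise ValueError(
                    f"{path}:{lineno}: coverage underivable from 12-column "
                    "output; regenerate with qlen/slen appended "
                    "(outfmt '6 std qlen slen')"
                )
            if len(fields) != 14:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 14 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                qlen = int(fields[12])
                hit = Hit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    query_coverage=100.0 * (qend - qstart + 1) / qlen,
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                    aln_length=int(fields[3]),
                )
            except (ValueError, ZeroDivisionError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            hits.append(hit)
    return hits


def _require_columns(reader: csv.DictReader, needed: list[str], path) -> None:
    have = reader.fieldnames or []
    missing = [c for c in needed if c not in have]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {have}")


def read_sidecar_tables(
    links_path, pubs_path, genomes_path
) -> tuple[dict[str, AnnotationRecord], dict[str, Publication], GenomeTable]:
    """Read the three annotation sidecar TSVs and cross-validate them.

    links:   protein_id, pubmed_ids (semicolon-joined, may be empty),
             in_swissprot, in_pdb, description
    pubs:    pmid, date (YYYY-MM-DD), n_linked_proteins
    genomes: protein_id, taxon

    Every PubMed id cited in links must exist in pubs.
    """
    publications: dict[str, Publication] = {}
    with open(pubs_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(reader, ["pmid", "date", "n_linked_proteins"], pubs_path)
        for row in reader:
            pmid = row["pmid"].strip()
            publications[pmid] = Publication(
                pmid=pmid,
                date=datetime.date.fromisoformat(row["date"].strip()),
                n_linked_proteins=int(row["n_linked_proteins"]),
            )

    annotations: dict[str, AnnotationRecord] = {}
    with open(links_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(
            reader,
            ["protein_id", "pubmed_ids", "in_swissprot", "in_pdb", "description"],
            links_path,
        )
        for row in reader:
            pid = row["protein_id"].strip()
            raw = row["pubmed_ids"].strip()
            pmids = frozenset(p for p in raw.split(";") if p) if raw else frozenset()
            dangling = pmids - publications.keys()
            if dangling:
                raise ValueError(
                    f"{links_path}: protein {pid!r} cites unknown PubMed "
                    f"id(s) {sorted(dangling)} absent from {pubs_path}"
                )
            annotations[pid] = AnnotationRecord(
                protein_id=pid,
                pubmed_ids=pmids,
                in_swissprot=row["in_swissprot"].strip() in ("1", "true", "True"),
                in_pdb=row["in_pdb"].strip() in ("1", "true", "True"),
                description=row["description"].strip(),
            )

    genome_table = GenomeTable()
    with open(genomes_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(reader, ["protein_id", "taxon"], genomes_path)
        for row in reader:
            genome_table.add(row["protein_id"].strip(), row["taxon"].strip())

    return annotations, publications, genome_table


REPORT_COLUMNS = [
    "rank",
    "subject_id",
    "description",
    "rating_score",
    "e_value",
    "percent_identity",
    "query_coverage",
    "sources",
    "pubmed_ids",
]

_SOURCE_ORDER = ["pubmed", "pdb", "swissprot"]


def _report_row(ranked) -> list[str]:
    cand = ranked.candidate
    hit = cand.hit
    sources = ",".join(s for s in _SOURCE_ORDER if s in cand.sources)
    pmids = ";".join(p.pmid for p in ranked.publications)
    return [
        str(ranked.rank),
        hit.subject_id,
        cand.description,
        f"{ranked.breakdown.total:.2f}",
        f"{hit.e_value:.3g}",
        f"{hit.percent_identity:.1f}",
        f"{hit.query_coverage:.1f}",
        sources,
        pmids,
    ]


def write_report(ranked, path, format: str = "tsv", detail=None) -> None:
    """Write the ranked reference-protein report.

    ``ranked`` is the already-sorted summary list (never re-sorted here);
    ``detail``, when given, is the display-filtered subset rendered as
    per-protein rating-breakdown blocks in the HTML report.
    """
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(REPORT_COLUMNS)
            for item in ranked:
                writer.writerow(_report_row(item))
    elif format == "html":
        _write_html_report(ranked, path, detail if detail is not None else ranked)
    else:
        raise ValueError(f"unknown report format: {format!r}")


def _write_html_report(ranked, path, detail) -> None:
    esc = _html.escape
    rows = []
    for item in ranked:
        cells = "".join(f"<td>{esc(v)}</td>" for v in _report_row(item))
        rows.append(f"<tr>{cells}</tr>")
    header = "".join(f"<th>{esc(c)}</th>" for c in REPORT_COLUMNS)

    blocks = []
    for item in detail:
        b = item.breakdown
        pubs = "".join(
            f"<li>{esc(p.pmid)} ({p.date.isoformat()})</li>" for p in item.publications
        )
        blocks.append(
            "<div class='detail'>"
            f"<h3>#{item.rank} {esc(item.candidate.hit.subject_id)} "
            f"&mdash; score {b.total:.2f}</h3>"
            f"<p>{esc(item.candidate.description)}</p>"
            "<ul>"
            f"<li>reciprocal search: {b.rb_points:.2f} / 2.00</li>"
            f"<li>multiple sequence comparison: {b.msc_points:.2f} / 1.50</li>"
            f"<li>pairwise identity: {b.pairwise_points:.2f} / 1.50</li>"
            f"<li>reference protein: {b.ref_point:.2f} / 1.00</li>"
            "</ul>"
            f"<ol>{pubs}</ol>"
            "</div>"
        )
    doc = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>Reference protein report</title>"
        "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:2px 6px}.detail{margin:1em 0;border-top:1px solid #ccc}</style>"
        "</head><body>"
        "<h1>Ranked reference proteins</h1>"
        f"<table><tr>{header}</tr>{''.join(rows)}</table>"
        "<h2>Details</h2>"
        f"{''.join(blocks)}"
        "</body></html>"
    )
    with open(path, "w") as fh:
        fh.write(doc)
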