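"""Homology search: a built-in Smith-Waterman backend and a BLAST+ adapter.

The built-in backend aligns with Biopython's ``PairwiseAligner`` (local
mode, substitution matrix + affine gaps) and attaches BLAST-style
statistics. E-values use the ungapped BLOSUM62 Karlin-Altschul constants
applied to the gapped score — a crude calibration, but monotone in the
alignment score, which is all the pipeline needs (e-values are used only
for ranking and set-membership filters, never as calibrated probabilities).
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import Hit, SeqRecord, read_hit_table, write_fasta

__all__ = ["SearchParams", "align_pair", "search_all", "external_search"]

# Ungapped BLOSUM62 Karlin-Altschul constants (natural-log units).
_LAMBDA = 0.318
_K = 0.13


@dataclass(frozen=True)
class SearchParams:
    """Knobs of a homology search; defaults mirror blastp conventions."""

    e_value_cutoff: float = 1e-3
    max_hits: int = 500
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.e_value_cutoff < 0:
            raise ValueError("e_value_cutoff must be non-negative")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    try:
        matrix = substitution_matrices.load(params.matrix_name)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix: {params.matrix_name!r}") from exc
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # BLAST convention: a gap of length k costs open + k*extend.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _stats_from_score(score: float, m: int, n: int) -> tuple[float, float]:
    bit_score = (_LAMBDA * score - math.log(_K)) / math.log(2)
    e_value = m * n * 2.0 ** (-bit_score)
    return bit_score, e_value


def align_pair(a: SeqRecord, b: SeqRecord, params: SearchParams | None = None) -> Hit:
    """Best local alignment of ``a`` (query) against ``b`` (subject) as a Hit.

    Identity is per aligned column (gaps count in the denominator);
    coverage is the aligned span over the query length. A non-positive
    optimal score means no local similarity: reported as identity 0,
    coverage 0, bit score 0 and e-value m*n (the search-space size).
    """
    params = params or SearchParams()
    aligner = _make_aligner(params)
    m, n = len(a), len(b)
    # align in a canonical orientation so co-optimal alignment choice (and
    # hence identity) is independent of argument order
    flip = (b.residues, b.protein_id) < (a.residues, a.protein_id)
    first, second = (b, a) if flip else (a, b)
    score = aligner.score(first.residues, second.residues)
    if score <= 0:
        return Hit(a.protein_id, b.protein_id, 0.0, 0.0, float(m * n), 0.0, 0)

    alignment = aligner.align(first.residues, second.residues)[0]
    counts = alignment.counts()
    identities = counts.identities
    # local alignments have no terminal gaps; columns = matches + internal gaps
    aln_length = counts.identities + counts.mismatches + counts.internal_gaps
    qblocks = alignment.aligned[1 if flip else 0]
    query_span = qblocks[-1][1] - qblocks[0][0]
    bit_score, e_value = _stats_from_score(score, m, n)
    return Hit(
        query_id=a.protein_id,
        subject_id=b.protein_id,
        percent_identity=100.0 * identities / aln_length,
        query_coverage=100.0 * query_span / m,
        e_value=e_value,
        bit_score=bit_score,
        aln_length=aln_length,
    )


def hit_sort_key(hit: Hit):
    """Canonical hit order: e-value up, bit score down, subject id up."""
    return (hit.e_value, -hit.bit_score, hit.subject_id)


def search_all(
    query: SeqRecord, db: list[SeqRecord], params: SearchParams | None = None
) -> list[Hit]:
    """Search ``query`` against every database sequence.

    Returns hits passing the e-value cutoff, in canonical order, truncated
    to ``max_hits``. The query's own record, if present in the database, is
    a legitimate (self-)hit.
    """
    params = params or SearchParams()
    hits = [align_pair(query, subject, params) for subject in db]
    hits = [h for h in hits if h.e_value <= params.e_value_cutoff]
    hits.sort(key=hit_sort_key)
    return hits[: params.max_hits]


def external_search(
    query: SeqRecord,
    db_path,
    params: SearchParams | None = None,
    executable: str = "blastp",
) -> list[Hit]:
    """Search with an external BLAST+ executable against a formatted database.

    Requests tabular output with qlen/slen appended so coverage is
    derivable, then applies the same filter/sort contract as
    :func:`search_all`.
    """
    params = params or SearchParams()
    if shutil.which(executable) is None:
        raise FileNotFoundError(
            f"{executable!r} not found on PATH; install NCBI BLAST+ or use "
            "the built-in search backend (backend='builtin')"
        )
    with tempfile.TemporaryDirectory() as tmp:
        query_path = Path(tmp) / "query.fasta"
        out_path = Path(tmp) / "hits.tsv"
        write_fasta([query], query_path)
        subprocess.run(
            [
                executable,
                "-query", str(query_path),
                "-db", str(db_path),
                "-outfmt", "6 std qlen slen",
                "-evalue", str(params.e_value_cutoff),
                "-max_target_seqs", str(params.max_hits),
                "-matrix", params.matrix_name,
                "-gapopen", str(params.gap_open),
                "-gapextend", str(params.gap_extend),
                "-out", str(out_path),
            ],
            check=True,
            capture_output=True,
            text=True,
        )
        hits = read_hit_table(out_path)
    hits = [h for h in hits if h.e_value <= params.e_value_cutoff]
    hits.sort(key=hit_sort_key)
    return hits[: params.max_hits]
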