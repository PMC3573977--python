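"""Deterministic synthetic multi-genome protein collections with known
ortholog/paralog structure, annotations and publications.

The generator emulates the homology structure the pipeline assumes: per
family one ancestor sequence, per genome one ortholog descended from it at
a controlled identity, and — for designated families — a duplicated
(paralog) lineage that diverged from the family ancestor before the
genomes split. The paralog lineage is present in every genome the family
spans, so a paralog is never the best reciprocal hit in either direction:
its own within-lineage ortholog always beats it. Designated reference
proteins carry publications (including one large-scale publication linking
>100 protein records, to exercise the exclusion rule), Swiss-Prot and PDB
flags; decoys are unrelated random sequences.

All randomness is seeded; identical (config, seed) gives byte-identical
output files.
"""

from __future__ import annotations

import datetime
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .io_formats import (
    AnnotationRecord,
    GenomeTable,
    Publication,
    SeqRecord,
    write_fasta,
)
from .benchmark import LabeledProtein

__all__ = ["FixtureConfig", "FixtureSet", "TruthEntry", "mutate_sequence", "generate_fixture"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureConfig:
    """Shape and divergence levels of a synthetic collection.

    Identity targets are percent identity relative to the immediate
    ancestor; orthologs diverge little (default 90%), the paralog lineage
    diverged substantially at duplication (default 55%). ``family_sizes``
    gives the number of genomes each family spans (default: all).
    """

    seed: int
    n_genomes: int = 3
    n_families: int = 4
    family_sizes: tuple[int, ...] | None = None
    ortholog_identity_target: float = 90.0
    paralog_identity_target: float = 55.0
    decoy_count: int = 2
    mega_publication_size: int = 150
    sequence_length: int = 200
    paralog_families: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if not 0 < self.ortholog_identity_target <= 100:
            raise ValueError("ortholog_identity_target must be in (0, 100]")
        if not 0 < self.paralog_identity_target <= 100:
            raise ValueError("paralog_identity_target must be in (0, 100]")
        if self.family_sizes is not None:
            if len(self.family_sizes) != self.n_families:
                raise ValueError(
                    f"family_sizes has {len(self.family_sizes)} entries for "
                    f"{self.n_families} families"
                )
            if any(s < 1 or s > self.n_genomes for s in self.family_sizes):
                raise ValueError("each family size must be in [1, n_genomes]")
        if any(f < 0 or f >= self.n_families for f in self.paralog_families):
            raise ValueError("paralog_families indices out of range")

    def spans(self) -> tuple[int, ...]:
        if self.family_sizes is not None:
            return tuple(self.family_sizes)
        return tuple(self.n_genomes for _ in range(self.n_families))


@dataclass(frozen=True)
class TruthEntry:
    """One planted relationship and its expected reciprocal verdicts.

    ``expected_q2h``/``expected_h2q`` use "true"/"false"/"na"; for
    ortholog pairs the verdict is assessed with ``a`` as query and ``b``
    as candidate (and holds symmetrically by construction).
    """

    kind: str  # ortholog_pair | paralog_pair | decoy
    a: str
    b: str
    expected_q2h: str
    expected_h2q: str


@dataclass
class FixtureSet:
    """In-memory fixture plus writers for the on-disk sidecar formats."""

    config: FixtureConfig
    records: list[SeqRecord]
    annotations: dict[str, AnnotationRecord]
    publications: dict[str, Publication]
    genome_table: GenomeTable
    labels: dict[str, LabeledProtein]
    truth: list[TruthEntry]
    query_id: str

    @property
    def collection(self) -> dict[str, SeqRecord]:
        return {r.protein_id: r for r in self.records}

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "collection.fasta",
            "links": outdir / "links.tsv",
            "pubs": outdir / "pubs.tsv",
            "genomes": outdir / "genomes.tsv",
            "labels": outdir / "labels.tsv",
            "truth": outdir / "truth.tsv",
            "query": outdir / "query.fasta",
        }
        write_fasta(self.records, paths["fasta"])
        write_fasta([self.collection[self.query_id]], paths["query"])
        with open(paths["links"], "w") as fh:
            fh.write("protein_id\tpubmed_ids\tin_swissprot\tin_pdb\tdescription\n")
            for pid in sorted(self.annotations):
                a = self.annotations[pid]
                fh.write(
                    f"{pid}\t{';'.join(sorted(a.pubmed_ids))}\t"
                    f"{int(a.in_swissprot)}\t{int(a.in_pdb)}\t{a.description}\n"
                )
        with open(paths["pubs"], "w") as fh:
            fh.write("pmid\tdate\tn_linked_proteins\n")
            for pmid in sorted(self.publications):
                p = self.publications[pmid]
                fh.write(f"{pmid}\t{p.date.isoformat()}\t{p.n_linked_proteins}\n")
        with open(paths["genomes"], "w") as fh:
            fh.write("protein_id\ttaxon\n")
            for rec in self.records:
                fh.write(f"{rec.protein_id}\t{rec.taxon}\n")
        with open(paths["labels"], "w") as fh:
            fh.write("protein_id\tfamily\tsubgroup\n")
            for pid in sorted(self.labels):
                lp = self.labels[pid]
                fh.write(f"{pid}\t{lp.family}\t{lp.subgroup}\n")
        with open(paths["truth"], "w") as fh:
            fh.write("kind\ta\tb\texpected_q2h\texpected_h2q\n")
            for t in self.truth:
                fh.write(
                    f"{t.kind}\t{t.a}\t{t.b}\t{t.expected_q2h}\t{t.expected_h2q}\n"
                )
        return paths


def mutate_sequence(seq: str, target_identity: float, seed: int) -> str:
    """Substitute round(len*(1-target/100)) seeded-random positions.

    Sites are chosen without replacement; each replacement is drawn
    uniformly from the 19 alternative residues, so length and substitution
    count are exact (realized alignment identity can wobble slightly when
    the aligner finds coincidental matches).
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target_identity must be in (0, 100]")
    rng = random.Random(seed)
    n_sub = round(len(seq) * (1.0 - target_identity / 100.0))
    positions = rng.sample(range(len(seq)), n_sub)
    residues = list(seq)
    for pos in positions:
        alternatives = _AA.replace(residues[pos], "")
        residues[pos] = rng.choice(alternatives)
    return "".join(residues)


def _random_sequence(length: int, rng: random.Random) -> str:
    return "".join(rng.choice(_AA) for _ in range(length))


def generate_fixture(config: FixtureConfig, outdir=None) -> FixtureSet:
    """Build the collection, sidecar tables, labels and truth table.

    The designated query is the family-0 ortholog in genome g0. Reference
    annotations go to family members outside the query's genome; one extra
    protein carries only the large-scale publication, and the query's
    closest ortholog cites it alongside its specific publications.
    """
    rng = random.Random(config.seed)
    spans = config.spans()
    L = config.sequence_length

    genomes = [f"g{g}" for g in range(config.n_genomes)]
    records: list[SeqRecord] = []
    labels: dict[str, LabeledProtein] = {}
    truth: list[TruthEntry] = []

    # family members: fam index -> list of (protein_id, genome)
    members: dict[str, list[tuple[str, str]]] = {}

    def _derive(parent: str, identity: float) -> str:
        return mutate_sequence(parent, identity, rng.randrange(2**31))

    for f in range(config.n_families):
        subgroup = f"S{f // 2}"
        ancestor = _random_sequence(L, rng)
        lineages = [(f"f{f}", ancestor)]
        if f in config.paralog_families:
            lineages.append(
                (f"f{f}p", _derive(ancestor, config.paralog_identity_target))
            )
        for lineage_name, lineage_ancestor in lineages:
            fam_label = lineage_name.upper()
            members[lineage_name] = []
            for g in range(spans[f]):
                pid = f"{lineage_name}_{genomes[g]}"
                residues = _derive(lineage_ancestor, config.ortholog_identity_target)
                records.append(
                    SeqRecord(
                        protein_id=pid,
                        residues=residues,
                        description=f"synthetic {fam_label} member",
                        taxon=genomes[g],
                    )
                )
                labels[pid] = LabeledProtein(pid, fam_label, subgroup)
                members[lineage_name].append((pid, genomes[g]))

    for d in range(config.decoy_count):
        pid = f"decoy{d}"
        taxon = genomes[d % config.n_genomes]
        records.append(
            SeqRecord(
                protein_id=pid,
                residues=_random_sequence(L, rng),
                description="synthetic unrelated decoy",
                taxon=taxon,
            )
        )
        labels[pid] = LabeledProtein(pid, f"D{d}", f"SD{d}")

    genome_table = GenomeTable()
    for rec in records:
        genome_table.add(rec.protein_id, rec.taxon)

    query_id = "f0_g0"
    query_genome = "g0"

    # --- truth table ---
    for lineage_name, mem in members.items():
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                truth.append(
                    TruthEntry("ortholog_pair", mem[i][0], mem[j][0], "true", "true")
                )
    for f in config.paralog_families:
        para = members.get(f"f{f}p", [])
        for pid, genome in members[f"f{f}"]:
            for ppid, pgenome in para:
                if genome == pgenome:
                    # within one genome the paralog trivially is the best
                    # remaining hit; only cross-genome pairs are confounded
                    continue
                # searching either member against the other's genome finds
                # the within-lineage ortholog first, never the paralog
                truth.append(TruthEntry("paralog_pair", pid, ppid, "false", "false"))

    # --- annotations & publications ---
    publications: dict[str, Publication] = {}
    annotations: dict[str, AnnotationRecord] = {}
    mega_pmid = "PM9999"
    publications[mega_pmid] = Publication(
        pmid=mega_pmid,
        date=datetime.date(2015, 6, 1),
        n_linked_proteins=config.mega_publication_size,
    )

    pub_counter = 0

    def _new_pubs(n: int) -> frozenset[str]:
        nonlocal pub_counter
        out = set()
        for _ in range(n):
            pmid = f"PM{1000 + pub_counter:04d}"
            date = datetime.date(2005, 1, 1) + datetime.timedelta(
                days=(137 * pub_counter) % 5800
            )
            publications[pmid] = Publication(
                pmid=pmid, date=date, n_linked_proteins=1 + (pub_counter % 7) * 10
            )
            out.add(pmid)
            pub_counter += 1
        return frozenset(out)

    reference_ids = [
        pid
        for lineage_name, mem in sorted(members.items())
        for pid, genome in mem
        if genome != query_genome
    ]
    for i, pid in enumerate(reference_ids):
        pmids = _new_pubs(1 + i % 3)
        if pid == "f0_g1":
            # cites the large-scale study alongside its specific papers
            pmids = pmids | {mega_pmid}
        annotations[pid] = AnnotationRecord(
            protein_id=pid,
            pubmed_ids=pmids,
            in_swissprot=(i % 2 == 0),
            in_pdb=(i % 3 == 0),
            description=f"characterized protein {pid}",
        )
    # one protein linked ONLY to the large-scale publication: never a
    # reference candidate despite having a literature link
    mega_only = "f1_g1"
    if mega_only in {r.protein_id for r in records}:
        annotations[mega_only] = AnnotationRecord(
            protein_id=mega_only,
            pubmed_ids=frozenset({mega_pmid}),
            in_swissprot=False,
            in_pdb=False,
            description=f"genome-survey protein {mega_only}",
        )

    fixture = FixtureSet(
        config=config,
        records=records,
        annotations=annotations,
        publications=publications,
        genome_table=genome_table,
        labels=labels,
        truth=truth,
        query_id=query_id,
    )
    if outdir is not None:
        fixture.write(outdir)
    return fixture


def load_fixture_config(path) -> FixtureConfig:
    """Read a FixtureConfig from a YAML/JSON-style key: value file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(FixtureConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown fixture config key(s): {sorted(unknown)}")
    for key in ("family_sizes", "paralog_families"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return FixtureConfig(**data)
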