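# homoref

Homology-based identification and rating of **reference proteins** — the
experimentally characterized, literature-linked or manually curated
homologs of a query protein — against a locally annotated sequence
collection.

Most protein sequences are annotated only by automatic transfer, which is
error-prone (paralog/ortholog confusion, multi-domain artifacts, stale
descriptions). Reliable functional interpretation should instead lean on
homologs that were actually studied: proteins with linked PubMed
publications, Swiss-Prot entries or PDB structures. `homoref` finds those
homologs for a query, evaluates how trustworthy each one's relationship to
the query is, and ranks them so the most transferable annotations come
first. It is aimed at anyone triaging proteins of unknown function —
curators, structural genomics groups, bench scientists picking references
for experimental design.

## Method

For a query sequence *q* against a collection with annotation sidecar
tables:

1. **Homolog detection.** Smith–Waterman local alignment (BLOSUM62,
   affine gaps 11/1) of *q* against every collection sequence; hits are
   kept at E ≤ 10⁻³. An adapter to an external BLAST+ installation is
   available for large collections.
2. **Reference identification.** A hit is a reference protein if it has
   (i) PubMed links — excluding publications associated with more than
   100 protein records, which are large-scale surveys carrying no specific
   functional signal — (ii) a PDB structure, or (iii) a Swiss-Prot entry.
3. **Reciprocal best hits (RB).** Each genome is greedily preclustered at
   97% identity / 90% coverage so near-identical gene variants cannot
   break best-hit equality; the query's taxon is auto-detected from its
   first ≥97%/≥90% hit (or given manually). Both search directions are
   assessed at the cluster-representative level.
4. **Multiple sequence comparison (MSC).** The close sequence set *N* of
   the query (coverage ≥ 50%, E ≤ 10⁻³, capped at 250) is searched with
   each reference as query; the *filtered hit ratio* is the fraction of
   members matched at identity ≥ c and coverage ≥ 50%. The reference is
   accepted at cutoff c ∈ {60, 50, 40}% iff the ratio exceeds 0.8.
5. **Plurality rating.** Score = RB (+1 per true direction, +0.25 per
   unassessable one; max 2) + MSC (+0.5 per accepted cutoff; max 1.5) +
   pairwise identity (+0.5 per strict threshold >60/>50/>40%; max 1.5) +
   reference status (+1). Totals run 1–6 for reference proteins; results
   are ranked by score, then E-value, and candidates under 3 are dropped
   from the detailed panel (distant homologs whose function may have
   diverged).

A benchmark module scores any labeled collection with nested
family/subgroup labels: per score cutoff, *coverage* (% of queries with a
reference at or above the cutoff) and *accuracy* (mean per-query
true-positive rate among covered queries, in family or subgroup context).

## Worked example

Generate a synthetic collection (3 genomes × 4 families, one duplicated
paralog lineage, planted reference annotations) and run the pipeline:

```
homoref simulate --seed 1 --out fx
homoref run --query fx/query.fasta --collection fx/collection.fasta \
    --links fx/links.tsv --pubs fx/pubs.tsv --genomes fx/genomes.tsv \
    --out results --log-level WARNING
cat results/report.tsv
```

Output (abridged; also written as `report.html` with per-protein rating
breakdowns, and `results.tsv` with every feature subtotal):

```
rank  subject_id  description                  rating_score  e_value   percent_identity  query_coverage
1     f0_g1       characterized protein f0_g1  5.00          5e-117    81.4              99.5
2     f0_g2       characterized protein f0_g2  5.00          1.8e-116  80.5              100.0
3     f0p_g1      characterized protein f0p_g1 2.00          1.2e-44   45.2              98.5
4     f0p_g2      characterized protein f0p_g2 2.00          1.3e-41   44.8              100.0
```

The two true orthologs of the query score 5.00 (reciprocal best hits both
ways, identity > 60%, MSC accepted at the 40% cutoff, reference status);
the two paralog-lineage members score 2.00 — they fail both reciprocal
directions because each genome's real ortholog outranks them — and fall
below the display threshold of 3, exactly the behaviour that protects
against paralog-driven annotation transfer.

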