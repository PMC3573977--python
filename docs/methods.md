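# Methods

## Problem and model

Annotation transfer from a homolog is only as good as the evidence behind
the homolog and the evidence for the homologous relationship. `homoref`
separates the two: *reference identification* asks whether a hit carries
experimental or curated evidence at all (PubMed links, Swiss-Prot, PDB),
and the *plurality rating* asks how confidently annotations can be moved
across the relationship. The rating deliberately combines four partially
redundant views of the same relationship — reciprocal best hits, multiple
sequence comparison, raw pairwise identity, and reference status — rather
than a single calibrated statistic: it is an intuitive indicator of
similarity level, not a probabilistic predictor of shared function.

## Homology search backend

The built-in backend is Smith–Waterman local alignment via Biopython's
`PairwiseAligner` (BLOSUM62; gap of length k costs 11 + k·1). Statistics:

- identity = identities / aligned columns (gaps included), in %;
- query coverage = aligned query span / query length, in % — coverage is
  always of the *query of the respective search* (the RB and MSC steps
  each search with a different sequence as query);
- bit score = (λ·S − ln K)/ln 2 with the **ungapped** BLOSUM62 constants
  λ = 0.318, K = 0.13 applied to the gapped score, and
  E = m·n·2^(−bit). This is a documented approximation: it is monotone in
  the raw score, and the pipeline uses E-values only for rank ordering and
  set-membership filters, where monotonicity suffices. A non-positive
  optimal score is reported as an empty hit (identity 0, coverage 0, bit
  0, E = m·n).

Only the single best local alignment per pair is scored; multi-domain
proteins with several strong HSPs are a known limitation. Among co-optimal
alignments the backend picks one in a canonical orientation of the pair,
so identity is exactly symmetric and runs are deterministic. An external
BLAST+ adapter (`outfmt "6 std qlen slen"`) exists for real-scale
collections; the built-in backend is the reference implementation the
tests oracle against (an independent plain-Python Gotoh DP).

Default search parameters: E cutoff 10⁻³, 500 hits max. The upstream
interface exposes these without fixed published defaults; 10⁻³ is the
conventional "clearly homologous" threshold and keeps decoys out of toy
collections.

## Reference identification

Publications linked to more than 100 protein records are dropped
per-publication (strict >100: exactly 100 survives), so a protein keeps
its specific literature even when one genome-survey paper is removed; the
protein itself is dropped only when no evidence source survives.
Publication lists are sorted newest-first (ties by PubMed id): the most
recent experimental study is usually the one not yet reflected in
database annotations, which is the main reason to look for references.

## Orthology

Greedy preclustering (longest-first; join the first representative matched
at ≥97% identity with ≥90% coverage of the shorter sequence) collapses
alleles and near-identical variants; the coverage denominator is the
shorter sequence, the convention of the standard greedy clustering tools.
Best-hit equality in both reciprocal directions is tested at the cluster-
representative level. Each direction is assessed independently; a
direction whose genome cannot be resolved (unknown query taxon, candidate
absent from the genome table, empty genome) is NA and earns +0.25 rather
than 0 — lack of evidence is not evidence of non-orthology. The query's
own record is excluded from the query-to-hit-genome target set only by
protein id: a sequence-identical but distinct record is a legitimate best
hit.

## MSC filter choices

The close-set filters (coverage ≥ 50%, E ≤ 10⁻³, cap 250) and the
counting filter (identity ≥ cutoff, coverage ≥ 50%) are package defaults,
all config-exposed (`MscConfig`). Rationale: permissive enough that a
query inside a family populates N with the whole family, strict enough
that the ratio measures family membership rather than incidental domain
sharing. Acceptance is strictly ratio > 0.8; with N = 0 all MSC points
are 0 (no NA state exists for MSC). Alignments against the close set are
computed once per reference and reused across cutoffs, which also makes
ratio monotonicity in the cutoff structural rather than numerical.

## Rating details

Pairwise-identity rows are strict and cumulative: identity 65% earns
+0.5 for each of >60, >50, >40; exactly 60.0 earns only the lower two.
Totals are sums of multiples of 0.25 — no rounding anywhere; reports
format with two decimals. Ranking is score desc, E-value asc, subject id
asc (the final tie-break is a determinism guarantee, not a biological
statement). The display filter drops totals < 3 from the detailed panel
while the summary table stays unfiltered.

## Benchmark metrics

Cutoff comparison is inclusive (score ≥ c). Coverage is context-free;
accuracy is averaged only over covered queries. Unlabeled hits abort the
run rather than being dropped silently — benchmark integrity over
convenience. Family accuracy ≤ subgroup accuracy is an invariant because
family labels nest within subgroups (validated at load).

## Synthetic collections

The generator emulates multi-genome ortholog families: per family one
i.i.d.-uniform ancestor (length 200, no indels by default so substitution
counts are exact), per genome one descendant with exactly
round(L·(1−t/100)) substitutions at t = 90%. Paralogs are modelled as a
duplicated lineage: a paralog ancestor at t = 55% from the family
ancestor, then per-genome descent at 90%. Because the lineage exists in
*every* genome the family spans, a paralog candidate loses both
reciprocal directions to the true within-lineage ortholog — which is the
confounder structure that matters for annotation transfer. Realized
pairwise identities are ~81% between orthologs and ~45–50% between a
query and a paralog-lineage member (two independent descents compound the
per-branch targets). One publication links 150 protein records to
exercise the large-scale exclusion; reference annotations go to family
members outside the query's genome.

What the fixtures do **not** emulate: indels and length variation
(config-gated off by default), rate heterogeneity across sites, domain
architecture, biased residue composition, and real database-scale hit
lists. Passing tests therefore demonstrate correctness of the decision
logic and scoring arithmetic under controlled divergence — not
performance on real proteomes, where alignment quality and annotation
noise dominate.

## Problem sizes and determinism

The default test collection is 17 sequences of length 200 (4 families × 3
genomes + 3 paralogs + 2 decoys); a full pipeline run is a few hundred
pairwise alignments and completes in under a second. All randomness
(sequence generation, mutation sites) flows from a single integer seed;
identical (config, seed) regenerates byte-identical fixture files, and two
pipeline runs on identical inputs produce byte-identical reports.

## Known limitations

- Single-HSP scoring: multi-domain proteins can be over- or under-rated.
- The Karlin–Altschul approximation makes absolute E-values of the
  built-in backend incomparable to BLAST's; only their order matters.
- NA scoring (+0.25/direction) floors an unresolvable candidate at 1.5,
  so an unresolved genome slightly boosts weak candidates relative to
  resolved-but-false ones; this mirrors the rating table's intent.
- The benchmark reproduces metric definitions, not any published survey
  of a real superfamily, which would require the full public databases.
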