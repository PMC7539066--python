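# Methods

This note defines the statistical and algorithmic choices behind each
analysis stage, the construction of the synthetic-data generator, and
the known limitations. Coordinates are 1-based and inclusive
throughout; an intron spans `(prev_exon.end + 1, next_exon.start − 1)`.

## Gene models and annotation I/O

A `TranscriptModel` holds strictly increasing, non-overlapping,
non-abutting exons (abutting exons would imply a zero-length intron and
are rejected — a merged exon is the correct representation), an
optional CDS span, and a strand; a `GeneModel` requires all transcripts
to share chromosome and strand. GTF and GFF3 parsing is delegated to
`gffutils` (in-memory database) and FASTA I/O to Biopython; parse
errors report the offending line number. Spliced sequences are
assembled 5′→3′ in transcript orientation (reverse-complemented on the
minus strand).

## Alternative-splicing events

Events follow the SUPPA taxonomy and are detected from all ordered
pairs of a gene's isoforms:

- **IR** — one isoform's exon spans both exons flanking an intron of
  the other; the signature is the retained intron's genomic span. A
  single-exon transcript can participate as the retaining partner.
- **ES** — an internal exon of one isoform lies strictly inside an
  intron of the other, with both flanking splice junctions shared.
- **A5 / A3** — the two isoforms share one boundary of an intron but
  differ at the other; the exons flanking the differing boundary must
  overlap (otherwise the variation is a terminal-exon event, below).
  A5 varies the donor (5′, transcript orientation), A3 the acceptor.
- **AF / AL** — distinct first (last) exons, each with its own
  flanking intron, splicing to a common downstream (upstream)
  boundary. Both partners need at least two exons, since the
  definition requires the terminal exon's own intron.
- **MX** — two internal exons, one per isoform, each skipped by the
  other isoform, non-overlapping, with shared outer junctions.

Signatures are canonical genomic coordinate tuples, so the same event
discovered from several pairs deduplicates to one record whose
inclusion/exclusion transcript sets are unions over pairs; a
transcript seen on the inclusion side is removed from the exclusion
side, and events whose exclusion side empties are dropped. A gene is
"AS" if it owns at least one event; the AS-gene percentage and
per-type event percentages are reported to two decimals (plain
rounding).

## PTC classification of retained-intron isoforms

The gene's *reference ORF* is the annotated CDS of a non-retaining
isoform when present (CDS spans include the stop codon), otherwise the
longest ATG-initiated ORF in that isoform's spliced sequence. For an
expressed retaining isoform, the reference start codon is mapped
through genomic coordinates into the retaining isoform's transcript
coordinates and translation proceeds codon by codon along its spliced
sequence. The isoform is **PTC+** iff the first in-frame stop lies
strictly upstream, in transcript orientation, of the position where
the reference stop maps; otherwise **PTC−**. This captures both stop
codons inside the retained intron and frameshifts caused by intron
lengths not divisible by three, while introns retained downstream of
the stop (3′ UTR) are PTC−. The classical NMD heuristic — stop more
than 50 nt upstream of the last exon–exon junction — is computed as an
auxiliary flag, not the verdict. Only isoforms passing the expression
filter (FPKM ≥ 1 in at least one tissue mean) are classified.

## Splice-site profiling

For every intron the first two and last two bases are read in
transcript orientation (minus-strand introns are reverse-complemented),
yielding a donor–acceptor pair such as GT–AG. Counts are tallied for
AS genes, non-AS genes, and all genes; by default every transcript's
introns count (so an intron shared by isoforms is counted per
transcript), with a `unique_introns` mode that counts each genomic
intron once per gene. Group totals always sum to the "all" total
within a mode. Percentages are reported to two decimals.

## Gene-structure features

Per-gene statistics (exon count, mean/total exon length, mean intron
length, gene span, isoform count) are computed on a representative
isoform (most exons, ties by identifier); intron metrics are NaN for
single-exon representatives. Group comparisons report median,
quartiles and a Mann–Whitney U test (SciPy). Transcripts that carry AS
events but no ORF of at least 100 codons are flagged as lncRNA
candidates.

## Expression

FPKM matrices are validated against a tissue→samples map. Tissue means
average replicates; presence is mean ≥ threshold (default 1.0) and is
monotone non-increasing in the threshold. A transcript involved in AS
is *tissue-specific* if present in exactly one tissue. Variance
filtering keeps the top fraction of rows by sample variance of the
supplied values (the pipeline applies it to FPKM before
log-transforming the retained rows), with the kept count rounded up
and ties broken by row id.

## Signed coexpression network

On log10(FPKM + 1) values: Pearson correlation `cor`, signed adjacency
`a_ij = ((1 + cor_ij)/2)^β`. The soft threshold is chosen as the
smallest β in the candidate grid whose scale-free model fit R² exceeds
0.8 (falling back to the best fit), or is supplied explicitly.
Topological overlap is

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with k the connectivity (row sum minus the diagonal), TOM_ii = 1.
Modules come from average-linkage hierarchical clustering of the TOM
dissimilarity (1 − TOM) with a static cut. When no height is given,
the cut is placed at the midpoint of the largest gap between
successive merge heights — a deterministic surrogate for dynamic tree
cutting; degenerate trees whose merge heights span less than 1e-9 are
treated as one cluster. Clusters below `min_size` get label 0
(unassigned). Hubs are, per module, the top ⌈0.10·size⌉ genes by
within-module weighted degree (adjacency row sum over the module,
excluding self).

## Synthetic-data generator

`simulate_bundle(config, outdir)` writes a genome FASTA, a GTF,
transcript- and gene-level FPKM tables, a tissue map, and truth tables
(planted events, splice sites, PTC statuses, module labels, hubs,
tissue-specific transcripts). All randomness flows from one
`numpy.random.default_rng(seed)` stream; identical configurations
produce byte-identical bundles.

- **Counts by largest remainder.** The number of AS genes is
  `round(fraction_as · n_genes)`; per-type event counts and the
  canonical/noncanonical splice-site split are integer allocations of
  the configured proportions by the largest-remainder method, so
  realized counts are exact, deterministic functions of the
  configuration.
- **Event planting.** Each AS gene gets a two-isoform pair whose
  second isoform is a coordinate edit of the first chosen to realize
  exactly one event of the assigned type (intron kept in the mature
  form for IR, internal exon dropped for ES, boundary shifted within
  the flanking exon for A5/A3, alternative terminal exon plus intron
  for AF/AL, swapped internal exons for MX). Planted events are
  emitted in the same canonical form the enumerator produces.
- **Splice sites.** Intron ends are written GT…AG, except introns
  drawn (largest remainder) for the noncanonical quota, which receive
  a non-GT/non-AG pair. Only introns whose terminal positions are not
  shared across isoforms and that are not engineered retained introns
  are eligible for the noncanonical quota, so no genomic base is
  assigned twice.
- **PTC truth.** Retained introns are built as GT + C-fill + AG with
  length divisible by three; PTC+ introns additionally carry an
  in-frame TAA. Exonic bases adjacent to donors avoid creating
  spurious GT junctions. Reference CDS spans (including the stop) are
  written to the GTF so classification uses the annotated ORF.
- **Expression.** Module eigengenes are per-module tissue profiles
  with replicate jitter, Gram–Schmidt-orthogonalized across modules so
  between-module correlation is exactly zero by construction. Module
  members are `√r·eigengene + √(1−r)·noise` (default within-module
  correlation r = 0.8); each module's designated hub gene carries the
  eigengene itself, making its expected within-module connectivity
  maximal. Values are mapped to non-negative FPKM through a
  monotone transform; tissue-specific transcripts get FPKM above
  threshold in one tissue and below in all others.

## Numerical choices

- Percentages use round-half-even to two decimals (Python `round`).
- Correlations, adjacency and TOM use float64 throughout; TOM tests
  compare against a brute-force triple-loop oracle at atol 1e-12.
- Largest-remainder ties break by the stable ordering of the category
  names, so allocations are deterministic.
- Seeds derived from user-facing seeds are reduced modulo 2³¹.

## Limitations

- The generator plants one event per AS gene and two isoforms per
  gene; real catalogs have richer per-gene event co-occurrence.
- The noncanonical splice-site quota is applied uniformly, so the
  AS-vs-non-AS difference in canonical proportions seen in real
  surveys is not emulated — only the overall planted fraction is.
- AF/AL events require both partners to have at least two exons; a
  single-exon isoform participates only as the retaining partner of an
  IR event.
- The static largest-gap tree cut is a simplification of dynamic tree
  cutting; on empirical data with gradual merge-height profiles an
  explicit cut height (or a different module detector) may be
  preferable.
- PTC classification assumes the reference start codon maps into the
  retaining isoform; isoforms that splice out the start are not
  classified.
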