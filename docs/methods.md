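# Methods

`guidescreen` designs sgRNA libraries for focused CRISPR knockout screens:
given a genome, gene models and a query list of up to 1000 genes, it returns
up to 30 ranked guides per gene. This note documents the model behind each
score, the selection procedure, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Candidate discovery

A candidate is any occurrence of `N{L}-NGG` (L = 19 or 20, canonical SpCas9
PAM only — NAG sites are excluded) on either genomic strand whose
protospacer interval overlaps the merged exons of the query gene. The exon
union over all isoforms defines the searchable region; overlap is judged on
the protospacer, so a PAM may hang off an exon end. Spacers containing `N`
(assembly gaps) are dropped silently. Coordinates are 0-based half-open on
the reference strand throughout; GFF3 and VCF inputs are converted at the
parse boundary, BED12 and bedGraph are native.

The cut site is placed 3 bp 5′ of the PAM (the blunt SpCas9 cut between
protospacer positions 17/18 of a 20-mer). It anchors exon attribution: a
guide "targets" whichever exon contains its cut site.

## The four ranking criteria

**Efficiency** — a positional-linear model over the spacer plus flanking
context (default 10 nt each side): score = intercept + Σ w(position, base).
This is the functional form of LASSO-derived sequence activity models; the
coefficients are pluggable via a TSV file (`position`, `nucleotide`,
`weight` rows plus an `#intercept` header). The shipped default is an
illustrative, non-negative-weight model intended for testing the machinery,
not a trained predictor — users with a trained coefficient set drop it in
via `--efficiency-model`. Guides whose context window runs off the
chromosome end are unscorable and are filtered (reason `UNSCORABLE`).

**Specificity** — off-target loci are enumerated exhaustively: every
NGG-adjacent window on either strand within `max_mismatch` (default 3)
Hamming mismatches of the spacer, over the whole assembly. The search is a
vectorised brute-force scan, exact by construction; it is intended for
desk-scale genomes (the regime of the bundled fixtures — up to ~100 kb runs
in well under a minute; an index structure could be added behind the same
interface for larger assemblies). Each off-target h is scored

    s_h = Π_{p ∈ mismatches} (1 − W[p]) × 1 / (((19 − d̄)/19)·4 + 1) × 1/n²

with W the published per-position mismatch penalty vector (PAM-distal
position 0; for 19-mers the PAM-distal entry is dropped), d̄ the mean
pairwise distance between mismatch positions (set to 19 when n < 2, making
the distance factor 1) and n the mismatch count; a perfect match scores
s_h = 1. The aggregate specificity is

    S = 100 · 100 / (100 + 100·Σ_h s_h)  ∈ [0, 100],

which is 100 exactly when the guide has no off-target hits. Hits overlapping
the query gene's own span are on-target (a guide may legitimately match
several isoform copies of its locus) and excluded from the sum.

**Conservation** — the arithmetic mean of per-base conservation scores
(e.g. phastCons, supplied as bedGraph, scores in [0, 1]) over the
protospacer interval. Bases not covered by the track count 0, so sparse
tracks remain averageable; with no track supplied every guide scores 0 and
the criterion becomes constant (and hence weightless, see below).

**Isoform commonality** — the fraction of the gene's transcripts whose
exons contain the guide's cut site, in (0, 1]. A guide whose cut site falls
in an intron while its protospacer straddles into an exon inherits the
maximum position-wise fraction over the overlapped exonic bases. Guides
cutting exons shared by all isoforms score 1 and are preferred, since they
knock out every isoform.

## Variant annotation

SNPs with minor allele frequency **strictly greater than 0.05** (the floor
is configurable; the comparison is strict, so AF = 0.05 is ignored) are
annotated onto any guide whose footprint contains them. The footprint
defaults to spacer+PAM — a PAM-disrupting variant abolishes cutting — and
can be narrowed to the spacer alone. Somatic loci (a user-supplied
chrom/pos/alt table) are annotated unconditionally but only *count* in the
filter when `--avoid-somatic` is set. VCF allele frequencies are read from
a configurable INFO key (default `AF`) and rounded to 6 decimals to undo
float32 representation noise before the strict comparison; records lacking
the key are skipped with a warning.

## Filter and rescue

Per gene, a candidate is removed iff any of:

1. its footprint overlaps a retained SNP (or somatic locus, when avoided);
2. its spacer is **more than 40%** guanine (strict: 8/20 G passes, 9/20
   fails; the comparison is done in integers, 5·#G > 2·L);
3. its efficiency score is **below zero** (strict: 0.0 passes);
4. it has a perfect-match off-target outside its own gene.

Candidates failing *only* rule 4 form the rescue pool, partitioned by the
worst region class among their perfect hits (coding exon ≻ non-coding exon ≻
intergenic, where a gene is "coding" if any transcript carries a CDS). All
violated rules are recorded, and every candidate lands in exactly one of
passed / filtered / rescue pool.

Survivors are ranked by a summary score S_i = Σ_j w_j · x̃_ij over the four
min-max-normalised criteria, with weights from the **CRITIC** method
(criteria importance through intercriteria correlation): after
normalisation, C_j = σ_j · Σ_k (1 − r_jk) combines each criterion's contrast
(sample standard deviation σ_j) with its conflict with the others (Pearson
correlations r_jk), and w_j = C_j / Σ C. Weights are therefore per-gene and
data-driven: a criterion that is constant within a gene (σ = 0) gets zero
weight, and duplicated criteria share shrunken weight. A `critic-conflict
product` option aggregates the conflict terms multiplicatively,
Π_{k≠j} (1 − r_jk), instead of summing; the sum form of the original CRITIC
formulation is the default. Degenerate cases fall back to uniform weights
(0.25 each): fewer than 3 candidates (correlation is meaningless) or Σ C = 0
(all criteria constant). Undefined correlations against a constant column
are set to 0.

If fewer than the requested n guides pass, the rescue step readmits pool
members: all intergenic-hit guides before any non-coding-exon-hit guide
before any coding-exon-hit guide; within a category ascending by
perfect-hit count, ties broken by descending summary score. Rescue-phase
summary scores are computed on the pooled (passed + rescue pool) criteria
matrix so the two phases are comparable; the passed guides' reported scores
come from the passed-only matrix that produced their ranking. Final output
is passed guides (descending summary score) followed by rescued guides (in
rescue order), truncated to n. Equal summary scores are broken by ascending
(chrom, start, strand), making the whole pipeline deterministic; a gene
with too few designable guides yields a short block and a warning, not an
error.

## Library assembly

Each selected guide becomes one TSV row (rank, coordinates, spacer, PAM,
the four criterion values, summary score, the weight vector used, status,
variant/off-target summaries). Optionally the spacer is embedded in a
synthesis-ready oligo, promoter + spacer + scaffold; the shipped defaults
are the standard human U6 promoter and SpCas9 scaffold, replaceable via a
key-value config. A `force_5prime_g` flag prepends a G to spacers lacking
one (U6 initiates transcription best on G). Negative and positive control
spacers are appended as `CTRL_NEG` / `CTRL_POS` rows with blank scores; the
shipped control files are synthetic placeholders (labelled as such) — real
screens should supply validated safe-harbor and essential-gene guides.
Floats are printed at 4 decimals and output is byte-stable.

## Request caps

At most 1000 genes per request, 1 to 30 guides per gene, spacer length 19
or 20 — validated before any file is opened. Gene IDs resolve
case-insensitively, symbol first, then transcript ID; unresolvable IDs are
warnings, not errors.

## Synthetic fixtures

`guidescreen makefixture` generates, deterministically per seed, a two-
chromosome genome (~16 kb gene-bearing + 8 kb gene-free), five coding genes
of 4–6 exons and 2–4 isoforms, one non-coding gene, and planted structure
with a written truth table: exact protospacer+PAM duplications in each of
the three off-target region classes, SNPs inside guide footprints at allele
frequencies 0.20 and 0.01 (straddling the floor), a somatic locus inside a
guide, and 1 kb piecewise-constant conservation blocks. Planted spacers are
constructed with ≤ 7 G so they can only fail the filters they are planted
to fail; the default efficiency model's non-negative weights likewise keep
them clear of the efficiency floor. These sizes keep a full five-gene
design under a second while exercising every decision branch.

The fixture establishes that the decision logic is exact — filters,
categories, weights, ordering and determinism. It does not establish
predictive performance on real genomes: random sequence lacks repeat
families (real off-target landscapes are far denser), the shipped
efficiency model is not trained, and conservation blocks are arbitrary.
Those limitations are properties of the test data, not the pipeline, which
consumes real FASTA/GFF3/VCF/bedGraph inputs identically.

## Known limitations

- Off-target enumeration is O(genome × candidates); practical for focused
  fixtures and small custom references, not for whole mammalian genomes
  without an added index.
- Only NGG PAMs and ungapped (mismatch-only) off-targets are modelled; no
  bulge or alternative-nuclease support.
- Efficiency prediction quality is entirely determined by the user-supplied
  coefficient file.
- Conservation is consumed, never computed; no liftover between assemblies.
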