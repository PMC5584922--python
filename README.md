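# guidescreen

Batch sgRNA library design for **focused CRISPR knockout screens** — screens
that target a curated set of up to ~1000 genes rather than the whole genome.
Given a reference genome (FASTA), gene models with isoforms (GFF3 or BED12)
and a gene list, `guidescreen` discovers every candidate guide over each
gene's exons, scores it on four criteria, removes empirically bad guides,
and returns a ranked, synthesis-ready library table.

Intended users: labs assembling pooled libraries for validation screens,
pathway-focused screens or in vivo screens, who need many genes processed
in one run with reproducible, criteria-aware guide selection.

## The method

For each gene, every protospacer+PAM occurrence (`N₁₉/₂₀-NGG`, either
strand) overlapping the gene's merged exons is a candidate, scored on:

| criterion | definition |
|---|---|
| efficiency | positional-linear sequence model over spacer + 10 nt flanks (pluggable coefficients) |
| specificity | `100·100 / (100 + 100·Σₕ sₕ)` over enumerated off-target loci h, with per-hit `sₕ = Π(1−W[p]) · 1/(((19−d̄)/19)·4+1) · 1/n²` |
| conservation | mean per-base conservation (e.g. phastCons bedGraph) over the protospacer |
| isoform commonality | fraction of the gene's transcripts whose exons contain the cut site |

Hard filters remove guides that (1) overlap a SNP with MAF > 0.05 (or a
somatic locus, on request), (2) exceed 40% guanine content, (3) score below
zero efficiency, or (4) have perfect-match off-targets. Survivors are
ranked by the summary score `Sᵢ = Σⱼ wⱼ·x̃ᵢⱼ` over the min-max-normalised
criteria, with per-gene **CRITIC** weights `wⱼ ∝ σⱼ·Σₖ(1−rⱼₖ)` — contrast
times conflict, so the weights adapt to each gene's score distributions.
If too few guides survive, rule-(4) casualties are *rescued* in increasing
off-target severity: intergenic hits first, then non-coding-exon hits, then
coding-exon hits; fewer hits first; summary score breaking ties. See
`docs/methods.md` for the full account.

## Worked example

No downloads are needed — the package generates a complete synthetic
reference (genome, multi-isoform gene models, SNPs, somatic loci,
conservation track) with planted, truth-annotated structure:

```bash
guidescreen makefixture --seed 11 -o fx
printf 'GENE1\nGENE2\nGENE3\n' > genes.txt
guidescreen design --genome fx/genome.fa --annotation fx/genes.gff3 \
    --genes genes.txt --n-per-gene 4 \
    --snps fx/snps.vcf --somatic fx/somatic.tsv --avoid-somatic \
    --conservation fx/conservation.bedGraph -o library.tsv
```

which logs one summary line per gene:

```
INFO gene GENE1: 121 candidates, 113 passed, 7 filtered, 1 rescuable, 4 selected
INFO gene GENE2: 121 candidates, 113 passed, 7 filtered, 1 rescuable, 4 selected
INFO gene GENE3: 125 candidates, 122 passed, 1 filtered, 2 rescuable, 4 selected
INFO wrote 12 library rows to library.tsv
```

GENE1's exons contain 121 NGG-adjacent spacers; 7 violated a hard filter,
1 had a perfect off-target match (rescuable had the gene come up short),
and the top 4 of the 113 clean guides were selected. The library table
begins:

```
gene_id rank chrom start strand spacer               efficiency specificity conservation commonality summary_score status
GENE1   1    chr1  1241  -      GATCTCGAGGCCGCCAGGCG 0.4400     100.0000    0.9000       1.0000      1.0000        PASSED
GENE1   2    chr1  1070  -      GCTATCTTCGAGGCTCGGTG 0.4100     100.0000    0.9000       1.0000      0.9832        PASSED
GENE1   3    chr1  1246  -      GTGCCGATCTCGAGGCCGCC 0.4100     100.0000    0.9000       1.0000      0.9832        PASSED
GENE1   4    chr1  1228  +      GCATAATCAACCCCGCCTGG 0.3900     100.0000    0.9000       1.0000      0.9720        PASSED
```

All four guides are unique in the genome (specificity 100), sit in a
conserved block (0.9) shared by every isoform (commonality 1), so the
per-gene CRITIC weights load on the only criteria that vary — the ranking
here follows efficiency, and the summary score is the weighted combination
rescaled to [0, 1] within the gene. Add `--append-construct` to emit full
U6-promoter + spacer + scaffold oligos, and
`--controls-neg/--controls-pos` to append control rows.

The same pipeline is available as a library —
`guidescreen.pipeline.run_design(DesignRequest(...), "library.tsv")` — with
each stage (`reference_io`, `candidates`, `scoring`, `ranking`, `assembly`)
usable on its own.

## Input formats

- genome: FASTA (gzip ok), alphabet A/C/G/T/N
- gene models: GFF3 (`gene`/`mRNA`/`exon`/`CDS`) or BED12 (name
  `gene:transcript`; coding iff thickStart < thickEnd)
- SNPs: VCF with an allele-frequency INFO key (default `AF`)
- somatic loci: TSV `chrom  pos(1-based)  alt`
- conservation: bedGraph, scores in [0, 1]
- efficiency model / specificity penalties / controls / construct: small
  TSV/key-value files, formats in `docs/methods.md` and the shipped
  examples under `src/guidescreen/data/`

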