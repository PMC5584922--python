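"""Seeded synthetic fixture generator with planted ground truth.

Emulates the reference data the designer consumes — a genome, multi-isoform
gene models, SNPs with allele frequencies, somatic loci and a conservation
track — with *planted structure* whose expected pipeline outcome is known
and written to a truth table:

* exact protospacer+PAM duplications placed in intergenic space, in a
  non-coding gene's exon, and in another coding gene's exon (the three
  off-target severity categories of the rescue step);
* SNPs inside guide footprints at allele frequencies above and below the
  0.05 floor, and a somatic locus inside a third guide;
* multi-isoform genes giving fractional isoform-commonality values.

Everything is a pure function of the spec (same seed, same bytes). What the
fixture does *not* emulate: real genomes' repeat structure and base
composition, linkage between variants, and empirically calibrated
conservation — it exercises the decision logic, not biological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Parameters of the planted fixture.

    Sizes are chosen so that a full multi-gene design runs in seconds while
    every decision branch of the pipeline is exercised: 5 coding genes of
    4-6 exons and 2-4 isoforms each on a 16 kb chromosome, one non-coding
    gene, an 8 kb gene-free chromosome for intergenic planting, SNP allele
    frequencies straddling the 0.05 floor, and 1 kb piecewise-constant
    conservation blocks.
    """

    seed: int = 0
    n_coding_genes: int = 5
    isoform_range: tuple[int, int] = (2, 4)
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_len: tuple[int, int] = (140, 220)
    intron_len: tuple[int, int] = (90, 180)
    gene_gap: tuple[int, int] = (350, 650)
    chrom2_len: int = 8000
    spacer_len: int = 20
    snp_maf_above: float = 0.20
    snp_maf_below: float = 0.01
    background_mafs: tuple[float, ...] = (0.30, 0.051, 0.05, 0.04, 0.01)
    conservation_block: int = 1000
    conservation_scores: tuple[float, ...] = (0.1, 0.9, 0.4, 0.7, 0.2, 0.6)


@dataclass
class PlantedGuide:
    gene_id: str
    chrom: str
    start: int  # protospacer interval, + strand
    end: int
    spacer: str
    commonality: float
    expected: str  # truth label
    kind: str


@dataclass
class FixtureTruth:
    guides: list[PlantedGuide] = field(default_factory=list)


def _random_spacer(rng: np.random.Generator, length: int) -> str:
    """Random spacer with at most 7 G (clear of the 40% filter) and a
    positive default efficiency score by construction."""
    while True:
        s = "".join(rng.choice(BASES, size=length))
        if s.count("G") <= 7 and "N" not in s:
            return s


class _GeneBuilder:
    def __init__(self, gene_id: str, chrom: str, start: int, rng, spec: SyntheticSpec, coding: bool):
        self.gene_id = gene_id
        self.chrom = chrom
        self.coding = coding
        exn = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        self.exons: list[tuple[int, int]] = []
        pos = start
        for _ in range(exn):
            elen = int(rng.integers(spec.exon_len[0], spec.exon_len[1] + 1))
            self.exons.append((pos, pos + elen))
            pos += elen + int(rng.integers(spec.intron_len[0], spec.intron_len[1] + 1))
        self.end = self.exons[-1][1]
        # isoform 1 uses every exon; others drop a random subset but always
        # keep the first exon and at least two exons overall
        n_iso = int(rng.integers(spec.isoform_range[0], spec.isoform_range[1] + 1))
        self.isoforms: list[list[int]] = [list(range(exn))]
        for _ in range(n_iso - 1):
            keep = [0] + [i for i in range(1, exn) if rng.random() < 0.65]
            if len(keep) < 2:
                keep = [0, int(rng.integers(1, exn))]
            self.isoforms.append(sorted(set(keep)))

    def commonality_at(self, pos: int) -> float:
        """Fraction of isoforms whose exons contain the genomic position."""
        n = 0
        for iso in self.isoforms:
            if any(self.exons[i][0] <= pos < self.exons[i][1] for i in iso):
                n += 1
        return n / len(self.isoforms)


def generate_fixture(spec: SyntheticSpec, outdir) -> FixtureTruth:
    """Write genome.fa, genes.gff3, snps.vcf, somatic.tsv,
    conservation.bedGraph, controls and truth.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    L = spec.spacer_len
    truth = FixtureTruth()

    # --- gene layout on chr1, then the sequence ---------------------------
    builders: list[_GeneBuilder] = []
    cursor = int(rng.integers(spec.gene_gap[0], spec.gene_gap[1] + 1))
    for i in range(spec.n_coding_genes):
        b = _GeneBuilder(f"GENE{i + 1}", "chr1", cursor, rng, spec, coding=True)
        builders.append(b)
        cursor = b.end + int(rng.integers(spec.gene_gap[0], spec.gene_gap[1] + 1))
    ncg = _GeneBuilder("NCG1", "chr1", cursor, rng, spec, coding=False)
    builders.append(ncg)
    chr1_len = ncg.end + 500
    if chr1_len < spec.conservation_block:
        raise ValueError("fixture spec infeasible: chromosome shorter than one conservation block")

    chr1 = rng.choice(BASES, size=chr1_len)
    chr2 = rng.choice(BASES, size=spec.chrom2_len)
    genome = {"chr1": chr1, "chr2": chr2}

    def plant(chrom: str, pos: int, seq: str):
        genome[chrom][pos:pos + len(seq)] = list(seq)

    def plant_guide(builder: _GeneBuilder, exon_idx: int, offset: int) -> tuple[int, str]:
        """Plant spacer+AGG inside an exon; returns (start, spacer)."""
        s, e = builder.exons[exon_idx]
        start = s + offset
        if start + L + 3 > e:
            raise ValueError("fixture spec infeasible: exon too short for plant")
        spacer = _random_spacer(rng, L)
        plant(builder.chrom, start, spacer + "AGG")
        return start, spacer

    coding = builders[: spec.n_coding_genes]

    # --- off-target plants: one guide per category ------------------------
    # NON_EXON: copy on gene-free chr2
    g1 = coding[0]
    start, spacer = plant_guide(g1, 1, 20)
    plant("chr2", 1000, spacer + "AGG")
    truth.guides.append(PlantedGuide(
        g1.gene_id, "chr1", start, start + L, spacer,
        g1.commonality_at(start + L - 3), "NON_EXON", "OFFTARGET",
    ))

    # EXON_NONCODING: copy inside the non-coding gene's exon
    g2 = coding[1]
    start, spacer = plant_guide(g2, 1, 20)
    ns, ne = ncg.exons[0]
    plant("chr1", ns + 10, spacer + "AGG")
    truth.guides.append(PlantedGuide(
        g2.gene_id, "chr1", start, start + L, spacer,
        g2.commonality_at(start + L - 3), "EXON_NONCODING", "OFFTARGET",
    ))

    # CODING: copy inside another coding gene's exon
    g3, g4 = coding[2], coding[3]
    start, spacer = plant_guide(g3, 1, 20)
    hs, he = g4.exons[2]
    plant("chr1", hs + 40, spacer + "AGG")
    truth.guides.append(PlantedGuide(
        g3.gene_id, "chr1", start, start + L, spacer,
        g3.commonality_at(start + L - 3), "CODING", "OFFTARGET",
    ))

    # --- variant plants ---------------------------------------------------
    g5 = coding[4]
    snps: list[tuple[str, int, str, str, float]] = []  # chrom, pos0, ref, alt, af

    start, spacer = plant_guide(g5, 1, 20)
    pos0 = start + 10
    ref = genome["chr1"][pos0]
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    snps.append(("chr1", pos0, ref, alt, spec.snp_maf_above))
    truth.guides.append(PlantedGuide(
        g5.gene_id, "chr1", start, start + L, spacer,
        g5.commonality_at(start + L - 3), "VARIANT_OVERLAP", "SNP_ABOVE",
    ))

    start, spacer = plant_guide(g5, 2, 20)
    pos0 = start + 10
    ref = genome["chr1"][pos0]
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    snps.append(("chr1", pos0, ref, alt, spec.snp_maf_below))
    truth.guides.append(PlantedGuide(
        g5.gene_id, "chr1", start, start + L, spacer,
        g5.commonality_at(start + L - 3), "PASSED", "SNP_BELOW",
    ))

    # somatic locus inside a guide of GENE4
    start, spacer = plant_guide(g4, 0, 20)
    som_pos0 = start + 8
    som_alt = "T" if genome["chr1"][som_pos0] != "T" else "A"
    truth.guides.append(PlantedGuide(
        g4.gene_id, "chr1", start, start + L, spacer,
        g4.commonality_at(start + L - 3), "SOMATIC_OVERLAP", "SOMATIC",
    ))

    # background SNPs in intergenic space on chr2, MAFs straddling the floor
    for i, maf in enumerate(spec.background_mafs):
        pos0 = 3000 + 50 * i
        ref = genome["chr2"][pos0]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        snps.append(("chr2", pos0, ref, alt, maf))
    snps.sort(key=lambda r: (r[0], r[1]))

    # --- write files ------------------------------------------------------
    seqs = {c: "".join(a) for c, a in genome.items()}

    with open(outdir / "genome.fa", "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            s = seqs[chrom]
            for i in range(0, len(s), 70):
                fh.write(s[i:i + 70] + "\n")

    _write_gff3(builders, outdir / "genes.gff3")
    _write_vcf(snps, {c: len(s) for c, s in seqs.items()}, outdir / "snps.vcf")

    with open(outdir / "somatic.tsv", "w") as fh:
        fh.write(f"chr1\t{som_pos0 + 1}\t{som_alt}\n")
        fh.write(f"chr2\t{spec.chrom2_len - 500 + 1}\tA\n")

    with open(outdir / "conservation.bedGraph", "w") as fh:
        for chrom in sorted(seqs):
            n = len(seqs[chrom])
            for i, s in enumerate(range(0, n, spec.conservation_block)):
                score = spec.conservation_scores[i % len(spec.conservation_scores)]
                fh.write(f"{chrom}\t{s}\t{min(s + spec.conservation_block, n)}\t{score}\n")

    for label, fname in (("NEG", "controls_neg.tsv"), ("POS", "controls_pos.tsv")):
        with open(outdir / fname, "w") as fh:
            fh.write(f"# synthetic {label.lower()} control spacers\n")
            for i in range(5):
                fh.write(f"ctrl_{label.lower()}_{i + 1:02d}\t{_random_spacer(rng, L)}\n")

    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("kind\tgene_id\tchrom\tstart\tend\tstrand\tspacer\tcommonality\texpected\n")
        for g in truth.guides:
            fh.write(
                f"{g.kind}\t{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t+\t"
                f"{g.spacer}\t{g.commonality:.6f}\t{g.expected}\n"
            )

    return truth


def _write_gff3(builders, path):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for b in builders:
            fh.write(
                f"{b.chrom}\tsynth\tgene\t{b.exons[0][0] + 1}\t{b.end}\t.\t+\t.\t"
                f"ID={b.gene_id};Name={b.gene_id}\n"
            )
            ttype = "mRNA" if b.coding else "ncRNA"
            for t, iso in enumerate(b.isoforms, 1):
                tid = f"{b.gene_id}.t{t}"
                tstart = b.exons[iso[0]][0] + 1
                tend = b.exons[iso[-1]][1]
                fh.write(
                    f"{b.chrom}\tsynth\t{ttype}\t{tstart}\t{tend}\t.\t+\t.\t"
                    f"ID={tid};Parent={b.gene_id}\n"
                )
                for i in iso:
                    s, e = b.exons[i]
                    fh.write(
                        f"{b.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                        f"ID={tid}.exon{i + 1};Parent={tid}\n"
                    )
                    if b.coding:
                        fh.write(
                            f"{b.chrom}\tsynth\tCDS\t{s + 1}\t{e}\t.\t+\t0\t"
                            f"ID={tid}.cds{i + 1};Parent={tid}\n"
                        )


def _write_vcf(snps, lengths, path):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(lengths):
            fh.write(f"##contig=<ID={chrom},length={lengths[chrom]}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alt, af in snps:
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\tAF={af}\n")
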