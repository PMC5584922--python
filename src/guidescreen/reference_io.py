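"""Readers and indexes for the reference data the designer consumes.

Everything is converted to a single internal coordinate convention — 0-based,
half-open, reference-strand — at the parse boundary: GFF3 and VCF are 1-based
inclusive on disk, BED12 and bedGraph already 0-based half-open. All readers
accept plain or gzip-compressed files.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

RegionClass = Literal["NON_EXON", "EXON_NONCODING", "CODING"]

# severity order used when picking the "worst" off-target category
REGION_SEVERITY = {"NON_EXON": 0, "EXON_NONCODING": 1, "CODING": 2}

_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_ENC[ord("N")] = 4


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


class GenomeError(ValueError):
    """Malformed or inconsistent reference input."""


@dataclass
class ReferenceAssembly:
    """In-memory genome: chromosome name -> uppercase A/C/G/T/N string."""

    sequences: dict[str, str]
    lengths: dict[str, int] = field(default_factory=dict)
    _encoded: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.lengths = {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise GenomeError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.lengths[chrom] or start > end:
            raise GenomeError(
                f"interval [{start},{end}) outside {chrom} (length {self.lengths[chrom]})"
            )
        return self.sequences[chrom][start:end]

    def encoded(self, chrom: str) -> np.ndarray:
        """uint8 encoding A,C,G,T,N -> 0..4, cached per chromosome."""
        if chrom not in self._encoded:
            raw = np.frombuffer(self.sequences[chrom].encode("ascii"), dtype=np.uint8)
            self._encoded[chrom] = _ENC[raw]
        return self._encoded[chrom]


def read_genome(path) -> ReferenceAssembly:
    """Load a FASTA genome, uppercasing and validating the alphabet.

    Raises :class:`GenomeError` for an empty file, a duplicate record name,
    or any character outside ``{A, C, G, T, N}`` (named with its record and
    1-based position).
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - VALID_ALPHABET
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise GenomeError(
                    f"record {rec.id!r}: invalid character {seq[pos]!r} at position {pos + 1}"
                )
            if rec.id in sequences:
                raise GenomeError(f"duplicate FASTA record {rec.id!r}")
            sequences[rec.id] = seq
    if not sequences:
        raise GenomeError(f"no FASTA records found in {path}")
    return ReferenceAssembly(sequences)


# ---------------------------------------------------------------------------
# gene models


@dataclass
class TranscriptModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # sorted, non-overlapping, 0-based half-open
    coding: bool

    def __post_init__(self):
        if not self.exons:
            raise GenomeError(f"transcript {self.transcript_id!r} has zero exons")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise GenomeError(
                    f"transcript {self.transcript_id!r}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def overlaps(self, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.exons)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def coding(self) -> bool:
        """A gene is coding if at least one transcript carries a CDS."""
        return any(t.coding for t in self.transcripts)

    @property
    def exon_union(self) -> list[tuple[int, int]]:
        return merge_intervals(
            iv for t in self.transcripts for iv in t.exons
        )

    @property
    def span(self) -> tuple[int, int]:
        union = self.exon_union
        return union[0][0], union[-1][1]


def _check_chroms(transcripts: Iterable[TranscriptModel], asm: ReferenceAssembly):
    for t in transcripts:
        if t.chrom not in asm.sequences:
            raise GenomeError(
                f"transcript {t.transcript_id!r} on unknown chromosome {t.chrom!r}"
            )
        for s, e in t.exons:
            if s < 0 or e > asm.lengths[t.chrom]:
                raise GenomeError(
                    f"exon [{s},{e}) of {t.transcript_id!r} outside {t.chrom}"
                )


def _read_gff3(path, asm: ReferenceAssembly) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, list[TranscriptModel]] = {}
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = gene.attributes.get("Name", [gene.id])[0]
        for tr in db.children(gene, level=1, order_by="start"):
            if tr.featuretype in ("exon", "CDS"):
                continue
            exons = [
                (f.start - 1, f.end)  # GFF3 1-based inclusive -> half-open
                for f in db.children(tr, featuretype="exon", order_by="start")
            ]
            has_cds = any(True for _ in db.children(tr, featuretype="CDS"))
            genes.setdefault(gene_id, []).append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=tr.id,
                    chrom=gene.seqid,
                    strand=tr.strand,
                    exons=exons,
                    coding=has_cds,
                )
            )
    models = [GeneModel(g, ts) for g, ts in genes.items()]
    for m in models:
        _check_chroms(m.transcripts, asm)
    return models


def _read_bed12(path, asm: ReferenceAssembly) -> list[GeneModel]:
    """BED12, one transcript per line.

    The name field may be ``gene_id:transcript_id``; a bare name serves as
    both. Coding iff thickStart < thickEnd.
    """
    genes: dict[str, list[TranscriptModel]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise GenomeError(f"{path} line {lineno}: expected 12 BED columns")
            chrom, chrom_start, name = f[0], int(f[1]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise GenomeError(f"{path} line {lineno}: block count mismatch")
            exons = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            if ":" in name:
                gene_id, transcript_id = name.split(":", 1)
            else:
                gene_id = transcript_id = name
            genes.setdefault(gene_id, []).append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    coding=thick_start < thick_end,
                )
            )
    models = [GeneModel(g, ts) for g, ts in genes.items()]
    for m in models:
        _check_chroms(m.transcripts, asm)
    return models


def read_gene_models(path, asm: ReferenceAssembly) -> list[GeneModel]:
    """Read GFF3 or BED12 gene models (dispatch on extension)."""
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".gff", ".gff3")):
        return _read_gff3(path, asm)
    if name.endswith((".bed", ".bed12")):
        return _read_bed12(path, asm)
    raise GenomeError(f"unrecognised annotation format: {path}")


def write_bed12(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as BED12 (one transcript per line, name gene:tx)."""
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                start, end = t.exons[0][0], t.exons[-1][1]
                sizes = ",".join(str(e - s) for s, e in t.exons)
                starts = ",".join(str(s - start) for s, _ in t.exons)
                thick = (start, end) if t.coding else (start, start)
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            t.chrom, start, end,
                            f"{t.gene_id}:{t.transcript_id}",
                            0, t.strand, thick[0], thick[1], "0,0,0",
                            len(t.exons), sizes + ",", starts + ",",
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# variants


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    maf: Optional[float]
    kind: Literal["SNP", "SOMATIC"]


def read_variants(
    vcf_path=None,
    somatic_path=None,
    maf_floor: float = 0.05,
    af_info_key: str = "AF",
) -> list[VariantRecord]:
    """Load SNPs above the MAF floor plus all somatic loci.

    SNPs come from a VCF; only records whose allele frequency (INFO key
    ``af_info_key``) is *strictly greater* than ``maf_floor`` are kept.
    Records missing the key are skipped with a warning. Somatic loci come
    from a 3-column TSV ``chrom  pos(1-based)  alt`` and are all kept.
    """
    out: list[VariantRecord] = []
    if vcf_path is not None:
        from cyvcf2 import VCF

        for rec in VCF(str(vcf_path)):
            af = rec.INFO.get(af_info_key)
            if af is None:
                logger.warning(
                    "VCF record %s:%d lacks INFO/%s; skipped",
                    rec.CHROM, rec.POS, af_info_key,
                )
                continue
            if isinstance(af, tuple):
                af = max(af)
            # AF is decimal text in the VCF but comes back as float32;
            # round off the representation noise so the strict floor
            # comparison honours the printed value
            af = round(float(af), 6)
            if af > maf_floor:
                out.append(
                    VariantRecord(
                        chrom=rec.CHROM,
                        pos=rec.POS - 1,
                        ref=rec.REF,
                        alt=rec.ALT[0] if rec.ALT else ".",
                        maf=af,
                        kind="SNP",
                    )
                )
    if somatic_path is not None:
        with _open_text(somatic_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                chrom, pos, alt = f[0], int(f[1]), f[2] if len(f) > 2 else "."
                out.append(
                    VariantRecord(
                        chrom=chrom, pos=pos - 1, ref=".", alt=alt,
                        maf=None, kind="SOMATIC",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# conservation


@dataclass
class ConservationTrack:
    """Piecewise-constant per-base conservation; uncovered bases score 0.

    ``blocks[chrom]`` is a list of ``(start, end, score)`` sorted and
    non-overlapping, scores in [0, 1].
    """

    blocks: dict[str, list[tuple[int, int, float]]]

    def __post_init__(self):
        for chrom, blks in self.blocks.items():
            blks.sort()
            for (s1, e1, v1), (s2, e2, v2) in zip(blks, blks[1:]):
                if s2 < e1:
                    raise GenomeError(
                        f"conservation blocks overlap on {chrom} at {s2}"
                    )
            for s, e, v in blks:
                if not (0.0 <= v <= 1.0):
                    raise GenomeError(
                        f"conservation score {v} outside [0,1] on {chrom}:{s}-{e}"
                    )


def read_conservation(path) -> ConservationTrack:
    """Read a bedGraph conservation track (0-based half-open, score in [0,1])."""
    blocks: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            chrom, start, end, score = line.split("\t")[:4]
            blocks.setdefault(chrom, []).append((int(start), int(end), float(score)))
    return ConservationTrack(blocks)


def mean_conservation(
    track: Optional[ConservationTrack], chrom: str, start: int, end: int
) -> float:
    """Arithmetic mean of per-base scores over [start, end); uncovered = 0.

    A ``None`` track means no conservation data: every interval scores 0.
    """
    if end <= start:
        raise ValueError(f"empty interval [{start},{end})")
    if track is None:
        return 0.0
    total = 0.0
    for s, e, v in track.blocks.get(chrom, ()):
        ov = min(e, end) - max(s, start)
        if ov > 0:
            total += ov * v
    return total / (end - start)


# ---------------------------------------------------------------------------
# region index


@dataclass
class RegionIndex:
    """Interval index over every exon of every gene, tagged with coding status."""

    trees: dict[str, IntervalTree]

    @classmethod
    def build(cls, genes: Iterable[GeneModel]) -> "RegionIndex":
        trees: dict[str, IntervalTree] = {}
        for gene in genes:
            coding = gene.coding
            tree = trees.setdefault(gene.chrom, IntervalTree())
            for s, e in gene.exon_union:
                tree.addi(s, e, (gene.gene_id, coding))
        return cls(trees)

    def query(self, chrom: str, start: int, end: int):
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted(tree.overlap(start, end))


def classify_interval(
    index: RegionIndex, chrom: str, start: int, end: int
) -> RegionClass:
    """CODING > EXON_NONCODING > NON_EXON precedence over overlapped exons."""
    hits = index.query(chrom, start, end)
    if any(coding for iv in hits for (_, coding) in [iv.data]):
        return "CODING"
    if hits:
        return "EXON_NONCODING"
    return "NON_EXON"
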