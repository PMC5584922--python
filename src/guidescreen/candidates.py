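"""Protospacer discovery: every NGG-adjacent spacer overlapping a gene's exons.

A candidate is one occurrence of ``N{L}-NGG`` on either genomic strand whose
protospacer interval overlaps the region of interest. The SpCas9 blunt cut
falls 3 bp 5' of the PAM (between positions 17/18 of a 20-mer protospacer);
that cut site anchors exon attribution for the isoform-commonality score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .reference_io import GeneModel, ReferenceAssembly, VariantRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GuideCandidate:
    """One spacer+PAM occurrence with its criterion values and annotations.

    Coordinates are 0-based half-open on the reference strand;
    ``spacer``/``pam``/``context`` are given on the protospacer strand.
    """

    gene_id: str
    chrom: str
    strand: str  # protospacer strand, '+' or '-'
    start: int  # protospacer interval on reference strand
    end: int
    spacer: str
    pam: str
    cut_site: int  # genomic position, 3 bp 5' of PAM
    context: Optional[str] = None  # spacer + flanks; None near chromosome ends
    efficiency: Optional[float] = None
    specificity: Optional[float] = None
    conservation: Optional[float] = None
    commonality: Optional[float] = None
    variant_hits: list[VariantRecord] = field(default_factory=list)
    perfect_hits: list = field(default_factory=list)  # OffTargetHit, off-gene 0-mm
    offtargets: list = field(default_factory=list)  # all OffTargetHit
    status: str = "PENDING"

    @property
    def spacer_len(self) -> int:
        return self.end - self.start

    @property
    def guanine_fraction(self) -> float:
        return self.spacer.count("G") / self.spacer_len

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def pam_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.end, self.end + 3)
        return (self.start - 3, self.start)

    @property
    def footprint(self) -> dict[str, tuple[int, int]]:
        """Intervals tested for variant overlap, by footprint mode."""
        if self.strand == "+":
            spacer_pam = (self.start, self.end + 3)
        else:
            spacer_pam = (self.start - 3, self.end)
        return {"SPACER": (self.start, self.end), "SPACER_PLUS_PAM": spacer_pam}


def _make_candidate(
    asm: ReferenceAssembly,
    chrom: str,
    strand: str,
    start: int,
    end: int,
    flank5: int,
    flank3: int,
) -> Optional[GuideCandidate]:
    seq = asm.sequences[chrom]
    L = end - start
    if strand == "+":
        spacer = seq[start:end]
        pam = seq[end:end + 3]
        cut_site = end - 3
        cstart, cend = start - flank5, end + flank3
        context = seq[cstart:cend] if cstart >= 0 and cend <= len(seq) else None
    else:
        spacer = revcomp(seq[start:end])
        pam = revcomp(seq[start - 3:start])
        cut_site = start + 2
        cstart, cend = start - flank3, end + flank5
        context = (
            revcomp(seq[cstart:cend]) if cstart >= 0 and cend <= len(seq) else None
        )
    if "N" in spacer:
        return None  # assembly gap
    if context is not None and "N" in context:
        context = None
    return GuideCandidate(
        gene_id="",
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        spacer=spacer,
        pam=pam,
        cut_site=cut_site,
        context=context,
    )


def scan_pam_sites(
    asm: ReferenceAssembly,
    chrom: str,
    start: int,
    end: int,
    spacer_len: int = 20,
    flank5: int = 10,
    flank3: int = 10,
) -> list[GuideCandidate]:
    """All N{L}-NGG occurrences on either strand whose protospacer overlaps
    ``[start, end)``. Spacers containing N are dropped; the scan clips at
    chromosome ends; output is deduplicated and coordinate-sorted.
    """
    if chrom not in asm.sequences:
        raise ValueError(f"unknown chromosome {chrom!r}")
    chrom_len = asm.lengths[chrom]
    if start < 0 or end > chrom_len or start > end:
        raise ValueError(f"region [{start},{end}) outside {chrom}")
    seq = asm.sequences[chrom]
    L = spacer_len
    out: dict[tuple, GuideCandidate] = {}

    # plus strand: protospacer [p, p+L), PAM NGG at [p+L, p+L+3)
    # protospacer overlaps region iff p < end and p+L > start
    lo = max(0, start - L + 1)
    hi = min(chrom_len - L - 3, end - 1)
    for p in range(lo, hi + 1):
        if seq[p + L + 1] == "G" and seq[p + L + 2] == "G":
            cand = _make_candidate(asm, chrom, "+", p, p + L, flank5, flank3)
            if cand is not None:
                out[cand.key] = cand

    # minus strand: reference shows CCN at [p-3, p), protospacer [p, p+L)
    lo = max(3, start - L + 1)
    hi = min(chrom_len - L, end - 1)
    for p in range(lo, hi + 1):
        if seq[p - 3] == "C" and seq[p - 2] == "C":
            cand = _make_candidate(asm, chrom, "-", p, p + L, flank5, flank3)
            if cand is not None:
                out[cand.key] = cand

    return sorted(out.values(), key=lambda c: c.key)


def collect_gene_candidates(
    gene: GeneModel,
    asm: ReferenceAssembly,
    spacer_len: int = 20,
    flank5: int = 10,
    flank3: int = 10,
) -> list[GuideCandidate]:
    """Union of PAM scans over the gene's merged exons, deduplicated.

    Overlap is judged on the protospacer interval; the PAM may lie outside
    the exon.
    """
    seen: dict[tuple, GuideCandidate] = {}
    for s, e in gene.exon_union:
        for cand in scan_pam_sites(asm, gene.chrom, s, e, spacer_len, flank5, flank3):
            cand.gene_id = gene.gene_id
            seen[cand.key] = cand
    cands = sorted(seen.values(), key=lambda c: c.key)
    if not cands:
        logger.warning("gene %s: no sgRNA candidates found", gene.gene_id)
    for cand in cands:
        cand.commonality = isoform_commonality(gene, cand)
    return cands


def isoform_commonality(gene: GeneModel, candidate: GuideCandidate) -> float:
    """Fraction of the gene's transcripts whose exons contain the cut site.

    If the cut site lies in no exon but the protospacer overlaps one, the
    maximum commonality over protospacer-overlapped exonic positions is used
    (a guide spanning an exon boundary still gets that exon's score).
    """
    n = len(gene.transcripts)
    score = sum(t.contains(candidate.cut_site) for t in gene.transcripts) / n
    if score > 0:
        return score
    # position-wise max of the per-exon score over the protospacer; the
    # fraction only changes at transcript exon boundaries, so evaluating
    # there suffices
    probes = {candidate.start}
    for t in gene.transcripts:
        for s, e in t.exons:
            for b in (s, e):
                if candidate.start <= b < candidate.end:
                    probes.add(b)
    best = max(
        sum(t.contains(p) for t in gene.transcripts) / n for p in probes
    )
    if best == 0.0:
        raise ValueError(
            f"candidate {candidate.key} does not overlap gene {gene.gene_id}"
        )
    return best
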