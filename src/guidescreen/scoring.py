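"""The four ranking criteria and the off-target / variant annotations.

Efficiency is a pluggable positional-linear model over the spacer-plus-flank
context (the functional form of LASSO-derived sequence models: an intercept
plus one weight per (position, nucleotide)). Specificity follows the Hsu
per-position mismatch-penalty aggregation on exhaustively enumerated
off-target loci; the search is a brute-force Hamming scan of the whole
assembly on both strands, exact by construction and adequate at desk scale.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

from .candidates import GuideCandidate, revcomp
from .reference_io import (
    REGION_SEVERITY,
    RegionIndex,
    ReferenceAssembly,
    VariantRecord,
    classify_interval,
)

logger = logging.getLogger(__name__)

_ENC_MAP = {c: i for i, c in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC_MAP[c] for c in seq), dtype=np.uint8, count=len(seq))


# ---------------------------------------------------------------------------
# efficiency


@dataclass
class EfficiencyModel:
    """Positional-linear efficiency scorer: intercept + sum of per-(position,
    nucleotide) weights over the context window.

    ``weights[(pos, nt)]`` with position 0 = first context base; absent keys
    contribute 0. The context window is flank5 + spacer + flank3.
    """

    spacer_len: int
    flank5: int
    flank3: int
    intercept: float
    weights: dict[tuple[int, str], float] = field(default_factory=dict)

    @property
    def window(self) -> int:
        return self.flank5 + self.spacer_len + self.flank3

    def score(self, context: str) -> float:
        if len(context) != self.window:
            raise ValueError(
                f"context length {len(context)} != model window {self.window}"
            )
        return self.intercept + sum(
            self.weights.get((i, c), 0.0) for i, c in enumerate(context)
        )


def load_efficiency_model(
    path, spacer_len: int = 20, flank5: int = 10, flank3: int = 10
) -> EfficiencyModel:
    """Read a TSV coefficient file.

    Format: a header line ``#intercept<TAB>value`` followed by rows
    ``position<TAB>nucleotide<TAB>weight`` (position 0 = first context base).
    """
    intercept = 0.0
    weights: dict[tuple[int, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#intercept"):
                intercept = float(line.split("\t")[1])
                continue
            if line.startswith("#"):
                continue
            pos, nt, w = line.split("\t")
            weights[(int(pos), nt.upper())] = float(w)
    return EfficiencyModel(
        spacer_len=spacer_len,
        flank5=flank5,
        flank3=flank3,
        intercept=intercept,
        weights=weights,
    )


def default_efficiency_model(
    spacer_len: int = 20, flank5: int = 10, flank3: int = 10
) -> EfficiencyModel:
    """The efficiency model shipped with the package (illustrative positional
    weights; swap in your own trained coefficients via the TSV interface)."""
    ref = importlib.resources.files("guidescreen.data") / "default_efficiency_model.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_efficiency_model(path, spacer_len, flank5, flank3)


def score_efficiency(candidate: GuideCandidate, model: EfficiencyModel) -> Optional[float]:
    """Score one candidate; ``None`` (unscorable) when the context window is
    unavailable (chromosome edge or assembly gap)."""
    if candidate.context is None or len(candidate.context) != model.window:
        candidate.efficiency = None
        return None
    candidate.efficiency = model.score(candidate.context)
    return candidate.efficiency


# ---------------------------------------------------------------------------
# off-targets


@dataclass(frozen=True)
class OffTargetHit:
    chrom: str
    start: int  # protospacer interval on reference strand
    end: int
    strand: str
    mismatch_positions: tuple[int, ...]  # spacer indices, PAM-distal = 0
    category: str  # ON_TARGET / NON_EXON / EXON_NONCODING / CODING

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatch_positions)


def enumerate_offtargets(
    candidate: GuideCandidate,
    asm: ReferenceAssembly,
    index: RegionIndex,
    gene_span: Optional[tuple[str, int, int]] = None,
    max_mismatch: int = 3,
) -> list[OffTargetHit]:
    """Exhaustive scan for NGG-adjacent loci within ``max_mismatch`` of the
    spacer, both strands, all chromosomes.

    Hits overlapping the queried gene's span are tagged ON_TARGET; other hits
    are categorised by the exon index. Perfect (0-mismatch) hits outside the
    gene populate ``candidate.perfect_hits``.
    """
    L = candidate.spacer_len
    spacer_fwd = _encode(candidate.spacer)
    spacer_rev = _encode(revcomp(candidate.spacer))
    hits: list[OffTargetHit] = []

    for chrom, enc in ((c, asm.encoded(c)) for c in sorted(asm.sequences)):
        n = len(enc)
        if n < L + 3:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)

        # plus strand: window at p, PAM GG at p+L+1, p+L+2
        pam_ok = (enc[L + 1:] == 2)[: n - L - 2] & (enc[L + 2:] == 2)[: n - L - 2]
        valid = np.flatnonzero(pam_ok)
        if valid.size:
            mm = (windows[valid] != spacer_fwd).sum(axis=1)
            for p, k in zip(valid[mm <= max_mismatch], mm[mm <= max_mismatch]):
                p = int(p)
                mmpos = tuple(
                    int(i) for i in np.flatnonzero(windows[p] != spacer_fwd)
                )
                hits.append(
                    _categorise_hit(chrom, p, p + L, "+", mmpos, index, gene_span)
                )

        # minus strand: reference CC at p-3, p-2; window content is the
        # reverse complement of the protospacer
        pam_ok = (enc[:-5] == 1) & (enc[1:-4] == 1)  # positions p-3 for p>=3
        valid = np.flatnonzero(pam_ok) + 3
        valid = valid[valid + L <= n]
        if valid.size:
            mm = (windows[valid] != spacer_rev).sum(axis=1)
            for p, k in zip(valid[mm <= max_mismatch], mm[mm <= max_mismatch]):
                p = int(p)
                ref_mm = np.flatnonzero(windows[p] != spacer_rev)
                # spacer index (PAM-distal = 0) maps to window index L-1-i
                mmpos = tuple(sorted(int(L - 1 - i) for i in ref_mm))
                hits.append(
                    _categorise_hit(chrom, p, p + L, "-", mmpos, index, gene_span)
                )

    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    candidate.offtargets = hits
    candidate.perfect_hits = [
        h for h in hits if h.n_mismatch == 0 and h.category != "ON_TARGET"
    ]
    return hits


def _categorise_hit(chrom, start, end, strand, mmpos, index, gene_span):
    if (
        gene_span is not None
        and chrom == gene_span[0]
        and start < gene_span[2]
        and end > gene_span[1]
    ):
        category = "ON_TARGET"
    else:
        category = classify_interval(index, chrom, start, end)
    return OffTargetHit(
        chrom=chrom, start=start, end=end, strand=strand,
        mismatch_positions=tuple(mmpos), category=category,
    )


def worst_category(hits: Iterable[OffTargetHit]) -> str:
    """Most severe region class among hits: CODING > EXON_NONCODING > NON_EXON."""
    return max((h.category for h in hits), key=REGION_SEVERITY.__getitem__)


# ---------------------------------------------------------------------------
# specificity


@dataclass
class SpecificityPenalty:
    """Per-position mismatch weight vector (PAM-distal = index 0), all in [0,1]."""

    weights: tuple[float, ...]

    def __post_init__(self):
        if any(not (0.0 <= w <= 1.0) for w in self.weights):
            raise ValueError("penalty weights must lie in [0,1]")

    def for_length(self, spacer_len: int) -> Sequence[float]:
        """Trim to a shorter spacer by dropping PAM-distal positions."""
        if spacer_len > len(self.weights):
            raise ValueError(
                f"penalty vector length {len(self.weights)} < spacer {spacer_len}"
            )
        return self.weights[len(self.weights) - spacer_len:]


def load_specificity_penalty(path) -> SpecificityPenalty:
    rows: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pos, w = line.split("\t")
            rows[int(pos)] = float(w)
    return SpecificityPenalty(tuple(rows[i] for i in sorted(rows)))


def default_specificity_penalty() -> SpecificityPenalty:
    """The published Hsu per-position mismatch penalty matrix (20 positions)."""
    ref = importlib.resources.files("guidescreen.data") / "hsu_mismatch_weights.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_specificity_penalty(path)


def single_hit_score(
    mismatch_positions: Sequence[int], weights: Sequence[float]
) -> float:
    """Hsu single off-target score in [0, 1].

    s = prod(1 - W[p]) * 1/(((19 - dbar)/19)*4 + 1) * 1/n^2 with dbar the
    mean pairwise distance between mismatch positions; a perfect match
    (n = 0) scores 1; with n < 2 the distance factor is 1.
    """
    n = len(mismatch_positions)
    if n == 0:
        return 1.0
    prod = 1.0
    for p in mismatch_positions:
        prod *= 1.0 - weights[p]
    if n < 2:
        dbar = 19.0
    else:
        pairs = list(combinations(mismatch_positions, 2))
        dbar = sum(abs(a - b) for a, b in pairs) / len(pairs)
    dist_factor = 1.0 / (((19.0 - dbar) / 19.0) * 4.0 + 1.0)
    return prod * dist_factor * (1.0 / (n * n))


def specificity_score(
    hits: Sequence[OffTargetHit],
    penalty: SpecificityPenalty,
    spacer_len: int = 20,
) -> float:
    """Aggregate specificity in [0, 100]; 100 means no off-target hits.

    The ON_TARGET hit is excluded; each remaining hit contributes its single
    score on the 0-100 scale and the aggregate is
    100 * 100 / (100 + sum of contributions).
    """
    if not hits:
        raise ValueError("hit list is empty (expected at least the on-target)")
    W = penalty.for_length(spacer_len)
    total = sum(
        single_hit_score(h.mismatch_positions, W)
        for h in hits
        if h.category != "ON_TARGET"
    )
    return 100.0 * 100.0 / (100.0 + 100.0 * total)


# ---------------------------------------------------------------------------
# variants


def annotate_variants(
    candidate: GuideCandidate,
    variants: Iterable[VariantRecord],
    footprint: str = "SPACER_PLUS_PAM",
) -> GuideCandidate:
    """Record variants whose position falls inside the guide's footprint
    (the spacer alone, or spacer plus PAM — the default, since a PAM-
    disrupting variant abolishes cutting)."""
    lo, hi = candidate.footprint[footprint]
    candidate.variant_hits = [
        v
        for v in variants
        if v.chrom == candidate.chrom and lo <= v.pos < hi
    ]
    return candidate
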