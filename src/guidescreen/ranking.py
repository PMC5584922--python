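"""Filter-and-rescue guide selection with CRITIC-weighted summary scores.

Hard filters remove guides overlapping variants, guides with more than 40%
guanine, guides with negative predicted efficiency, and guides with perfect
off-target matches. Survivors are ranked by a weighted sum of the four
criteria (efficiency, specificity, conservation, isoform commonality) where
the weights come from the CRITIC method: each criterion's weight is
proportional to its contrast (standard deviation after min-max normalisation)
times its conflict with the other criteria (aggregated 1 - correlation
terms), so a criterion that varies a lot and disagrees with the others
carries more weight — computed per gene, not fixed globally.

When the filters leave fewer guides than requested, guides removed *only*
for having perfect off-target matches are readmitted in increasing order of
off-target severity (intergenic, then non-coding exon, then coding exon),
fewest hits first, summary score breaking ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .candidates import GuideCandidate
from .config import DesignConfig
from .reference_io import REGION_SEVERITY
from .scoring import worst_category

logger = logging.getLogger(__name__)

CRITERIA = ("efficiency", "specificity", "conservation", "commonality")

RESCUE_ORDER = ("NON_EXON", "EXON_NONCODING", "CODING")

# filter reason codes
VARIANT_OVERLAP = "VARIANT_OVERLAP"
HIGH_G = "HIGH_G"
PERFECT_OFFTARGET = "PERFECT_OFFTARGET"
LOW_EFFICIENCY = "LOW_EFFICIENCY"
UNSCORABLE = "UNSCORABLE"


@dataclass
class FilterReport:
    """Partition of a gene's candidates into passed / filtered / rescuable."""

    passed: list[GuideCandidate]
    filtered: list[GuideCandidate]
    reasons: dict[tuple, list[str]]  # candidate.key -> violated rules
    rescue_pool: dict[str, list[GuideCandidate]]  # category -> candidates

    @property
    def n_input(self) -> int:
        return (
            len(self.passed)
            + len(self.filtered)
            + sum(len(v) for v in self.rescue_pool.values())
        )


def filter_candidates(
    cands: Sequence[GuideCandidate],
    use_somatic: bool = False,
    config: Optional[DesignConfig] = None,
) -> FilterReport:
    """Apply the hard filters; every candidate lands in exactly one of
    passed, filtered, or the rescue pool.

    A candidate is removed iff it violates any rule. Candidates whose *only*
    violation is a perfect off-target match go to the rescue pool, keyed by
    the worst category among their perfect hits; all violated rules are
    recorded.
    """
    cfg = config or DesignConfig()
    passed: list[GuideCandidate] = []
    filtered: list[GuideCandidate] = []
    reasons: dict[tuple, list[str]] = {}
    pool: dict[str, list[GuideCandidate]] = {c: [] for c in RESCUE_ORDER}

    for cand in cands:
        violated: list[str] = []
        hits = [
            v
            for v in cand.variant_hits
            if v.kind == "SNP" or (use_somatic and v.kind == "SOMATIC")
        ]
        if hits:
            violated.append(VARIANT_OVERLAP)
        # strict >40%: integer comparison avoids float-boundary surprises
        if 5 * cand.spacer.count("G") > 2 * cand.spacer_len:
            violated.append(HIGH_G)
        if cand.efficiency is None:
            violated.append(UNSCORABLE)
        elif cand.efficiency < cfg.min_efficiency:
            violated.append(LOW_EFFICIENCY)
        if cand.perfect_hits:
            violated.append(PERFECT_OFFTARGET)

        if not violated:
            cand.status = "PASSED"
            passed.append(cand)
        elif violated == [PERFECT_OFFTARGET]:
            category = worst_category(cand.perfect_hits)
            cand.status = f"FILTERED_{PERFECT_OFFTARGET}"
            pool[category].append(cand)
            reasons[cand.key] = violated
        else:
            cand.status = "FILTERED_" + "+".join(violated)
            filtered.append(cand)
            reasons[cand.key] = violated

    return FilterReport(passed=passed, filtered=filtered, reasons=reasons, rescue_pool=pool)


# ---------------------------------------------------------------------------
# CRITIC


@dataclass
class CriteriaMatrix:
    """Per-gene candidates x criteria matrix with CRITIC weights.

    Columns are [efficiency, specificity, conservation, commonality]; each is
    min-max normalised (a constant column maps to all zeros) before the
    contrast/conflict computation.
    """

    gene_id: str
    candidates: list[GuideCandidate]
    raw: np.ndarray
    conflict: str = "sum"
    normalized: np.ndarray = field(init=False)
    sigma: np.ndarray = field(init=False)
    corr: np.ndarray = field(init=False)
    information: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)

    @classmethod
    def from_candidates(
        cls,
        gene_id: str,
        cands: Sequence[GuideCandidate],
        conflict: str = "sum",
    ) -> "CriteriaMatrix":
        if not cands:
            raise ValueError(f"gene {gene_id}: empty criteria matrix")
        raw = np.array(
            [[getattr(c, crit) for crit in CRITERIA] for c in cands], dtype=float
        )
        if not np.all(np.isfinite(raw)):
            raise ValueError(f"gene {gene_id}: non-finite criterion value")
        return cls(gene_id=gene_id, candidates=list(cands), raw=raw, conflict=conflict)

    def __post_init__(self):
        self.normalized = _minmax(self.raw)
        self.sigma, self.corr, self.information, self.weights = critic_weights(
            self.normalized, conflict=self.conflict
        )

    def summary_scores(self) -> np.ndarray:
        return self.normalized @ self.weights

    def score_of(self, cand: GuideCandidate) -> float:
        i = next(
            i for i, c in enumerate(self.candidates) if c.key == cand.key
        )
        return float(self.summary_scores()[i])


def _minmax(raw: np.ndarray) -> np.ndarray:
    lo = raw.min(axis=0)
    span = raw.max(axis=0) - lo
    out = np.zeros_like(raw, dtype=float)
    nz = span > 0
    out[:, nz] = (raw[:, nz] - lo[nz]) / span[nz]
    return out


def critic_weights(
    normalized: np.ndarray, conflict: str = "sum"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """CRITIC objective weights from a min-max-normalised matrix.

    Returns (sigma, corr, C, w): per-column sample standard deviation,
    Pearson correlation matrix (undefined entries 0), information amount
    C_j = sigma_j * agg_k(1 - r_jk), and w = C / sum(C). The conflict
    aggregation is the sum over all other criteria or, with
    ``conflict="product"``, the product. Degenerate inputs (fewer than 3
    rows, or no informative column) fall back to uniform weights.
    """
    n, m = normalized.shape
    if n < 3:
        sigma = np.zeros(m)
        corr = np.eye(m)
        return sigma, corr, np.zeros(m), np.full(m, 1.0 / m)
    sigma = normalized.std(axis=0, ddof=1)
    corr = np.eye(m)
    for j in range(m):
        for k in range(j + 1, m):
            if sigma[j] > 0 and sigma[k] > 0:
                r = float(np.corrcoef(normalized[:, j], normalized[:, k])[0, 1])
            else:
                r = 0.0
            corr[j, k] = corr[k, j] = r
    if conflict == "sum":
        agg = np.array([sum(1.0 - corr[j, k] for k in range(m) if k != j) for j in range(m)])
    elif conflict == "product":
        agg = np.array(
            [np.prod([1.0 - corr[j, k] for k in range(m) if k != j]) for j in range(m)]
        )
    else:
        raise ValueError(f"bad conflict mode {conflict!r}")
    information = sigma * agg
    total = information.sum()
    if total <= 0:
        return sigma, corr, information, np.full(m, 1.0 / m)
    return sigma, corr, information, information / total


# ---------------------------------------------------------------------------
# ordering helpers


def _ranked(cands: Sequence[GuideCandidate], scores: dict[tuple, float]) -> list[GuideCandidate]:
    """Descending summary score; ties broken by ascending (chrom, start, strand)."""
    return sorted(cands, key=lambda c: (-scores[c.key], c.chrom, c.start, c.strand))


def rescue(
    report: FilterReport,
    scores: dict[tuple, float],
    needed: int,
) -> list[GuideCandidate]:
    """Readmit off-target-only failures, least severe first.

    Order: NON_EXON before EXON_NONCODING before CODING; within a category,
    ascending perfect-hit count, then descending summary score, then genomic
    coordinate. Stops when ``needed`` guides are rescued or the pool is
    exhausted.
    """
    out: list[GuideCandidate] = []
    for category in RESCUE_ORDER:
        pool = report.rescue_pool.get(category, [])
        ordered = sorted(
            pool,
            key=lambda c: (
                len(c.perfect_hits),
                -scores[c.key],
                c.chrom,
                c.start,
                c.strand,
            ),
        )
        for cand in ordered:
            if len(out) >= needed:
                return out
            cand.status = f"RESCUED_{category}"
            out.append(cand)
    return out


@dataclass
class GeneSelection:
    """Outcome of the per-gene pipeline: ordered guides plus diagnostics."""

    gene_id: str
    guides: list[GuideCandidate]
    summary: dict[tuple, float]
    weights: np.ndarray
    report: FilterReport
    n_candidates: int


def select_guides(
    gene_id: str,
    cands: Sequence[GuideCandidate],
    n: int,
    config: Optional[DesignConfig] = None,
) -> GeneSelection:
    """Filter, rank and (if needed) rescue; return the top ``n`` guides.

    Input candidates must already be scored and annotated. Output is ordered
    passed-first by descending summary score, then rescued guides in rescue
    order. Returns fewer than ``n`` (with a warning) when the gene simply
    does not have enough designable guides.
    """
    cfg = config or DesignConfig()
    if not 1 <= n <= 30:
        raise ValueError(f"guides per gene must be in [1,30], got {n}")
    report = filter_candidates(cands, use_somatic=cfg.use_somatic, config=cfg)

    summary: dict[tuple, float] = {}
    weights = np.full(len(CRITERIA), 1.0 / len(CRITERIA))

    ordered_passed: list[GuideCandidate] = []
    if report.passed:
        matrix = CriteriaMatrix.from_candidates(
            gene_id, report.passed, conflict=cfg.critic_conflict
        )
        weights = matrix.weights
        for cand, s in zip(matrix.candidates, matrix.summary_scores()):
            summary[cand.key] = float(s)
        ordered_passed = _ranked(report.passed, summary)

    selected = ordered_passed[:n]
    if len(selected) < n:
        pool = [c for cat in RESCUE_ORDER for c in report.rescue_pool.get(cat, [])]
        if pool:
            # pooled matrix makes passed and rescued scores comparable
            pooled = CriteriaMatrix.from_candidates(
                gene_id, list(report.passed) + pool, conflict=cfg.critic_conflict
            )
            pooled_scores = {
                c.key: float(s)
                for c, s in zip(pooled.candidates, pooled.summary_scores())
            }
            if not report.passed:
                weights = pooled.weights
            for c in pool:
                summary.setdefault(c.key, pooled_scores[c.key])
            rescued = rescue(report, pooled_scores, n - len(selected))
            selected = selected + rescued
    if len(selected) < n:
        logger.warning(
            "gene %s: only %d designable guides for a request of %d",
            gene_id, len(selected), n,
        )
    return GeneSelection(
        gene_id=gene_id,
        guides=selected,
        summary=summary,
        weights=weights,
        report=report,
        n_candidates=len(cands),
    )
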