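"""Batch design: validate a request, run the per-gene pipeline, write the
library.

The request caps mirror the intended use — focused screens of up to 1000
genes with up to 30 guides per gene and 19 or 20 nt spacers — and are
enforced before any file is opened.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import assembly, candidates, ranking, reference_io, scoring
from .config import MAX_GENES, MAX_GUIDES_PER_GENE, SPACER_LENGTHS, DesignConfig

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """A request violates the design caps."""


@dataclass
class DesignRequest:
    gene_ids: list[str]
    genome: Path
    annotation: Path
    n_per_gene: int = 6
    spacer_len: int = 20
    snps: Optional[Path] = None
    somatic: Optional[Path] = None
    conservation: Optional[Path] = None
    efficiency_model: Optional[Path] = None
    specificity_penalty: Optional[Path] = None
    controls_neg: Optional[Path] = None
    controls_pos: Optional[Path] = None
    construct_config: Optional[Path] = None
    append_construct: bool = False
    config: DesignConfig = field(default_factory=DesignConfig)


def validate_request(req: DesignRequest) -> DesignRequest:
    """Enforce the request caps; deduplicate gene IDs preserving order."""
    if req.spacer_len not in SPACER_LENGTHS:
        raise ValidationError(
            f"spacer length must be one of {SPACER_LENGTHS}, got {req.spacer_len}"
        )
    if not 1 <= req.n_per_gene <= MAX_GUIDES_PER_GENE:
        raise ValidationError(
            f"guides per gene must be in [1,{MAX_GUIDES_PER_GENE}], got {req.n_per_gene}"
        )
    seen = set()
    deduped = []
    for g in req.gene_ids:
        key = g.strip()
        if key and key.lower() not in seen:
            seen.add(key.lower())
            deduped.append(key)
    if not deduped:
        raise ValidationError("empty gene list")
    if len(deduped) > MAX_GENES:
        raise ValidationError(
            f"at most {MAX_GENES} genes per request, got {len(deduped)}"
        )
    req.gene_ids = deduped
    req.config = req.config.with_(spacer_len=req.spacer_len)
    return req


def resolve_gene_ids(
    gene_ids: list[str], genes: list[reference_io.GeneModel]
) -> tuple[dict[str, reference_io.GeneModel], list[str]]:
    """Case-insensitive resolution: gene symbol first, then transcript ID."""
    by_symbol = {g.gene_id.lower(): g for g in genes}
    by_tx = {
        t.transcript_id.lower(): g for g in genes for t in g.transcripts
    }
    resolved: dict[str, reference_io.GeneModel] = {}
    missing: list[str] = []
    for gid in gene_ids:
        g = by_symbol.get(gid.lower()) or by_tx.get(gid.lower())
        if g is None:
            missing.append(gid)
        else:
            resolved[gid] = g
    return resolved, missing


def design_gene(
    gene: reference_io.GeneModel,
    asm: reference_io.ReferenceAssembly,
    index: reference_io.RegionIndex,
    variants: list[reference_io.VariantRecord],
    cons_track: Optional[reference_io.ConservationTrack],
    eff_model: scoring.EfficiencyModel,
    penalty: scoring.SpecificityPenalty,
    n: int,
    config: DesignConfig,
) -> ranking.GeneSelection:
    """Collect, score, annotate and select guides for one gene."""
    cands = candidates.collect_gene_candidates(
        gene, asm, config.spacer_len, config.flank5, config.flank3
    )
    span = (gene.chrom, *gene.span)
    for cand in cands:
        scoring.score_efficiency(cand, eff_model)
        hits = scoring.enumerate_offtargets(
            cand, asm, index, gene_span=span, max_mismatch=config.max_mismatch
        )
        cand.specificity = scoring.specificity_score(hits, penalty, config.spacer_len)
        cand.conservation = reference_io.mean_conservation(
            cons_track, cand.chrom, cand.start, cand.end
        )
        scoring.annotate_variants(cand, variants, config.variant_footprint)
    sel = ranking.select_guides(gene.gene_id, cands, n, config)
    logger.info(
        "gene %s: %d candidates, %d passed, %d filtered, %d rescuable, %d selected",
        gene.gene_id,
        sel.n_candidates,
        len(sel.report.passed),
        len(sel.report.filtered),
        sum(len(v) for v in sel.report.rescue_pool.values()),
        len(sel.guides),
    )
    return sel


def run_design(req: DesignRequest, out_path) -> list[assembly.LibraryRow]:
    """Execute the full batch pipeline and write the library TSV."""
    req = validate_request(req)
    cfg = req.config

    asm = reference_io.read_genome(req.genome)
    genes = reference_io.read_gene_models(req.annotation, asm)
    index = reference_io.RegionIndex.build(genes)
    variants = reference_io.read_variants(
        req.snps, req.somatic, maf_floor=cfg.maf_floor, af_info_key=cfg.af_info_key
    )
    cons_track = (
        reference_io.read_conservation(req.conservation) if req.conservation else None
    )
    eff_model = (
        scoring.load_efficiency_model(
            req.efficiency_model, cfg.spacer_len, cfg.flank5, cfg.flank3
        )
        if req.efficiency_model
        else scoring.default_efficiency_model(cfg.spacer_len, cfg.flank5, cfg.flank3)
    )
    penalty = (
        scoring.load_specificity_penalty(req.specificity_penalty)
        if req.specificity_penalty
        else scoring.default_specificity_penalty()
    )
    construct = None
    if req.append_construct:
        construct = (
            assembly.load_construct_config(req.construct_config)
            if req.construct_config
            else assembly.default_construct_config()
        )
        if cfg.force_5prime_g:
            construct.force_5prime_g = True

    resolved, missing = resolve_gene_ids(req.gene_ids, genes)
    for gid in missing:
        logger.warning("gene ID %r not found in annotation; skipped", gid)

    rows: list[assembly.LibraryRow] = []
    for gid in req.gene_ids:
        gene = resolved.get(gid)
        if gene is None:
            continue
        sel = design_gene(
            gene, asm, index, variants, cons_track, eff_model, penalty,
            req.n_per_gene, cfg,
        )
        rows.extend(assembly.rows_from_selection(sel, construct))

    negatives = (
        assembly.load_control_set(req.controls_neg, "NEGATIVE")
        if req.controls_neg
        else None
    )
    positives = (
        assembly.load_control_set(req.controls_pos, "POSITIVE")
        if req.controls_pos
        else None
    )
    rows = assembly.attach_controls(
        rows, negatives, positives,
        spacer_len=cfg.spacer_len, construct=construct,
    )
    assembly.write_library(rows, out_path, include_oligo=construct is not None)
    logger.info("wrote %d library rows to %s", len(rows), out_path)
    return rows
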