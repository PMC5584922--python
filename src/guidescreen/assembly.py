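"""Final library assembly: oligo construction, controls, and the output table.

The output TSV is deterministic down to the byte for identical inputs:
fixed column order, floats printed at 4 decimals, rows in selection order.
A construct config (promoter + scaffold sequences) turns each spacer into a
synthesis-ready oligo; negative (safe-harbor) and positive (essential-gene)
control guides are appended as rows with blank scores.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .candidates import GuideCandidate
from .ranking import CRITERIA, GeneSelection


@dataclass
class ConstructConfig:
    """5' promoter and 3' scaffold appended around the spacer."""

    promoter: str = ""
    scaffold: str = ""
    force_5prime_g: bool = False


def load_construct_config(path) -> ConstructConfig:
    """Key-value file: lines ``promoter=SEQ`` / ``scaffold=SEQ`` /
    ``force_5prime_g=true|false``."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            kv[k.strip().lower()] = v.strip()
    return ConstructConfig(
        promoter=kv.get("promoter", "").upper(),
        scaffold=kv.get("scaffold", "").upper(),
        force_5prime_g=kv.get("force_5prime_g", "false").lower() in ("1", "true", "yes"),
    )


def default_construct_config() -> ConstructConfig:
    ref = importlib.resources.files("guidescreen.data") / "construct_elements.cfg"
    with importlib.resources.as_file(ref) as path:
        return load_construct_config(path)


def build_oligo(spacer: str, config: ConstructConfig) -> str:
    """promoter + spacer + scaffold; optionally prepend a G to spacers that
    lack one (U6 transcription initiates best on G)."""
    if not spacer:
        raise ValueError("empty spacer")
    if config.force_5prime_g and not spacer.startswith("G"):
        spacer = "G" + spacer
    return config.promoter + spacer + config.scaffold


@dataclass
class ControlSet:
    label: str  # NEGATIVE or POSITIVE
    entries: list[tuple[str, str]]  # (name, spacer)


def load_control_set(path, label: str) -> ControlSet:
    entries: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, spacer = line.split("\t")[:2]
            entries.append((name, spacer.upper()))
    return ControlSet(label=label, entries=entries)


@dataclass
class LibraryRow:
    gene_id: str
    rank: int
    chrom: str
    start: Optional[int]
    end: Optional[int]
    strand: str
    spacer: str
    pam: str
    efficiency: Optional[float]
    specificity: Optional[float]
    conservation: Optional[float]
    commonality: Optional[float]
    summary_score: Optional[float]
    weights: Optional[Sequence[float]]
    status: str
    n_variant_hits: int = 0
    n_perfect_offtargets: int = 0
    offtarget_categories: str = ""
    oligo: Optional[str] = None


def rows_from_selection(
    sel: GeneSelection,
    construct: Optional[ConstructConfig] = None,
) -> list[LibraryRow]:
    rows = []
    for rank, cand in enumerate(sel.guides, 1):
        cats = sorted({h.category for h in cand.perfect_hits})
        rows.append(
            LibraryRow(
                gene_id=sel.gene_id,
                rank=rank,
                chrom=cand.chrom,
                start=cand.start,
                end=cand.end,
                strand=cand.strand,
                spacer=cand.spacer,
                pam=cand.pam,
                efficiency=cand.efficiency,
                specificity=cand.specificity,
                conservation=cand.conservation,
                commonality=cand.commonality,
                summary_score=sel.summary.get(cand.key),
                weights=list(sel.weights),
                status=cand.status,
                n_variant_hits=len(cand.variant_hits),
                n_perfect_offtargets=len(cand.perfect_hits),
                offtarget_categories=",".join(cats),
                oligo=build_oligo(cand.spacer, construct) if construct else None,
            )
        )
    return rows


def attach_controls(
    rows: list[LibraryRow],
    negatives: Optional[ControlSet] = None,
    positives: Optional[ControlSet] = None,
    n_negative: Optional[int] = None,
    n_positive: Optional[int] = None,
    spacer_len: int = 20,
    construct: Optional[ConstructConfig] = None,
) -> list[LibraryRow]:
    """Append control rows (gene_id CTRL_NEG / CTRL_POS, blank scores).

    Control spacers must match the library spacer length; a mismatch raises
    with the offending entry named.
    """
    out = list(rows)
    for cs, gene_id, count in (
        (negatives, "CTRL_NEG", n_negative),
        (positives, "CTRL_POS", n_positive),
    ):
        if cs is None:
            continue
        entries = cs.entries if count is None else cs.entries[:count]
        for rank, (name, spacer) in enumerate(entries, 1):
            if len(spacer) != spacer_len:
                raise ValueError(
                    f"control {name!r}: spacer length {len(spacer)} != "
                    f"library spacer length {spacer_len}"
                )
            out.append(
                LibraryRow(
                    gene_id=gene_id,
                    rank=rank,
                    chrom=name,
                    start=None,
                    end=None,
                    strand=".",
                    spacer=spacer,
                    pam="",
                    efficiency=None,
                    specificity=None,
                    conservation=None,
                    commonality=None,
                    summary_score=None,
                    weights=None,
                    status="CONTROL",
                    oligo=build_oligo(spacer, construct) if construct else None,
                )
            )
    return out


_COLUMNS = (
    "gene_id", "rank", "chrom", "start", "end", "strand", "spacer", "pam",
    "efficiency", "specificity", "conservation", "commonality",
    "summary_score", "weights", "status", "n_variant_hits",
    "n_perfect_offtargets", "offtarget_categories",
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.4f}"
    if isinstance(value, (list, tuple, np.ndarray)):
        return "|".join(f"{float(v):.4f}" for v in value)
    return str(value)


def write_library(rows: Iterable[LibraryRow], path, include_oligo: bool = False) -> None:
    """Tab-separated library table; byte-identical across runs on identical
    input."""
    cols = _COLUMNS + (("oligo",) if include_oligo else ())
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(getattr(row, c)) for c in cols) + "\n")
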