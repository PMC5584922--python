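"""Design thresholds and pipeline options.

Every threshold the selection procedure applies lives here with its default:
the minor-allele-frequency floor for SNP annotation (variants at or below it
are ignored), the guanine-content ceiling (strictly more than 40% G in the
spacer disqualifies a guide), the efficiency floor (strictly below zero
disqualifies), and the off-target mismatch cap. The CLI and config files both
funnel into a single :class:`DesignConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

SPACER_LENGTHS = (19, 20)
MAX_GENES = 1000
MAX_GUIDES_PER_GENE = 30

Footprint = Literal["SPACER", "SPACER_PLUS_PAM"]
ConflictMode = Literal["sum", "product"]


@dataclass(frozen=True)
class DesignConfig:
    """All tunable thresholds of the design pipeline.

    Attributes
    ----------
    spacer_len:
        Protospacer length, 19 or 20 nt.
    flank5, flank3:
        Context bases taken on each side of the spacer for efficiency models.
    maf_floor:
        SNPs with minor allele frequency strictly greater than this are
        annotated onto guides; 0.05 by default.
    max_g_fraction:
        Guides with guanine fraction strictly greater than this are filtered.
    min_efficiency:
        Guides with efficiency score strictly below this are filtered.
    max_mismatch:
        Off-target enumeration reports loci within this many mismatches.
    af_info_key:
        VCF INFO key holding the allele frequency (dbSNP dialects vary).
    variant_footprint:
        Interval tested for variant overlap: the spacer alone or spacer+PAM.
    critic_conflict:
        Aggregation of the (1 - r) conflict terms in CRITIC: "sum" or
        "product".
    force_5prime_g:
        Prepend a G to spacers that do not start with one when building
        oligos (U6 transcription prefers a 5' G).
    """

    spacer_len: int = 20
    flank5: int = 10
    flank3: int = 10
    maf_floor: float = 0.05
    max_g_fraction: float = 0.40
    min_efficiency: float = 0.0
    max_mismatch: int = 3
    af_info_key: str = "AF"
    variant_footprint: Footprint = "SPACER_PLUS_PAM"
    critic_conflict: ConflictMode = "sum"
    force_5prime_g: bool = False
    use_somatic: bool = False

    def __post_init__(self) -> None:
        if self.spacer_len not in SPACER_LENGTHS:
            raise ValueError(
                f"spacer_len must be one of {SPACER_LENGTHS}, got {self.spacer_len}"
            )
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.variant_footprint not in ("SPACER", "SPACER_PLUS_PAM"):
            raise ValueError(f"bad variant footprint {self.variant_footprint!r}")
        if self.critic_conflict not in ("sum", "product"):
            raise ValueError(f"bad critic_conflict {self.critic_conflict!r}")

    def with_(self, **kwargs) -> "DesignConfig":
        return replace(self, **kwargs)
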