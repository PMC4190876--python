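"""Core variant containers shared across the pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .annotation import Consequence


@dataclass
class VariantCall:
    """One candidate small variant in one sample.

    Read support is kept split by sequencing strand (``fwd_*`` / ``rev_*``)
    because the both-strand rule is one of the prioritization filters.
    ``pop_freqs`` maps population-database names to observed allele
    frequencies (a missing database means the variant was not observed
    there); ``in_pathogenic_db`` records membership in a curated
    disease-mutation database (HGMD/PKDB-style), which can rescue a variant
    from the common-polymorphism filter.
    """

    sample_id: str
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    fwd_ref: int = 0
    rev_ref: int = 0
    fwd_alt: int = 0
    rev_alt: int = 0
    pop_freqs: dict[str, float] = field(default_factory=dict)
    in_pathogenic_db: bool = False
    consequence: Optional[Consequence] = None
    # curated metadata carried by cohort fixtures
    curated_class: Optional[str] = None
    in_duplicated_region: bool = False

    def __post_init__(self) -> None:
        for name in ("fwd_ref", "rev_ref", "fwd_alt", "rev_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for db, f in self.pop_freqs.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency for {db!r} outside [0, 1]: {f}")

    @property
    def ref_depth(self) -> int:
        return self.fwd_ref + self.rev_ref

    @property
    def alt_depth(self) -> int:
        return self.fwd_alt + self.rev_alt

    @property
    def depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def alt_fraction(self) -> float:
        """Alt reads over ref+alt reads at the site; NaN at zero depth."""
        d = self.depth
        return self.alt_depth / d if d else float("nan")


@dataclass
class StructuralEvent:
    """A large deletion/duplication event in one sample (target-span evidence)."""

    sample_id: str
    contig: str
    start: int  # 0-based
    end: int    # half-open
    kind: str = "deletion"
    label: Optional[str] = None  # e.g. "g.2154344-2186386del"
    curated_class: Optional[str] = None
    in_duplicated_region: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("structural event must have end > start")
        if self.kind not in {"deletion", "duplication"}:
            raise ValueError(f"unknown SV kind {self.kind!r}")
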