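"""The variant prioritization filter cascade.

Targeted capture of a gene whose 5' region is mirrored in six ~97.7%-identical
pseudogenes produces a specific artifact signature: reads from the pseudogenes
that misalign onto the genuine gene accumulate as low-allele-fraction,
often strand-skewed variant calls.  The cascade removes them with three rules:

1. *strand*: alternate-allele reads must be present on both sequenced strands;
2. *fraction*: the alternate allele must account for >= 20% of ref+alt reads
   at the site;
3. *frequency*: variants at >= 5% frequency in any population database are
   discarded as common polymorphisms or recurrent artifacts — unless the
   variant is a known disease mutation (curated-database membership), in which
   case it is rescued.

Every rule evaluation is recorded so a reviewer can audit why each candidate
was kept or removed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .variants import VariantCall

RULE_STRAND = "strand"
RULE_FRACTION = "fraction"
RULE_FREQUENCY = "frequency"
RULE_ZERO_DEPTH = "zero_depth"


@dataclass
class FilterDecision:
    variant: VariantCall
    passed: bool
    failed_rules: list[str] = field(default_factory=list)
    rescue_applied: bool = False

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_rules):
            raise ValueError("passed must be equivalent to an empty failed_rules list")


def strand_filter(v: VariantCall) -> bool:
    """True iff the alternate allele is supported on both strands."""
    return v.fwd_alt >= 1 and v.rev_alt >= 1


def allele_fraction_filter(v: VariantCall, min_fraction: float = 0.20) -> bool:
    """True iff alt reads make up at least ``min_fraction`` of ref+alt reads.

    Zero-depth sites fail (the cascade tags them with an explicit
    ``zero_depth`` rule so they are distinguishable in the audit trail).
    """
    if v.depth == 0:
        return False
    return v.alt_depth / v.depth >= min_fraction


def frequency_filter(v: VariantCall, max_freq: float = 0.05) -> tuple[bool, bool]:
    """Common-polymorphism filter with pathogenic-database rescue.

    Returns ``(passed, rescue_applied)``.  A variant fails when *any*
    population database reports frequency >= ``max_freq``; a failing variant
    passes with ``rescue_applied=True`` when it is a known disease mutation.
    """
    for db, f in v.pop_freqs.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"frequency for {db!r} outside [0, 1]: {f}")
    common = any(f >= max_freq for f in v.pop_freqs.values())
    if not common:
        return True, False
    if v.in_pathogenic_db:
        return True, True
    return False, False


def run_cascade(
    variants: Iterable[VariantCall],
    min_fraction: float = 0.20,
    max_freq: float = 0.05,
) -> list[FilterDecision]:
    """Apply all three rules to every variant and return the audit trail.

    The rules are independent: the retained set is the intersection of the
    per-rule pass sets, so the order of application cannot matter.
    """
    decisions: list[FilterDecision] = []
    for v in variants:
        failed: list[str] = []
        if not strand_filter(v):
            failed.append(RULE_STRAND)
        if v.depth == 0:
            failed.append(RULE_ZERO_DEPTH)
        elif not allele_fraction_filter(v, min_fraction):
            failed.append(RULE_FRACTION)
        freq_ok, rescued = frequency_filter(v, max_freq)
        if not freq_ok:
            failed.append(RULE_FREQUENCY)
        decisions.append(
            FilterDecision(variant=v, passed=not failed, failed_rules=failed,
                           rescue_applied=rescued)
        )
    return decisions


def retained(decisions: Sequence[FilterDecision]) -> list[VariantCall]:
    return [d.variant for d in decisions if d.passed]
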