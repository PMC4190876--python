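"""Pathogenicity classification.

Two routes:

* Truncating consequences (stop-gain, frameshift, canonical splice,
  exon-disrupting structural deletion) are classified *definitely pathogenic*
  outright.
* Everything else is an Unclassified Sequence Variant (UCV).  Evidence items
  (conservation, physicochemical severity of the substitution, splice-predictor
  deltas, population data, cosegregation) each carry integer points; their sum
  is the Variant Score (VS) and fixed integer cut-offs map VS to one of four
  classes:

  ==============================  =========
  highly likely pathogenic        VS >= 11
  likely pathogenic               5..10
  indeterminate                   0..4
  highly likely neutral           VS <= -1
  ==============================  =========

Reportable (diagnostic) classes are definitely / highly-likely / likely
pathogenic.  The exact point values of the published PKD1/PKD2 scoring system
are not reproduced here; the evidence table is configuration, and cohort
fixtures carry curated classes for concordance checks.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .annotation import Consequence, is_truncating
from .variants import VariantCall


class ClassificationError(ValueError):
    pass


class ScoringError(ValueError):
    pass


class PathogenicityClass(str, enum.Enum):
    DEFINITELY_PATHOGENIC = "definitely_pathogenic"
    HIGHLY_LIKELY_PATHOGENIC = "highly_likely_pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    INDETERMINATE = "indeterminate"
    HIGHLY_LIKELY_NEUTRAL = "highly_likely_neutral"


REPORTABLE_CLASSES = frozenset(
    {
        PathogenicityClass.DEFINITELY_PATHOGENIC,
        PathogenicityClass.HIGHLY_LIKELY_PATHOGENIC,
        PathogenicityClass.LIKELY_PATHOGENIC,
    }
)

# printed labels (case-insensitive) -> enum
_PRINTED = {
    "definitely pathogenic": PathogenicityClass.DEFINITELY_PATHOGENIC,
    "highly likely pathogenic": PathogenicityClass.HIGHLY_LIKELY_PATHOGENIC,
    "likely pathogenic": PathogenicityClass.LIKELY_PATHOGENIC,
    "indeterminate": PathogenicityClass.INDETERMINATE,
    "highly likely neutral": PathogenicityClass.HIGHLY_LIKELY_NEUTRAL,
}


def parse_class_label(label: str) -> PathogenicityClass:
    key = " ".join(label.split()).lower()
    try:
        return _PRINTED[key]
    except KeyError:
        raise ClassificationError(f"unrecognized classification label {label!r}") from None


@dataclass(frozen=True)
class EvidenceRule:
    """One scoring-table row: a named boolean feature worth ``points``."""

    name: str
    points: int

    def __post_init__(self) -> None:
        if not isinstance(self.points, int) or isinstance(self.points, bool):
            raise ScoringError(f"points for {self.name!r} must be an integer")


@dataclass(frozen=True)
class ScoringConfig:
    """Evidence table plus the four VS cut-offs.

    The thresholds partition the integers completely:
    ``>= highly_likely_min`` / ``likely_min..highly_likely_min-1`` /
    ``indeterminate_min..likely_min-1`` / ``< indeterminate_min``.
    """

    rules: tuple[EvidenceRule, ...]
    highly_likely_min: int = 11
    likely_min: int = 5
    indeterminate_min: int = 0

    def __post_init__(self) -> None:
        for t in (self.highly_likely_min, self.likely_min, self.indeterminate_min):
            if not isinstance(t, int) or isinstance(t, bool):
                raise ScoringError("VS thresholds must be integers")
        if not (self.indeterminate_min < self.likely_min < self.highly_likely_min):
            raise ScoringError("VS thresholds must be strictly increasing")
        names = [r.name for r in self.rules]
        if len(names) != len(set(names)):
            raise ScoringError("duplicate evidence-rule names")


def default_scoring_config() -> ScoringConfig:
    """A documented default evidence table for UCV scoring.

    Positive evidence: strong cross-species conservation, a radical
    (high-Grantham-distance) substitution, predicted splice-signal loss,
    absence from control populations, cosegregation with disease in the
    family, prior reports in unrelated patients.  Negative evidence:
    observation in healthy controls or failure to segregate.
    """
    return ScoringConfig(
        rules=(
            EvidenceRule("conservation_strong", 5),
            EvidenceRule("grantham_radical", 4),
            EvidenceRule("grantham_moderate", 2),
            EvidenceRule("splice_predictor_loss", 3),
            EvidenceRule("absent_in_controls", 2),
            EvidenceRule("cosegregates_with_disease", 3),
            EvidenceRule("reported_in_unrelated_patients", 2),
            EvidenceRule("observed_in_controls", -2),
            EvidenceRule("benign_cosegregation", -3),
        )
    )


@dataclass(frozen=True)
class VariantScore:
    """Integer VS with its satisfied components."""

    components: Mapping[str, int]
    vs_total: int

    def __post_init__(self) -> None:
        if sum(self.components.values()) != self.vs_total:
            raise ScoringError("vs_total must equal the sum of components")


def compute_variant_score(
    variant: VariantCall,
    cfg: ScoringConfig,
    features: Mapping[str, bool],
) -> VariantScore:
    """Sum the points of satisfied evidence rules for a UCV.

    Every rule in ``cfg`` must have its feature present in ``features``;
    truncating variants are rejected (they bypass scoring entirely).
    """
    if variant.consequence is not None and is_truncating(variant.consequence):
        raise ScoringError("truncating variants are not scored; they are "
                           "definitely pathogenic by rule")
    components: dict[str, int] = {}
    for rule in cfg.rules:
        if rule.name not in features:
            raise ScoringError(f"missing feature {rule.name!r}")
        if features[rule.name]:
            components[rule.name] = rule.points
    return VariantScore(components=components, vs_total=sum(components.values()))


def vs_to_class(vs: int, cfg: Optional[ScoringConfig] = None) -> PathogenicityClass:
    """Map an integer VS to its pathogenicity class."""
    if not isinstance(vs, int) or isinstance(vs, bool):
        raise ScoringError(f"VS must be an integer, got {vs!r}")
    cfg = cfg or default_scoring_config()
    if vs >= cfg.highly_likely_min:
        return PathogenicityClass.HIGHLY_LIKELY_PATHOGENIC
    if vs >= cfg.likely_min:
        return PathogenicityClass.LIKELY_PATHOGENIC
    if vs >= cfg.indeterminate_min:
        return PathogenicityClass.INDETERMINATE
    return PathogenicityClass.HIGHLY_LIKELY_NEUTRAL


def classify_variant(
    variant: VariantCall,
    score: Optional[VariantScore] = None,
    cfg: Optional[ScoringConfig] = None,
    allow_unscored: bool = False,
) -> PathogenicityClass:
    """Classify a cascade-surviving variant.

    Truncating consequences dominate any score.  Otherwise the VS class is
    used; fixture variants without score features fall back to their curated
    class.  An unscored, uncurated UCV is an error unless ``allow_unscored``
    (then it is conservatively called indeterminate, i.e. not reportable).
    """
    if variant.consequence is None:
        raise ClassificationError("variant has no consequence annotation")
    if is_truncating(variant.consequence):
        return PathogenicityClass.DEFINITELY_PATHOGENIC
    if score is not None:
        return vs_to_class(score.vs_total, cfg)
    if variant.curated_class is not None:
        return parse_class_label(variant.curated_class)
    if allow_unscored:
        return PathogenicityClass.INDETERMINATE
    raise ClassificationError(
        f"UCV {variant.contig}:{variant.pos} has neither a score nor a curated class"
    )


def is_reportable(c: PathogenicityClass) -> bool:
    """True iff the class counts as a diagnostic (pathogenic) finding."""
    return c in REPORTABLE_CLASSES
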