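"""End-to-end orchestration and per-sample diagnostic reporting.

A sample is *diagnosed* when it carries at least one reportable finding —
a cascade-surviving small variant classified definitely / highly-likely /
likely pathogenic, or a large deletion event.  The cohort diagnostic rate is
the percentage of diagnosed samples, rendered to one decimal (half-up).
Samples without findings get the low-coverage follow-up flag attached.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .annotation import ConsequenceKind
from .classify import (PathogenicityClass, classify_variant, is_reportable,
                       parse_class_label)
from .cnv import CnvCall, CoverageMatrix, detect_deletions
from .cohort import (CohortRecord, records_to_structural_events,
                     records_to_variant_calls)
from .coverage import AuditFlag, DepthTrack, flag_missed_mutation_risk, low_coverage_regions
from .filters import FilterDecision, run_cascade
from .variants import StructuralEvent, VariantCall


@dataclass
class PipelineConfig:
    """Stage thresholds, all at their published/default values."""

    min_fraction: float = 0.20
    max_freq: float = 0.05
    cnv_k: int = 3
    cnv_threshold: float = 1.5
    cnv_min_targets: int = 2
    min_depth: int = 20
    allow_unscored_ucv: bool = True  # unscored UCVs become indeterminate (not reportable)


@dataclass(frozen=True)
class ReportedMutation:
    """One reportable finding in a sample."""

    gene: str
    kind: ConsequenceKind
    classification: PathogenicityClass
    cdna: Optional[str] = None
    protein: Optional[str] = None
    in_duplicated_region: bool = False


@dataclass
class DiagnosticReport:
    sample_id: str
    mutations: list[ReportedMutation] = field(default_factory=list)
    cnv_events: list = field(default_factory=list)
    filter_audit: list[FilterDecision] = field(default_factory=list)
    low_coverage: Optional[AuditFlag] = None

    @property
    def diagnosed(self) -> bool:
        return bool(self.mutations)


@dataclass
class CohortSummary:
    n_samples: int
    n_reported_mutations: int
    per_gene_counts: dict[str, int]
    duplicated_region_count: int
    diagnostic_rate: Optional[float]  # percentage to one decimal, None when n=0

    @property
    def rate_label(self) -> str:
        return "n=0" if self.diagnostic_rate is None else f"{self.diagnostic_rate}%"


def diagnostic_rate(reports: Sequence[DiagnosticReport]) -> Optional[float]:
    """100 × diagnosed / n, one decimal, round half-up; None for n=0."""
    n = len(reports)
    if n == 0:
        return None
    k = sum(1 for r in reports if r.diagnosed)
    return float((Decimal(100 * k) / Decimal(n)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def duplicated_region_count(reports: Sequence[DiagnosticReport]) -> int:
    """Number of reported mutations flagged inside the segmentally duplicated region."""
    return sum(1 for r in reports for m in r.mutations if m.in_duplicated_region)


def _summarize(reports: Sequence[DiagnosticReport]) -> CohortSummary:
    per_gene: dict[str, int] = {}
    n_mut = 0
    for r in reports:
        for m in r.mutations:
            n_mut += 1
            per_gene[m.gene] = per_gene.get(m.gene, 0) + 1
    return CohortSummary(
        n_samples=len(reports),
        n_reported_mutations=n_mut,
        per_gene_counts=dict(sorted(per_gene.items())),
        duplicated_region_count=duplicated_region_count(reports),
        diagnostic_rate=diagnostic_rate(reports),
    )


def run_cohort_pipeline(
    records: Sequence[CohortRecord],
    config: Optional[PipelineConfig] = None,
) -> tuple[list[DiagnosticReport], CohortSummary]:
    """Run the full analysis on a published-cohort fixture.

    Count-bearing records go through the filter cascade and classification
    (truncating consequences dominate; curated classes stand in for UCV
    scores).  SV records enter as structural deletion events, definitely
    pathogenic by rule.  Samples without findings get the Sanger flag.
    """
    config = config or PipelineConfig()
    sample_ids = sorted(dict.fromkeys(r.sample_id for r in records))
    calls = records_to_variant_calls(records)
    events = records_to_structural_events(records)
    decisions = run_cascade(calls, config.min_fraction, config.max_freq)

    reports = {s: DiagnosticReport(sample_id=s) for s in sample_ids}
    for d in decisions:
        v = d.variant
        reports[v.sample_id].filter_audit.append(d)
        if not d.passed:
            continue
        pclass = classify_variant(v)
        if is_reportable(pclass):
            cons = v.consequence
            reports[v.sample_id].mutations.append(ReportedMutation(
                gene=v.contig, kind=cons.kind, classification=pclass,
                cdna=cons.cdna_label, protein=cons.protein_label,
                in_duplicated_region=v.in_duplicated_region,
            ))
    for ev in events:
        reports[ev.sample_id].cnv_events.append(ev)
        reports[ev.sample_id].mutations.append(ReportedMutation(
            gene=ev.contig, kind=ConsequenceKind.STRUCTURAL_DELETION,
            classification=PathogenicityClass.DEFINITELY_PATHOGENIC,
            cdna=ev.label, in_duplicated_region=ev.in_duplicated_region,
        ))
    ordered = [reports[s] for s in sample_ids]
    for r in ordered:
        r.low_coverage = flag_missed_mutation_risk(r.sample_id, (), r.diagnosed)
    return ordered, _summarize(ordered)


def run_pipeline(
    variants: Sequence[VariantCall],
    coverage_matrix: Optional[CoverageMatrix] = None,
    depth_tracks: Optional[Sequence[DepthTrack]] = None,
    config: Optional[PipelineConfig] = None,
) -> tuple[list[DiagnosticReport], CohortSummary]:
    """Run the analysis on arbitrary (e.g. simulated) inputs.

    Stages: filter cascade → classification (unscored UCVs are conservatively
    indeterminate unless disabled) → SVD-ZRPKM deletion calling on the
    coverage matrix → low-coverage audit from the depth tracks for samples
    left without findings.  Deterministic given inputs and configuration.
    """
    config = config or PipelineConfig()
    sample_ids = sorted({v.sample_id for v in variants})
    if coverage_matrix is not None:
        sample_ids = sorted(set(sample_ids) | set(coverage_matrix.samples))
    if depth_tracks:
        sample_ids = sorted(set(sample_ids) | {t.sample_id for t in depth_tracks})

    decisions = run_cascade(variants, config.min_fraction, config.max_freq)
    reports = {s: DiagnosticReport(sample_id=s) for s in sample_ids}
    for d in decisions:
        v = d.variant
        reports[v.sample_id].filter_audit.append(d)
        if not d.passed:
            continue
        pclass = classify_variant(v, allow_unscored=config.allow_unscored_ucv)
        if is_reportable(pclass):
            cons = v.consequence
            reports[v.sample_id].mutations.append(ReportedMutation(
                gene=v.contig, kind=cons.kind, classification=pclass,
                cdna=cons.cdna_label, protein=cons.protein_label,
                in_duplicated_region=v.in_duplicated_region,
            ))

    if coverage_matrix is not None:
        cnv_calls, _ = detect_deletions(
            coverage_matrix, k=config.cnv_k, threshold=config.cnv_threshold,
            min_targets=config.cnv_min_targets,
        )
        for c in cnv_calls:
            reports[c.sample_id].cnv_events.append(c)
            if c.direction == "deletion":
                contig, start, _ = coverage_matrix.targets[c.first_target]
                _, _, end = coverage_matrix.targets[c.last_target]
                reports[c.sample_id].mutations.append(ReportedMutation(
                    gene=contig, kind=ConsequenceKind.STRUCTURAL_DELETION,
                    classification=PathogenicityClass.DEFINITELY_PATHOGENIC,
                    cdna=f"g.{start + 1}-{end}del",
                ))

    tracks_by_sample = {t.sample_id: t for t in (depth_tracks or [])}
    for s, r in reports.items():
        regions = ()
        if s in tracks_by_sample:
            regions = low_coverage_regions(tracks_by_sample[s], config.min_depth)
        r.low_coverage = flag_missed_mutation_risk(s, regions, r.diagnosed)
    ordered = [reports[s] for s in sample_ids]
    return ordered, _summarize(ordered)


def report_to_dict(report: DiagnosticReport) -> dict:
    """JSON-serializable rendering of one sample report."""
    return {
        "sample_id": report.sample_id,
        "diagnosed": report.diagnosed,
        "mutations": [
            {
                "gene": m.gene, "kind": m.kind.value,
                "classification": m.classification.value,
                "cdna": m.cdna, "protein": m.protein,
                "in_duplicated_region": m.in_duplicated_region,
            }
            for m in report.mutations
        ],
        "cnv_events": [
            {"sample_id": getattr(e, "sample_id", report.sample_id),
             "detail": str(e)}
            for e in report.cnv_events
        ],
        "filter_audit": [
            {
                "contig": d.variant.contig, "pos": d.variant.pos,
                "passed": d.passed, "failed_rules": d.failed_rules,
                "rescue_applied": d.rescue_applied,
            }
            for d in report.filter_audit
        ],
        "low_coverage": None if report.low_coverage is None else {
            "sanger_recommended": report.low_coverage.sanger_recommended,
            "regions": [list(iv) for iv in report.low_coverage.regions],
            "message": report.low_coverage.message,
        },
    }


def summary_to_dict(summary: CohortSummary) -> dict:
    return {
        "n_samples": summary.n_samples,
        "n_reported_mutations": summary.n_reported_mutations,
        "per_gene_counts": summary.per_gene_counts,
        "duplicated_region_count": summary.duplicated_region_count,
        "diagnostic_rate": summary.diagnostic_rate,
        "rate_label": summary.rate_label,
    }
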