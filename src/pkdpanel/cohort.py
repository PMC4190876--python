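"""Published-cohort fixtures: loading, validation and conversion to pipeline inputs.

Two machine-readable tables ship with the package: a 36-sample validation
cohort (samples with previously characterized PKD1/PKD2 mutations, including
two large deletions and one sample whose mutation was missed for lack of
coverage) and a 12-sample discovery cohort (two samples without findings, one
sample carrying mutations in both genes).  The tables carry the published
per-variant ref/alt read counts, curated HGVS-style labels, disease-database
membership and pathogenicity classifications, so the cohort-level diagnostic
results can be recomputed entirely offline.

Stranded read counts are not published; when converting records to variant
calls the totals are split as evenly as possible across strands (odd counts
give the forward strand the extra read).  This is a fixture convention, not
data.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .annotation import Consequence, ConsequenceKind, AnnotationError
from .variants import StructuralEvent, VariantCall

_ABSENT = {"", "-", "–", "—"}  # ASCII hyphen / en / em dash

COLUMNS = [
    "Sample", "Gene", "Duplicated region", "cDNA change", "Protein change",
    "PKDB", "# Patients", "Classification", "Ref counts", "Variants counts",
    "SV coordinates",
]


class CohortParseError(ValueError):
    pass


@dataclass(frozen=True)
class CohortRecord:
    """One table row: a mutation in a sample, or an all-absent (undetected) row.

    Exactly one of three shapes is valid: read-count-bearing (small variant),
    SV-coordinate-bearing (large deletion), or fully absent (no finding).
    """

    sample_id: str
    gene: Optional[str] = None
    in_duplicated_region: bool = False
    cdna_change: Optional[str] = None
    protein_change: Optional[str] = None
    pkdb_present: bool = False
    prior_patient_count: int = 0
    printed_classification: Optional[str] = None
    ref_count: Optional[int] = None
    variant_count: Optional[int] = None
    sv_coordinates: Optional[tuple[int, int]] = None  # 0-based half-open
    sv_label: Optional[str] = None

    def __post_init__(self) -> None:
        has_counts = self.ref_count is not None and self.variant_count is not None
        has_sv = self.sv_coordinates is not None
        empty = self.gene is None and self.cdna_change is None
        if sum([has_counts, has_sv, empty]) != 1:
            raise CohortParseError(
                f"record {self.sample_id!r} must carry counts, SV coordinates "
                "or be fully absent (exactly one)"
            )
        if has_counts and (self.ref_count < 0 or self.variant_count < 0):
            raise CohortParseError(f"negative read count in {self.sample_id!r}")

    @property
    def is_empty(self) -> bool:
        return self.gene is None and self.cdna_change is None

    @property
    def has_counts(self) -> bool:
        return self.ref_count is not None


def _fixture_path(name: str) -> Path:
    return Path(resources.files("pkdpanel").joinpath("data", name))


def validation_fixture_path() -> Path:
    return _fixture_path("validation_cohort.tsv")


def discovery_fixture_path() -> Path:
    return _fixture_path("discovery_cohort.tsv")


_SV_RE = re.compile(r"g\.(\d+)-(\d+)del")


def _parse_row(fields: list[str], lineno: int) -> CohortRecord:
    if len(fields) != len(COLUMNS):
        raise CohortParseError(
            f"line {lineno}: expected {len(COLUMNS)} columns, got {len(fields)}"
        )
    get = lambda i: fields[i].strip()
    absent = lambda s: s in _ABSENT

    sample = get(0)
    if absent(sample):
        raise CohortParseError(f"line {lineno}: missing sample identifier")
    try:
        gene = None if absent(get(1)) else get(1)
        dup = get(2).lower() == "yes"
        cdna = None if absent(get(3)) else get(3)
        protein = None if absent(get(4)) else get(4)
        pkdb = get(5).lower() == "present"
        npat = 0 if absent(get(6)) else int(get(6))
        printed = None if absent(get(7)) else get(7)
        ref_c = None if absent(get(8)) else int(get(8))
        var_c = None if absent(get(9)) else int(get(9))
        sv_raw = None if absent(get(10)) else get(10)
    except ValueError as exc:
        raise CohortParseError(f"line {lineno}: {exc}") from None

    sv_coords = None
    if sv_raw is not None:
        m = _SV_RE.fullmatch(sv_raw)
        if not m:
            raise CohortParseError(f"line {lineno}: malformed SV coordinates {sv_raw!r}")
        sv_coords = (int(m.group(1)) - 1, int(m.group(2)))  # to 0-based half-open

    try:
        return CohortRecord(
            sample_id=sample, gene=gene, in_duplicated_region=dup,
            cdna_change=cdna, protein_change=protein, pkdb_present=pkdb,
            prior_patient_count=npat, printed_classification=printed,
            ref_count=ref_c, variant_count=var_c,
            sv_coordinates=sv_coords, sv_label=sv_raw,
        )
    except CohortParseError as exc:
        raise CohortParseError(f"line {lineno}: {exc}") from None


def load_cohort(fixture_path: Union[str, Path]) -> list[CohortRecord]:
    """Load a cohort table (TSV with the published column layout)."""
    path = Path(fixture_path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise CohortParseError(f"{path}: empty fixture")
    header = lines[0].split("\t")
    if header != COLUMNS:
        raise CohortParseError(f"{path}: unexpected header {header!r}")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        records.append(_parse_row(line.split("\t"), lineno))
    return records


def load_validation_cohort(fixture_path: Union[str, Path, None] = None) -> list[CohortRecord]:
    """The 36-sample validation cohort (35 mutations incl. two large deletions)."""
    return load_cohort(fixture_path or validation_fixture_path())


def load_discovery_cohort(fixture_path: Union[str, Path, None] = None) -> list[CohortRecord]:
    """The 12-sample discovery cohort (11 mutations in 10 samples)."""
    return load_cohort(fixture_path or discovery_fixture_path())


def write_cohort(records: Sequence[CohortRecord], path: Union[str, Path]) -> None:
    """Write records back to the fixture TSV layout (round-trip safe)."""
    def cell(value) -> str:
        return "-" if value in (None, "") else str(value)

    rows = ["\t".join(COLUMNS)]
    for r in records:
        if r.is_empty:
            rows.append("\t".join([r.sample_id] + ["-"] * (len(COLUMNS) - 1)))
            continue
        rows.append("\t".join([
            r.sample_id, cell(r.gene), "Yes" if r.in_duplicated_region else "No",
            cell(r.cdna_change), cell(r.protein_change),
            "Present" if r.pkdb_present else "Absent",
            str(r.prior_patient_count), cell(r.printed_classification),
            cell(r.ref_count), cell(r.variant_count), cell(r.sv_label),
        ]))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# curated-label consequence parsing

_INTRON_OFFSET_RE = re.compile(r"c\.\*?-?\d+([+-])(\d+)")
_SNV_RE = re.compile(r"c\.(\d+)([ACGT])>([ACGT])")
_MISSENSE_RE = re.compile(r"p\.\(([A-Z][a-z]{2})\d+([A-Z][a-z]{2})\)")
_LEADING_POS_RE = re.compile(r"c\.\*?(-?\d+)")


def consequence_from_labels(cdna: str, protein: Optional[str]) -> Consequence:
    """Infer a consequence kind from curated HGVS-style labels.

    Intronic cDNA offsets take precedence over the protein suffix: a variant
    printed as ``c.N+25_...del`` with a downstream ``fs`` protein label is a
    splice-region/intronic change at the DNA level, not an exonic frameshift —
    and it is the DNA-level kind that routes classification.
    """
    protein = protein or ""
    m = _INTRON_OFFSET_RE.search(cdna)
    if m:
        offset = int(m.group(2))
        if offset <= 2:
            return Consequence(ConsequenceKind.CANONICAL_SPLICE, cdna)
        if offset <= 10:
            return Consequence(ConsequenceKind.NONCANONICAL_SPLICE, cdna)
        return Consequence(ConsequenceKind.INTRONIC, cdna)
    if "fs" in protein:
        return Consequence(ConsequenceKind.FRAMESHIFT, cdna, protein)
    if "*" in protein:
        return Consequence(ConsequenceKind.STOP_GAIN, cdna, protein)
    if "del" in protein:
        # residue-level deletion without frameshift, e.g. p.(Ile2260del)
        return Consequence(ConsequenceKind.INFRAME_INDEL, cdna, protein)
    m = _MISSENSE_RE.fullmatch(protein)
    if m:
        kind = (
            ConsequenceKind.SYNONYMOUS if m.group(1) == m.group(2)
            else ConsequenceKind.MISSENSE
        )
        return Consequence(kind, cdna, protein)
    raise AnnotationError(f"cannot interpret labels cdna={cdna!r} protein={protein!r}")


def split_strands(total: int) -> tuple[int, int]:
    """Even forward/reverse split; odd totals give the forward strand the extra read."""
    fwd = (total + 1) // 2
    return fwd, total - fwd


def records_to_variant_calls(records: Iterable[CohortRecord]) -> list[VariantCall]:
    """Convert count-bearing records into VariantCall objects.

    Positions are the curated cDNA coordinates (there is no attempt to map
    the published variants back onto the genomic reference); REF/ALT alleles
    are taken from simple substitution labels and default to placeholders for
    indels.
    """
    calls = []
    for r in records:
        if not r.has_counts:
            continue
        cons = consequence_from_labels(r.cdna_change, r.protein_change)
        m = _SNV_RE.fullmatch(r.cdna_change)
        if m:
            pos, ref, alt = int(m.group(1)) - 1, m.group(2), m.group(3)
        else:
            mpos = _LEADING_POS_RE.search(r.cdna_change)
            pos = abs(int(mpos.group(1))) - 1 if mpos else 0
            ref, alt = "N", "<INDEL>"
        fwd_ref, rev_ref = split_strands(r.ref_count)
        fwd_alt, rev_alt = split_strands(r.variant_count)
        calls.append(VariantCall(
            sample_id=r.sample_id, contig=r.gene, pos=pos, ref=ref, alt=alt,
            fwd_ref=fwd_ref, rev_ref=rev_ref, fwd_alt=fwd_alt, rev_alt=rev_alt,
            pop_freqs={}, in_pathogenic_db=r.pkdb_present, consequence=cons,
            curated_class=r.printed_classification,
            in_duplicated_region=r.in_duplicated_region,
        ))
    return calls


def records_to_structural_events(records: Iterable[CohortRecord]) -> list[StructuralEvent]:
    """Convert SV-coordinate-bearing records into structural deletion events."""
    events = []
    for r in records:
        if r.sv_coordinates is None:
            continue
        start, end = r.sv_coordinates
        events.append(StructuralEvent(
            sample_id=r.sample_id, contig=r.gene, start=start, end=end,
            kind="deletion", label=r.sv_label,
            curated_class=r.printed_classification,
            in_duplicated_region=r.in_duplicated_region,
        ))
    return events
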