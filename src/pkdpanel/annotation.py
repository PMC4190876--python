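"""Molecular-consequence annotation against a single-transcript gene model.

The diagnostic logic downstream splits variants into two arms: *truncating*
changes (stop-gain, frameshift, canonical ±1/±2 splice, multi-exon structural
deletion), which are reported as definitely pathogenic without further
evidence, and everything else, which enters the Unclassified Sequence Variant
(UCV) scoring route.  This module predicts which arm a variant belongs to from
a minimal transcript model: ordered exons, a CDS interval and the reference
sequence.

Coordinates are 0-based half-open internally; cDNA ("c.") labels follow the
1-based HGVS convention.  The HGVS output is a simplified dialect: indels are
not 3'-shifted and only single-transcript annotation is supported.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqUtils import seq3


class AnnotationError(ValueError):
    """Raised when a variant or label cannot be interpreted on the transcript."""


class ReferenceMismatchError(AnnotationError):
    """The declared REF allele disagrees with the reference sequence."""


class ConsequenceKind(str, enum.Enum):
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    NONCANONICAL_SPLICE = "noncanonical_splice"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    STRUCTURAL_DELETION = "structural_deletion"


#: Consequences reported as definitely pathogenic without scoring.
TRUNCATING_KINDS = frozenset(
    {
        ConsequenceKind.STOP_GAIN,
        ConsequenceKind.FRAMESHIFT,
        ConsequenceKind.CANONICAL_SPLICE,
        ConsequenceKind.STRUCTURAL_DELETION,
    }
)

#: Consequences that enter the UCV scoring route.
UCV_KINDS = frozenset(
    {
        ConsequenceKind.MISSENSE,
        ConsequenceKind.NONCANONICAL_SPLICE,
        ConsequenceKind.INFRAME_INDEL,
    }
)


@dataclass(frozen=True)
class Consequence:
    """Predicted molecular effect of a variant on the transcript."""

    kind: ConsequenceKind
    cdna_label: str
    protein_label: Optional[str] = None


def is_truncating(consequence: Consequence) -> bool:
    """True for consequences that predict a prematurely truncated protein."""
    return consequence.kind in TRUNCATING_KINDS


@dataclass
class TranscriptModel:
    """One transcript on one contig: exons, CDS bounds and reference access.

    Parameters
    ----------
    gene_id:
        Gene symbol used in reports (e.g. ``PKD1``-like ``GENE1``).
    strand:
        ``"+"`` or ``"-"``; cDNA numbering runs 5'→3' on this strand.
    exons:
        Sorted, non-overlapping genomic intervals (0-based half-open).
    cds_start, cds_end:
        Genomic CDS span (0-based half-open); boundaries must fall inside
        exons and the spliced CDS length must be a multiple of 3.
    reference:
        Full contig sequence (uppercase ACGT string).
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    reference: str
    contig: str = "chrSim"
    _cum: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError("transcript needs at least one exon")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"empty exon interval ({s}, {e})")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError("exons must be sorted and non-overlapping")
        self.exons = exons
        if not (self._is_exonic(self.cds_start) and self._is_exonic(self.cds_end - 1)):
            raise ValueError("CDS boundaries must lie inside exons")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length {self.cds_length} not divisible by 3")
        # cumulative exonic bases before each exon, for fast projection
        cum = [0]
        for s, e in exons:
            cum.append(cum[-1] + (e - s))
        self._cum = tuple(cum)

    # -- basic geometry ------------------------------------------------
    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(
            max(0, min(e, self.cds_end) - max(s, self.cds_start)) for s, e in self.exons
        )

    def fetch(self, start: int, end: int) -> str:
        return self.reference[start:end]

    def _is_exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def _exonic_index(self, pos: int) -> int:
        """0-based index of ``pos`` within the spliced transcript (genomic order)."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos < e:
                return self._cum[i] + (pos - s)
        raise ValueError(f"position {pos} is not exonic")

    def _cds_offset_genomic_order(self, pos: int) -> int:
        """Spliced-bases offset of ``pos`` from cds_start, in genomic order."""
        return self._exonic_index(pos) - self._exonic_index(self.cds_start)

    def cds_index(self, pos: int) -> int:
        """0-based index of an exonic genomic position within the spliced CDS
        (transcript orientation).  Negative for 5'UTR, >= cds_length for 3'UTR."""
        off = self._cds_offset_genomic_order(pos)
        if self.strand == "+":
            return off
        last = self._exonic_index(self.cds_end - 1) - self._exonic_index(self.cds_start)
        return last - off

    def cds_sequence(self) -> str:
        parts = []
        for s, e in self.exons:
            a, b = max(s, self.cds_start), min(e, self.cds_end)
            if a < b:
                parts.append(self.reference[a:b])
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


def project_to_cdna(pos: int, transcript: TranscriptModel) -> str:
    """Project a genomic position to a cDNA-coordinate label.

    Exonic CDS positions map to ``c.N`` (1-based); exonic UTR positions to
    ``c.-N`` / ``c.*N``; intronic positions to the nearest exon edge as
    ``c.N+k`` or ``c.N-k``; positions outside the transcript span return
    ``"intergenic"``.
    """
    lo, hi = transcript.span
    if not (lo <= pos < hi):
        return "intergenic"
    if transcript._is_exonic(pos):
        return _exonic_label(pos, transcript)
    # intronic: nearest exon boundary, ties to the upstream (donor) side
    prev_end = max(e for s, e in transcript.exons if e <= pos)
    next_start = min(s for s, e in transcript.exons if s > pos)
    d_prev = pos - prev_end + 1          # offset past the last base of prev exon
    d_next = next_start - pos            # offset before the first base of next exon
    if transcript.strand == "+":
        if d_prev <= d_next:
            return f"{_exonic_label(prev_end - 1, transcript)}+{d_prev}"
        return f"{_exonic_label(next_start, transcript)}-{d_next}"
    else:
        # on the minus strand the donor side of the intron is the *next* exon
        if d_next <= d_prev:
            return f"{_exonic_label(next_start, transcript)}+{d_next}"
        return f"{_exonic_label(prev_end - 1, transcript)}-{d_prev}"


def _exonic_label(pos: int, transcript: TranscriptModel) -> str:
    i = transcript.cds_index(pos)
    n = transcript.cds_length
    if i < 0:
        return f"c.-{-i}"
    if i >= n:
        return f"c.*{i - n + 1}"
    return f"c.{i + 1}"


def _intron_offset(pos: int, transcript: TranscriptModel) -> Optional[int]:
    """Unsigned distance from an intronic position to the nearest exon edge,
    or None for exonic positions."""
    if transcript._is_exonic(pos):
        return None
    lo, hi = transcript.span
    if not (lo <= pos < hi):
        return None
    prev_end = max(e for s, e in transcript.exons if e <= pos)
    next_start = min(s for s, e in transcript.exons if s > pos)
    return min(pos - prev_end + 1, next_start - pos)


def classify_consequence(
    variant,
    transcript: TranscriptModel,
    noncanonical_window: int = 10,
    check_reference: bool = True,
) -> Consequence:
    """Classify a variant's molecular effect on ``transcript``.

    ``variant`` needs ``pos``, ``ref`` and ``alt`` attributes (genomic,
    forward-strand alleles), or ``start``/``end`` for structural events.
    Intronic SNVs at offsets 1–2 are canonical splice; offsets
    3..``noncanonical_window`` are noncanonical splice; deeper is intronic.
    """
    # structural events: deletion spanning one or more exons
    if hasattr(variant, "start") and hasattr(variant, "end") and not hasattr(variant, "ref"):
        s, e = int(variant.start), int(variant.end)
        n_exons = sum(1 for xs, xe in transcript.exons if xs < e and s < xe)
        label = f"g.{s + 1}-{e}del"
        if n_exons >= 1:
            return Consequence(ConsequenceKind.STRUCTURAL_DELETION, label)
        lo, hi = transcript.span
        kind = ConsequenceKind.INTRONIC if (s < hi and e > lo) else ConsequenceKind.INTERGENIC
        return Consequence(kind, label)

    pos, ref, alt = int(variant.pos), str(variant.ref), str(variant.alt)
    if check_reference and all(c in "ACGT" for c in ref):
        observed = transcript.fetch(pos, pos + len(ref))
        if observed != ref:
            raise ReferenceMismatchError(
                f"REF {ref!r} at {transcript.contig}:{pos} does not match reference {observed!r}"
            )

    lo, hi = transcript.span
    if pos >= hi or pos + max(1, len(ref)) <= lo:
        return Consequence(ConsequenceKind.INTERGENIC, "intergenic")

    if len(ref) != len(alt):
        return _classify_indel(pos, ref, alt, transcript, noncanonical_window)
    return _classify_snv(pos, ref, alt, transcript, noncanonical_window)


def _splice_kind(offset: int, window: int) -> ConsequenceKind:
    if offset <= 2:
        return ConsequenceKind.CANONICAL_SPLICE
    if offset <= window:
        return ConsequenceKind.NONCANONICAL_SPLICE
    return ConsequenceKind.INTRONIC


def _classify_snv(
    pos: int, ref: str, alt: str, t: TranscriptModel, window: int
) -> Consequence:
    label_pos = project_to_cdna(pos, t)
    if t._is_exonic(pos):
        i = t.cds_index(pos)
        if 0 <= i < t.cds_length:
            cds = t.cds_sequence()
            ref_t, alt_t = ref, alt
            if t.strand == "-":
                ref_t = str(Seq(ref).reverse_complement())
                alt_t = str(Seq(alt).reverse_complement())
            cdna = f"{label_pos}{ref_t}>{alt_t}"
            codon_i = i // 3
            codon = list(cds[codon_i * 3 : codon_i * 3 + 3])
            codon[i % 3] = alt_t
            old_aa = str(Seq(cds[codon_i * 3 : codon_i * 3 + 3]).translate())
            new_aa = str(Seq("".join(codon)).translate())
            num = codon_i + 1
            if new_aa == old_aa:
                return Consequence(
                    ConsequenceKind.SYNONYMOUS, cdna, f"p.({seq3(old_aa)}{num}=)"
                )
            if new_aa == "*":
                return Consequence(
                    ConsequenceKind.STOP_GAIN, cdna, f"p.({seq3(old_aa)}{num}*)"
                )
            return Consequence(
                ConsequenceKind.MISSENSE,
                cdna,
                f"p.({seq3(old_aa)}{num}{seq3(new_aa)})",
            )
        # exonic but UTR: treated as non-coding, no protein label
        return Consequence(ConsequenceKind.INTRONIC, f"{label_pos}{ref}>{alt}")
    offset = _intron_offset(pos, t)
    return Consequence(_splice_kind(offset, window), f"{label_pos}{ref}>{alt}")


def _classify_indel(
    pos: int, ref: str, alt: str, t: TranscriptModel, window: int
) -> Consequence:
    size = abs(len(ref) - len(alt))
    # changed interval (after the shared anchor base, VCF-style)
    start = pos + 1 if (ref and alt and ref[0] == alt[0]) else pos
    end = max(start + 1, pos + len(ref))
    cdna = f"{project_to_cdna(start, t)}_{project_to_cdna(end - 1, t)}" + (
        "del" if len(ref) > len(alt) else "ins"
    )
    touches_cds = any(
        t._is_exonic(p) and 0 <= t.cds_index(p) < t.cds_length for p in range(start, end)
    )
    if touches_cds:
        if size % 3 != 0:
            i = next(
                t.cds_index(p)
                for p in range(start, end)
                if t._is_exonic(p) and 0 <= t.cds_index(p) < t.cds_length
            )
            num = i // 3 + 1
            aa = str(Seq(t.cds_sequence()[(num - 1) * 3 : num * 3]).translate())
            return Consequence(ConsequenceKind.FRAMESHIFT, cdna, f"p.({seq3(aa)}{num}fs)")
        return Consequence(ConsequenceKind.INFRAME_INDEL, cdna)
    offsets = [o for o in (_intron_offset(p, t) for p in range(start, end)) if o is not None]
    if offsets:
        return Consequence(_splice_kind(min(offsets), window), cdna)
    return Consequence(ConsequenceKind.INTRONIC, cdna)
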