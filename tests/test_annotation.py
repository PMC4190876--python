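"""Consequence annotation: cDNA projection, codon effects, splice windows."""
import numpy as np
import pytest
from Bio.Seq import Seq

from pkdpanel.annotation import (Consequence, ConsequenceKind,
                                 ReferenceMismatchError, TranscriptModel,
                                 classify_consequence, is_truncating,
                                 project_to_cdna)
from pkdpanel.variants import StructuralEvent, VariantCall


def _plus_transcript() -> TranscriptModel:
    # 3 exons of 100 bp; CDS = whole spliced transcript = ATG + 99×CAG
    cds = "ATG" + "CAG" * 99
    seq = ("T" * 100 + cds[:100] + "T" * 100 + cds[100:200]
           + "T" * 100 + cds[200:] + "T" * 100)
    return TranscriptModel(
        gene_id="G", strand="+",
        exons=((100, 200), (300, 400), (500, 600)),
        cds_start=100, cds_end=600, reference=seq,
    )


@pytest.fixture(scope="module")
def tx():
    return _plus_transcript()


def _call(pos, ref, alt):
    return VariantCall(sample_id="s", contig="chrSim", pos=pos, ref=ref, alt=alt,
                       fwd_ref=10, rev_ref=10, fwd_alt=10, rev_alt=10)


class TestProjection:
    @pytest.mark.parametrize("pos, label", [
        (100, "c.1"),           # first CDS base
        (199, "c.100"),         # last base of exon 1
        (200, "c.100+1"),       # first intron base after the exon
        (299, "c.101-1"),       # last intron base before exon 2
        (99, "intergenic"),     # outside the transcript span
        (600, "intergenic"),
    ])
    def test_plus_strand_labels(self, tx, pos, label):
        assert project_to_cdna(pos, tx) == label

    def test_five_prime_utr_label(self):
        cds = "ATG" + "CAG" * 29
        seq = "T" * 100 + "A" * 10 + cds + "T" * 100
        t = TranscriptModel(gene_id="G", strand="+", exons=((100, 100 + 10 + 90),),
                            cds_start=110, cds_end=200, reference=seq)
        assert project_to_cdna(100, t) == "c.-10"

    def test_minus_strand_numbering_runs_backwards(self, tx):
        rc = str(Seq(tx.reference).reverse_complement())
        L = len(tx.reference)
        exons = tuple(sorted((L - e, L - s) for s, e in tx.exons))
        mt = TranscriptModel(gene_id="G", strand="-", exons=exons,
                             cds_start=L - 600, cds_end=L - 100, reference=rc)
        assert project_to_cdna(L - 1 - 100, mt) == "c.1"
        assert project_to_cdna(L - 1 - 200, mt) == "c.100+1"


class TestClassification:
    def test_stop_gain_from_gln_codon(self, tx):
        # codon 2 is CAG (Gln); C>T makes TAG (stop)
        c = classify_consequence(_call(103, "C", "T"), tx)
        assert c.kind is ConsequenceKind.STOP_GAIN
        assert c.protein_label == "p.(Gln2*)"

    def test_missense_and_synonymous(self, tx):
        assert classify_consequence(_call(104, "A", "C"), tx).kind is ConsequenceKind.MISSENSE
        assert classify_consequence(_call(105, "G", "A"), tx).kind is ConsequenceKind.SYNONYMOUS

    def test_single_base_deletion_is_frameshift(self, tx):
        c = classify_consequence(_call(103, "CA", "C"), tx)
        assert c.kind is ConsequenceKind.FRAMESHIFT

    def test_three_base_deletion_is_inframe(self, tx):
        assert classify_consequence(_call(103, "CAGC", "C"), tx).kind \
            is ConsequenceKind.INFRAME_INDEL

    @pytest.mark.parametrize("pos, kind", [
        (200, ConsequenceKind.CANONICAL_SPLICE),     # donor +1
        (201, ConsequenceKind.CANONICAL_SPLICE),     # donor +2
        (205, ConsequenceKind.NONCANONICAL_SPLICE),  # +6
        (298, ConsequenceKind.CANONICAL_SPLICE),     # acceptor -2
        (250, ConsequenceKind.INTRONIC),             # deep intron
    ])
    def test_splice_windows(self, tx, pos, kind):
        ref = tx.reference[pos]
        alt = "A" if ref != "A" else "G"
        assert classify_consequence(_call(pos, ref, alt), tx).kind is kind

    def test_reference_mismatch_raises(self, tx):
        with pytest.raises(ReferenceMismatchError):
            classify_consequence(_call(103, "G", "T"), tx)  # actual base is C

    def test_structural_deletion_spanning_exons(self, tx):
        ev = StructuralEvent(sample_id="s", contig="chrSim", start=150, end=450)
        assert classify_consequence(ev, tx).kind is ConsequenceKind.STRUCTURAL_DELETION

    def test_intronic_structural_event(self, tx):
        ev = StructuralEvent(sample_id="s", contig="chrSim", start=210, end=290)
        assert classify_consequence(ev, tx).kind is ConsequenceKind.INTRONIC


@pytest.mark.parametrize("kind, expected", [
    (ConsequenceKind.STOP_GAIN, True),
    (ConsequenceKind.FRAMESHIFT, True),
    (ConsequenceKind.CANONICAL_SPLICE, True),
    (ConsequenceKind.STRUCTURAL_DELETION, True),
    (ConsequenceKind.MISSENSE, False),
    (ConsequenceKind.NONCANONICAL_SPLICE, False),
    (ConsequenceKind.INFRAME_INDEL, False),
    (ConsequenceKind.SYNONYMOUS, False),
])
def test_truncating_table(kind, expected):
    assert is_truncating(Consequence(kind, "c.?")) is expected


def test_snv_kinds_agree_with_full_cds_translation(small_reference):
    """Oracle: re-translate the whole mutant CDS and diff the proteins."""
    t = small_reference.transcript
    cds = t.cds_sequence()
    protein = str(Seq(cds).translate())
    rng = np.random.default_rng(42)
    cds_positions = [p for s, e in t.exons for p in range(s, e)]
    for pos in rng.choice(cds_positions, size=150, replace=False):
        pos = int(pos)
        i = t.cds_index(pos)
        ref = small_reference.sequence[pos]
        alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(3))) % 4]
        if alt == ref:
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        got = classify_consequence(_call(pos, ref, alt), t).kind
        mutant = cds[:i] + alt + cds[i + 1:]
        mp = str(Seq(mutant).translate())
        if "*" in mp:
            expected = ConsequenceKind.STOP_GAIN
        elif mp == protein:
            expected = ConsequenceKind.SYNONYMOUS
        else:
            expected = ConsequenceKind.MISSENSE
        assert got is expected, (pos, ref, alt)


def test_strand_symmetry_of_consequence_kinds(small_reference):
    """Reverse-complementing the genome and flipping strand preserves kinds."""
    t = small_reference.transcript
    seq = small_reference.sequence
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    exons = tuple(sorted((L - e, L - s) for s, e in t.exons))
    mt = TranscriptModel(gene_id=t.gene_id, strand="-", exons=exons,
                         cds_start=L - t.cds_end, cds_end=L - t.cds_start,
                         reference=rc)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rng = np.random.default_rng(7)
    lo, hi = t.span
    for pos in rng.integers(lo, hi, size=120):
        pos = int(pos)
        ref = seq[pos]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        k_plus = classify_consequence(_call(pos, ref, alt), t).kind
        k_minus = classify_consequence(
            _call(L - 1 - pos, comp[ref], comp[alt]), mt).kind
        assert k_plus is k_minus, (pos, ref, alt, k_plus, k_minus)
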