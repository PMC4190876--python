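"""Synthetic data emulating a pseudogene-contaminated two-gene capture panel.

The generator builds the statistical world the analysis assumes, so every
pipeline stage can be exercised without sequencing data:

* a mini-genome carrying one genuine gene (exon/intron structure, CDS) plus
  ``n_pseudogenes`` diverged copies (default six at per-base substitution
  probability 0.023, i.e. ~97.7% identity — the hallmark of the PKD1 locus);
* per-sample variant calls: true heterozygous variants at ~50% allele
  fraction with both-strand support, common benign polymorphisms carrying
  population frequencies, and pseudogene-leakage artifacts whose observable
  signature is a low allele fraction (< 20%) and, half the time,
  single-strand support;
* samples × targets coverage matrices with Poisson counts, lognormal
  library-size scales, low-rank multiplicative capture-batch structure,
  forced dropout targets, and spiked heterozygous deletions;
* per-base depth tracks for the coverage audit.

Simulation starts at the variant-call/read-count level: read mapping is
upstream third-party work, and pseudogene leakage is modeled by its
observable signature rather than by simulating an aligner.  Everything is
deterministic under ``seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .annotation import TranscriptModel, classify_consequence
from .cnv import CoverageMatrix, Target
from .coverage import DepthTrack
from .variants import VariantCall

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


class SimConfig(BaseModel):
    """Study conditions for the synthetic world.

    Defaults mirror the system being emulated: six pseudogenes at 2.3%
    per-base divergence, a 41-sample cohort (36 patients + 5 controls),
    ~300× mean per-base depth, heterozygous variants at 50% expected allele
    fraction, leakage-call fractions strictly below the 20% filter
    threshold, and the first exon forced to dropout (the high-GC
    first-exon capture failure).

    ``mean_depth`` is per-base coverage (X), used for variant-site depths
    and depth tracks; ``mean_target_count`` is the expected number of reads
    assigned to one capture target, used for the CNV count matrix.  At ~300×
    over ~1 kb targets with ~100 bp reads these differ by an order of
    magnitude (≈3000 reads/target), which is why they are separate knobs.
    """

    model_config = {"frozen": True}

    gene_length_bp: int = 12_000
    n_exons: int = 20
    exon_length_bp: int = 150
    intron_length_bp: int = 300
    flank_bp: int = 500
    n_pseudogenes: int = Field(default=6, ge=0)
    divergence: float = 0.023
    n_samples: int = Field(default=41, ge=1)
    mean_depth: float = Field(default=300.0, gt=0)
    mean_target_count: float = Field(default=3000.0, gt=0)
    het_variants_per_sample: int = Field(default=1, ge=0)
    n_benign_sites: int = Field(default=2, ge=0)
    benign_frequency: float = Field(default=0.12, ge=0.0, le=1.0)
    leakage_rate: float = Field(default=2.0, ge=0.0)
    leakage_fraction_range: tuple[float, float] = (0.01, 0.15)
    het_fraction_mean: float = Field(default=0.5, gt=0.0, lt=1.0)
    dropout_exons: tuple[int, ...] = (0,)
    dropout_depth_factor: float = Field(default=0.02, ge=0.0, lt=0.05)
    panel_fraction: float = Field(default=0.05, gt=0.0, le=1.0)
    capture_factor_loading: float = Field(default=0.05, ge=0.0)
    n_capture_factors: int = Field(default=3, ge=0)
    library_scale_sd: float = Field(default=0.2, ge=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must lie in [0, 1)")
        lo, hi = self.leakage_fraction_range
        if not (0.0 < lo < hi < 0.20):
            raise ValueError(
                "leakage_fraction_range must lie strictly inside (0, 0.20) so the "
                "allele-fraction filter is the discriminator"
            )
        if (self.n_exons * self.exon_length_bp) % 3 != 0:
            raise ValueError("total CDS length (n_exons × exon_length_bp) must be a multiple of 3")
        needed = self.n_exons * self.exon_length_bp + (self.n_exons - 1) * self.intron_length_bp
        if self.gene_length_bp < needed:
            raise ValueError(
                f"gene_length_bp={self.gene_length_bp} too small for {self.n_exons} exons "
                f"of {self.exon_length_bp} bp with {self.intron_length_bp} bp introns "
                f"(needs >= {needed})"
            )
        if any(i < 0 or i >= self.n_exons for i in self.dropout_exons):
            raise ValueError("dropout_exons indices must be valid exon indices")
        return self


@dataclass(frozen=True)
class TrueVariant:
    sample_id: str
    pos: int
    kind: str
    alt_fraction: float


@dataclass(frozen=True)
class SpuriousCall:
    sample_id: str
    pos: int
    alt_fraction: float
    single_strand: bool


@dataclass(frozen=True)
class DeletionEvent:
    sample_id: str
    first_target: int
    last_target: int  # inclusive
    copy_ratio: float  # 0.5 het, 0.0 hom

    def __post_init__(self) -> None:
        if self.copy_ratio not in (0.5, 0.0):
            raise ValueError("copy_ratio must be 0.5 (het) or 0.0 (hom)")


@dataclass
class SyntheticTruth:
    true_variants: list[TrueVariant] = field(default_factory=list)
    spurious_calls: list[SpuriousCall] = field(default_factory=list)
    deletion_events: list[DeletionEvent] = field(default_factory=list)


@dataclass
class Reference:
    """The simulated mini-genome with its annotation."""

    contig: str
    sequence: str
    gene_interval: tuple[int, int]
    pseudogene_intervals: list[tuple[int, int]]
    exons: list[tuple[int, int]]
    transcript: TranscriptModel

    @property
    def targets(self) -> list[Target]:
        """Capture targets: one per exon."""
        return [(self.contig, s, e) for s, e in self.exons]

    def pseudogene_identities(self) -> np.ndarray:
        """Fraction of bases identical between each pseudogene and the gene."""
        gs, ge = self.gene_interval
        gene = np.frombuffer(self.sequence[gs:ge].encode(), dtype="S1")
        out = []
        for ps, pe in self.pseudogene_intervals:
            pseudo = np.frombuffer(self.sequence[ps:pe].encode(), dtype="S1")
            out.append(float((gene == pseudo).mean()))
        return np.array(out)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random coding sequence without internal stop codons."""
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)


def generate_reference(config: SimConfig) -> Reference:
    """Build the mini-genome: genuine gene plus diverged pseudogene copies.

    Each pseudogene is a copy of the gene span in which every base is
    substituted independently with probability ``divergence`` (uniformly to
    one of the three other bases), so the expected gene–pseudogene identity
    is exactly ``1 − divergence``.
    """
    rng = np.random.default_rng(config.seed)
    n_cds = config.n_exons * config.exon_length_bp
    cds = _random_cds(rng, n_cds // 3)

    gene_start = config.flank_bp
    exons: list[tuple[int, int]] = []
    pos = gene_start
    gene_parts: list[str] = []
    ci = 0
    for i in range(config.n_exons):
        exons.append((pos, pos + config.exon_length_bp))
        gene_parts.append(cds[ci : ci + config.exon_length_bp])
        ci += config.exon_length_bp
        pos += config.exon_length_bp
        if i < config.n_exons - 1:
            gene_parts.append("".join(rng.choice(_BASES, size=config.intron_length_bp)))
            pos += config.intron_length_bp
    gene_end = pos
    gene_seq = "".join(gene_parts)

    spacer = config.flank_bp
    seq_parts = ["".join(rng.choice(_BASES, size=gene_start)), gene_seq]
    pseudo_intervals = []
    cursor = gene_end
    gene_arr = np.frombuffer(gene_seq.encode(), dtype="S1").copy()
    for _ in range(config.n_pseudogenes):
        seq_parts.append("".join(rng.choice(_BASES, size=spacer)))
        cursor += spacer
        mutated = gene_arr.copy()
        hits = np.flatnonzero(rng.random(len(mutated)) < config.divergence)
        for h in hits:
            current = mutated[h].decode()
            options = [b for b in "ACGT" if b != current]
            mutated[h] = rng.choice(options).encode()
        pseudo_seq = mutated.tobytes().decode()
        seq_parts.append(pseudo_seq)
        pseudo_intervals.append((cursor, cursor + len(pseudo_seq)))
        cursor += len(pseudo_seq)
    seq_parts.append("".join(rng.choice(_BASES, size=config.flank_bp)))
    sequence = "".join(seq_parts)

    transcript = TranscriptModel(
        gene_id="GENE1", strand="+", exons=tuple(exons),
        cds_start=exons[0][0], cds_end=exons[-1][1],
        reference=sequence, contig="chrSim",
    )
    return Reference(
        contig="chrSim", sequence=sequence,
        gene_interval=(gene_start, gene_end),
        pseudogene_intervals=pseudo_intervals,
        exons=exons, transcript=transcript,
    )


def _split_both_strands(rng: np.random.Generator, total: int) -> tuple[int, int]:
    """Binomial strand split constrained to leave >= 1 read on each strand."""
    if total < 2:
        return total, 0
    fwd = int(rng.binomial(total, 0.5))
    fwd = min(max(fwd, 1), total - 1)
    return fwd, total - fwd


def simulate_variant_calls(
    config: SimConfig, reference: Reference
) -> tuple[list[VariantCall], SyntheticTruth]:
    """Simulate per-sample variant calls plus ground truth.

    True heterozygous variants: random CDS SNVs, alt depth binomial around
    ``het_fraction_mean``, alt reads forced onto both strands, no population
    frequency.  Benign polymorphisms: shared sites carried by every sample
    with database frequency >= 5%.  Pseudogene-leakage artifacts: alt
    fraction drawn inside ``leakage_fraction_range`` (hence always below the
    20% filter) and single-strand alt support with probability 0.5.
    """
    rng = np.random.default_rng(config.seed + 1)
    t = reference.transcript
    cds_positions = np.array(
        [p for s, e in t.exons for p in range(s, e)
         if 0 <= t.cds_index(p) < t.cds_length]
    )
    calls: list[VariantCall] = []
    truth = SyntheticTruth()

    benign_sites = rng.choice(cds_positions, size=config.n_benign_sites, replace=False) \
        if config.n_benign_sites else np.array([], dtype=int)

    lo, hi = config.leakage_fraction_range
    for si in range(config.n_samples):
        sample = f"S{si + 1:03d}"
        taken: set[int] = set()

        for _ in range(config.het_variants_per_sample):
            pos = int(rng.choice(cds_positions))
            while pos in taken or pos in benign_sites:
                pos = int(rng.choice(cds_positions))
            taken.add(pos)
            ref = reference.sequence[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            depth = max(20, int(rng.poisson(config.mean_depth)))
            alt_n = int(rng.binomial(depth, config.het_fraction_mean))
            alt_n = min(max(alt_n, 2), depth - 2)
            fwd_alt, rev_alt = _split_both_strands(rng, alt_n)
            fwd_ref, rev_ref = _split_both_strands(rng, depth - alt_n)
            v = VariantCall(
                sample_id=sample, contig=reference.contig, pos=pos, ref=ref, alt=alt,
                fwd_ref=fwd_ref, rev_ref=rev_ref, fwd_alt=fwd_alt, rev_alt=rev_alt,
            )
            v.consequence = classify_consequence(v, t)
            calls.append(v)
            truth.true_variants.append(TrueVariant(
                sample_id=sample, pos=pos, kind=v.consequence.kind.value,
                alt_fraction=alt_n / depth,
            ))

        for pos in benign_sites:
            pos = int(pos)
            taken.add(pos)
            ref = reference.sequence[pos]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]  # site-consistent alt allele
            depth = max(20, int(rng.poisson(config.mean_depth)))
            alt_n = min(max(int(rng.binomial(depth, 0.5)), 2), depth - 2)
            fwd_alt, rev_alt = _split_both_strands(rng, alt_n)
            fwd_ref, rev_ref = _split_both_strands(rng, depth - alt_n)
            v = VariantCall(
                sample_id=sample, contig=reference.contig, pos=pos, ref=ref, alt=alt,
                fwd_ref=fwd_ref, rev_ref=rev_ref, fwd_alt=fwd_alt, rev_alt=rev_alt,
                pop_freqs={"popdb": config.benign_frequency},
            )
            v.consequence = classify_consequence(v, t)
            calls.append(v)

        gs, ge = reference.gene_interval
        for _ in range(int(rng.poisson(config.leakage_rate))):
            pos = int(rng.integers(gs, ge))
            while pos in taken:
                pos = int(rng.integers(gs, ge))
            taken.add(pos)
            ref = reference.sequence[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            depth = max(20, int(rng.poisson(config.mean_depth)))
            frac = float(rng.uniform(lo, hi))
            alt_n = max(1, int(round(depth * frac)))
            # keep the realized fraction strictly below the 20% threshold
            ceiling = int(np.ceil(0.20 * depth)) - 1
            alt_n = max(1, min(alt_n, ceiling))
            single = bool(rng.random() < 0.5)
            if single:
                fwd_alt, rev_alt = (alt_n, 0) if rng.random() < 0.5 else (0, alt_n)
            else:
                fwd_alt, rev_alt = _split_both_strands(rng, alt_n)
            fwd_ref, rev_ref = _split_both_strands(rng, depth - alt_n)
            v = VariantCall(
                sample_id=sample, contig=reference.contig, pos=pos, ref=ref, alt=alt,
                fwd_ref=fwd_ref, rev_ref=rev_ref, fwd_alt=fwd_alt, rev_alt=rev_alt,
            )
            v.consequence = classify_consequence(v, t)
            calls.append(v)
            truth.spurious_calls.append(SpuriousCall(
                sample_id=sample, pos=pos, alt_fraction=alt_n / depth,
                single_strand=single,
            ))
    return calls, truth


def simulate_coverage_matrix(
    config: SimConfig,
    targets: Optional[Sequence[Target]] = None,
    deletions: Sequence[DeletionEvent] = (),
) -> tuple[CoverageMatrix, SyntheticTruth]:
    """Simulate a samples × targets read-count matrix with known CNV truth.

    Expected counts are ``mean_depth × length weight × library scale ×
    batch factor × copy ratio`` with Poisson sampling.  The lognormal
    per-sample scale (sd ``library_scale_sd``) emulates library-size
    variation that RPKM must remove; the rank-``n_capture_factors``
    multiplicative structure emulates capture-batch effects that the SVD
    stage must strip.  Dropout targets are scaled to < 5% of the mean in
    every sample; deletion events thin their span by the copy ratio.
    """
    if targets is None:
        targets = [("chrSim", 1000 * i, 1000 * i + 500) for i in range(99)]
    targets = list(targets)
    if config.n_samples < 8:
        raise ValueError("need >= 8 samples as a z-score baseline cohort")
    if len(targets) < 20:
        raise ValueError(f"need >= 20 targets, got {len(targets)}")
    n_s, n_t = config.n_samples, len(targets)
    for ev in deletions:
        if not (0 <= ev.first_target <= ev.last_target < n_t):
            raise ValueError(f"deletion span {ev} outside target range")

    rng = np.random.default_rng(config.seed + 2)
    samples = [f"S{si + 1:03d}" for si in range(n_s)]
    lengths = np.array([e - s for _, s, e in targets], dtype=float)
    weight = lengths / lengths.mean()
    scale = rng.lognormal(mean=0.0, sigma=config.library_scale_sd, size=n_s)

    if config.n_capture_factors:
        # every target carries a comparable loading magnitude on every factor
        # (random sign, ±10% jitter): systematic capture variability dominates
        # Poisson noise panel-wide, as in real capture data, so per-target
        # z-scaling leaves a small, homogeneous stochastic residual once the
        # SVD strips the factors
        shape = (n_t, config.n_capture_factors)
        mag = config.capture_factor_loading * rng.uniform(0.9, 1.1, size=shape)
        loadings = mag * rng.choice([-1.0, 1.0], size=shape)
        scores = rng.normal(0.0, 1.0, size=(n_s, config.n_capture_factors))
        log_batch = scores @ loadings.T
        batch = np.exp(log_batch - 0.5 * (loadings ** 2).sum(axis=1)[None, :])
    else:
        batch = np.ones((n_s, n_t))

    copy = np.ones((n_s, n_t))
    sample_index = {s: i for i, s in enumerate(samples)}
    for ev in deletions:
        si = sample_index[ev.sample_id]
        copy[si, ev.first_target : ev.last_target + 1] = ev.copy_ratio

    lam = config.mean_target_count * weight[None, :] * scale[:, None] * batch * copy
    for t_idx in config.dropout_exons:
        if t_idx < n_t:
            lam[:, t_idx] *= config.dropout_depth_factor
    counts = rng.poisson(lam)

    # the panel is a small slice of the full capture design, so per-sample
    # total mapped reads are dominated by off-panel reads: a large deletion
    # inside the panel must not visibly shift the RPKM normalizer
    off_panel = rng.poisson(
        config.mean_target_count * weight.sum() * scale
        * (1.0 / config.panel_fraction - 1.0)
    )
    totals = counts.sum(axis=1) + off_panel

    matrix = CoverageMatrix(samples=samples, targets=targets, counts=counts,
                            totals=totals.astype(float))
    truth = SyntheticTruth(deletion_events=list(deletions))
    return matrix, truth


def simulate_depth_tracks(
    config: SimConfig, targets: Optional[Sequence[Target]] = None
) -> list[DepthTrack]:
    """Per-base depth tracks for the coverage audit (one per sample).

    Per-base depths are Poisson around the sample's scaled mean; dropout
    targets are thinned to ``dropout_depth_factor`` of the mean.
    """
    if targets is None:
        reference = generate_reference(config)
        targets = reference.targets
    targets = list(targets)
    rng = np.random.default_rng(config.seed + 3)
    scale = rng.lognormal(mean=0.0, sigma=config.library_scale_sd, size=config.n_samples)
    tracks = []
    for si in range(config.n_samples):
        depths = []
        for ti, (_, s, e) in enumerate(targets):
            lam = config.mean_depth * scale[si]
            if ti in config.dropout_exons:
                lam *= config.dropout_depth_factor
            depths.append(rng.poisson(lam, size=e - s))
        tracks.append(DepthTrack(sample_id=f"S{si + 1:03d}", targets=targets, depths=depths))
    return tracks
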