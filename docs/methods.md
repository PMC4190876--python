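# Methods

## The problem being modeled

Molecular diagnosis of ADPKD requires mutation screening of *PKD1* and
*PKD2*. Roughly 70% of the 5′ genomic region of *PKD1* (exons 1–33) is
duplicated in six pseudogenes sharing ~97.7% sequence identity with the
genuine gene. Capture-based sequencing of this locus therefore co-captures
pseudogene fragments; reads that misalign onto the genuine gene accumulate
as spurious variant calls. The package implements the downstream defense:
a prioritization cascade whose rules target the observable artifact
signature, a two-route pathogenicity classification, read-depth CNV
detection for large deletions that allele counts cannot see, and a coverage
audit that routes mutation-negative samples to orthogonal follow-up.

## Filter cascade

Three independent boolean rules per candidate call:

* **strand** — alternate allele present on both sequenced strands
  (`fwd_alt ≥ 1` and `rev_alt ≥ 1`);
* **fraction** — alternate reads ≥ 20% of ref+alt reads at the site.
  "Total reads at the site" is interpreted as ref+alt of this variant;
  third alleles are out of scope. Zero-depth records fail with an explicit
  `zero_depth` audit tag;
* **frequency** — fails when *any* population database reports ≥ 5%
  (max-over-databases; the sources give no aggregation rule, and max is the
  conservative choice). Membership in a curated disease-mutation database
  rescues a frequency failure, because population databases also contain
  known pathogenic variants. An in-house artifact database is modeled as
  just another frequency source.

The retained set is the intersection of the three per-rule pass sets, so
rule order cannot matter; this is asserted as a property test against a
brute-force oracle.

Large deletions bypass the cascade entirely: their evidence is read depth,
not allele counts.

## Classification

Truncating consequences — stop-gain, frameshift, canonical ±1/±2 splice,
structural deletion spanning ≥ 1 exon — are definitely pathogenic regardless
of any score. Other consequences (missense, noncanonical splice at intronic
offsets 3–10, in-frame indels) are UCVs: integer evidence points
(conservation, Grantham-distance bins, splice-predictor deltas, population
absence, cosegregation) sum to the Variant Score, thresholded at
≥ 11 / 5–10 / 0–4 / ≤ −1. The VS is integer by construction — the printed
ranges only partition the integers — and non-integer points or thresholds
are rejected at configuration time. The exact point values of the published
PKD1/PKD2 scoring system are not reproduced; the evidence table is shipped
as a documented default configuration, and the packaged cohort tables carry
curated classes used for concordance checks.

Reportable (diagnostic) classes: definitely, highly-likely and likely
pathogenic. A sample with only indeterminate/neutral UCVs counts as
undiagnosed. Cohort diagnostic rate = 100 × diagnosed/n, rendered to one
decimal, half-up.

### Curated-label parsing

The packaged tables carry HGVS-style labels rather than genomic positions
(no attempt is made to re-map them onto the human reference). Consequence
kinds are inferred from the labels with intronic cDNA offsets taking
precedence over the protein suffix: a change printed as `c.N-10C>A` with a
downstream-frameshift protein label is a splice-region change at the DNA
level, and it is the DNA-level kind that routes classification (such
variants are UCVs, not automatic truncating calls). Canonical splice =
offsets 1–2; noncanonical = 3–10 (the window is configurable; the published
example at −10 sits inside it); deeper offsets are intronic but can still be
reported through their curated class. One table entry with a typographic
cDNA label is stored verbatim and classified by its protein column.

## CNV calling (SVD-ZRPKM)

Stages over a samples × targets count matrix:

1. **RPKM** `counts × 10⁹ / (length × total mapped reads)` — removes
   library-size and target-length effects. Samples with zero mapped reads
   are dropped with a warning.
2. **ZRPKM** `(rpkm − median_t)/sd_t` per target across ≥ 8 samples.
   Targets with cohort SD below 10⁻⁸ (all-zero or constant, e.g. dropout
   exons) carry no information and are masked rather than divided by ~0.
3. **SVD-ZRPKM** — the k largest singular values are zeroed and the matrix
   reconstructed, stripping systematic structure (capture-batch, GC) shared
   across samples. Default k = 3, configurable; at panel scale a small k
   suffices, and k must stay below the number of true latent factors plus
   any signal components you want to keep.
4. **Calling** — per sample, maximal runs of ≥ `min_targets` (default 2)
   consecutive unmasked targets at z ≤ −threshold (default 1.5) are
   deletions; mirrored at +threshold for duplications. Masked targets break
   runs. Calls report target spans, not breakpoints.

Heterozygous deletions are expected at copy ratio 0.5, i.e. roughly half
the cohort-median depth over the span, which at realistic per-target counts
sits many residual standard deviations below the −1.5 cut.

## Synthetic-data generator

The generator emulates the statistical world at the *variant-call /
read-count* level; read mapping is upstream third-party work, so pseudogene
leakage is represented by its observable signature rather than by
simulating an aligner.

* **Mini-genome.** One gene (default 20 exons × 150 bp CDS, 300 bp introns)
  plus `n_pseudogenes = 6` copies, each base substituted independently with
  probability `divergence = 0.023`, giving expected identity
  1 − divergence ≈ 97.7%. Coordinates are 0-based half-open internally;
  1-based only in HGVS-style text and VCF.
* **Variant calls.** True heterozygous variants: depth ~ Poisson(mean
  depth 300X), alt count binomial at `het_fraction_mean = 0.5`, alt reads
  forced onto both strands, no population frequency. Benign polymorphisms:
  shared sites at ≥ 5% database frequency. Leakage artifacts: per-sample
  count ~ Poisson(`leakage_rate`), alt fraction uniform in
  `leakage_fraction_range = (0.01, 0.15)` — validated to stay strictly
  inside (0, 0.20) so the fraction filter is the discriminator — and
  single-strand support with probability 0.5.
* **Coverage matrices.** `counts ~ Poisson(mean_target_count × length
  weight × library scale × batch factor × copy ratio)`. Two deliberately
  distinct intensity knobs: `mean_depth` (per-base coverage, 300X-like,
  used for variant depths and depth tracks) and `mean_target_count`
  (expected reads per capture target, default 3000 — at ~1 kb targets and
  ~100 bp reads, 300X corresponds to thousands of reads per target, and
  conflating the two units would exaggerate per-target Poisson noise by
  ~√10). Library scale is lognormal (σ = 0.2), removed exactly by RPKM.
  The batch factor is low-rank multiplicative structure: 3 latent factors
  with per-target loading magnitude ≈ 0.05 (random sign, ±10% jitter) on
  *every* target, emulating capture-batch variability that dominates
  Poisson noise panel-wide — this is the structure the SVD stage exists to
  remove, and the default factor count matches the default k. Per-sample
  RPKM totals include off-panel mapped reads (`panel_fraction = 0.05`,
  the two-gene panel's share of a larger capture design), so a large
  deletion does not shift its own normalizer. Dropout targets are thinned
  to 2% of the mean (< 5% in every sample), emulating high-GC first-exon
  capture failure. Deletions thin their span by the copy ratio
  (0.5 het / 0.0 hom).

### What the generator does *not* model

No read-level simulation, no base-quality or mapping-quality structure, no
GC-content continuum (only fixed dropout targets), no duplication CNVs, no
related individuals, and leakage is summarized by fraction/strand signature
rather than alignment mechanics. Passing tests therefore demonstrate that
the *rules and normalizations* behave as designed under the stated
statistical assumptions — not that any particular wet-lab assay reaches the
same sensitivity on real libraries.

A known mechanism worth documenting: under a multiplicative batch × copy
model, the SVD subtracts a carrier's full batch contribution while deleted
targets only carry half of it, leaving extra within-span variance
(~0.45 z-units). The default calibration keeps the deletion amplitude
(≈ 5 z-units at copy ratio 0.5) far enough below the −1.5 cut that spans
are recovered cleanly; at much larger batch loadings relative to the
deletion amplitude, spans fragment — real CoNIFER-style analyses show the
same behavior.

## Numerical and design choices

* SD floor 10⁻⁸ masks invariant targets; masked targets are excluded from
  calling and break runs.
* Strand counts in the cohort tables are not published; conversion splits
  totals as evenly as possible (odd → forward gets the extra read). This is
  a fixture convention, documented, not data; it makes the both-strand rule
  pass exactly as the published retained set implies.
* The two published large deletions are represented as structural events
  with their printed genomic coordinates and enter classification via the
  structural route.
* Rates use decimal half-up rounding to one decimal (97.222… → 97.2).
* Problem sizes in the test-suite simulations: 41 samples × 99 targets for
  CNV recovery (the published cohort's 36 + 5 controls and 99 capture
  regions), 20 replicates/seeds for the stochastic suites, 10-exon
  mini-genes for fast unit-level checks.

## Known limitations

* HGVS output is a simplified dialect (no 3′-shifting of indels; single
  transcript per gene; UTR-exonic SNVs are labeled but typed as
  non-coding).
* The VS evidence table is a configurable stand-in calibrated only to the
  threshold structure, not to the published per-component point values.
* The deep-intronic boundary (beyond offset 10) between "noncanonical
  splice UCV" and "discard" is not specified by the source scheme; such
  variants are typed intronic and can only be reported through curated
  classes.
* CNV duplications are called symmetrically but the generator produces no
  gains, so duplication calling is exercised only at unit level.
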