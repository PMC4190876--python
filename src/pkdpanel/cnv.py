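"""Read-depth CNV detection on capture targets (SVD-ZRPKM, CoNIFER-style).

Large heterozygous deletions are invisible to allele-count filters but leave a
clear footprint in capture read depth: the carrier's counts over the deleted
targets drop to ~half the cohort's.  The caller normalizes a samples × targets
count matrix in three stages:

1. **RPKM** — reads per kilobase of target per million mapped reads; removes
   library-size and target-length effects.
2. **ZRPKM** — per-target robust z-score (median/SD across samples); puts all
   targets on a common scale so one threshold applies panel-wide.
3. **SVD-ZRPKM** — the top *k* singular components are removed, stripping
   systematic structure (capture-batch and GC effects shared across samples)
   that would otherwise dominate the variance and drown single-sample signals.

Deletions are then called as maximal runs of >= ``min_targets`` consecutive
targets at ZRPKM <= -threshold (duplications mirrored at >= +threshold).
Calls report target spans, not breakpoint base pairs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

Target = tuple[str, int, int]


@dataclass
class CoverageMatrix:
    """Samples × capture-targets read counts with target geometry."""

    samples: list[str]
    targets: list[Target]
    counts: np.ndarray  # (n_samples, n_targets) nonnegative ints
    totals: Optional[np.ndarray] = None  # per-sample total mapped reads

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), len(self.targets)):
            raise ValueError("counts shape does not match samples × targets")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        for c, s, e in self.targets:
            if e <= s:
                raise ValueError(f"target ({c}, {s}, {e}) has nonpositive length")
        row_sums = self.counts.sum(axis=1)
        if self.totals is None:
            self.totals = row_sums.astype(float)
        else:
            self.totals = np.asarray(self.totals, dtype=float)
            if self.totals.shape != (len(self.samples),):
                raise ValueError("totals length does not match samples")
            if (self.totals < row_sums).any():
                raise ValueError("totals must be >= per-sample row sums")

    @property
    def target_lengths(self) -> np.ndarray:
        return np.array([e - s for _, s, e in self.targets], dtype=float)


@dataclass
class ZrpkmMatrix:
    """Normalized depth matrix at one of the three stages."""

    samples: list[str]
    targets: list[Target]
    values: np.ndarray
    stage: str  # rpkm | zrpkm | svd_zrpkm
    masked: np.ndarray = field(default=None)  # per-target bool, uninformative targets
    removed_components: int = 0

    def __post_init__(self) -> None:
        if self.stage not in {"rpkm", "zrpkm", "svd_zrpkm"}:
            raise ValueError(f"unknown stage {self.stage!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.masked is None:
            self.masked = np.zeros(len(self.targets), dtype=bool)
        if self.removed_components and self.stage != "svd_zrpkm":
            raise ValueError("removed_components only applies to the svd_zrpkm stage")


@dataclass(frozen=True)
class CnvCall:
    """A contiguous-target deletion/duplication event in one sample."""

    sample_id: str
    first_target: int
    last_target: int  # inclusive
    direction: str  # deletion | duplication
    mean_signal: float

    def __post_init__(self) -> None:
        if self.last_target < self.first_target:
            raise ValueError("last_target must be >= first_target")
        if self.direction not in {"deletion", "duplication"}:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def n_targets(self) -> int:
        return self.last_target - self.first_target + 1


def compute_rpkm(m: CoverageMatrix) -> ZrpkmMatrix:
    """counts × 1e9 / (target length × sample total mapped reads).

    Samples with zero total reads are excluded with a warning.
    """
    keep = m.totals > 0
    if not keep.all():
        dropped = [s for s, k in zip(m.samples, keep) if not k]
        warnings.warn(f"excluding samples with zero mapped reads: {dropped}")
    counts = m.counts[keep]
    totals = m.totals[keep]
    values = counts * 1e9 / (m.target_lengths[None, :] * totals[:, None])
    return ZrpkmMatrix(
        samples=[s for s, k in zip(m.samples, keep) if k],
        targets=list(m.targets), values=values, stage="rpkm",
    )


def compute_zrpkm(r: ZrpkmMatrix, sd_floor: float = 1e-8) -> ZrpkmMatrix:
    """Per-target z-score against the cohort: (rpkm − median) / SD.

    Requires >= 8 samples for a usable baseline.  Targets whose cohort SD is
    below ``sd_floor`` carry no information (e.g. all-zero dropout targets or
    identical rows) and are masked rather than divided by ~0.
    """
    if r.stage != "rpkm":
        raise ValueError("compute_zrpkm expects an rpkm-stage matrix")
    if len(r.samples) < 8:
        raise ValueError(f"need >= 8 samples for the z-score baseline, got {len(r.samples)}")
    med = np.median(r.values, axis=0)
    sd = r.values.std(axis=0, ddof=1)
    masked = sd < sd_floor
    z = np.zeros_like(r.values)
    ok = ~masked
    z[:, ok] = (r.values[:, ok] - med[ok]) / sd[ok]
    return ZrpkmMatrix(samples=list(r.samples), targets=list(r.targets),
                       values=z, stage="zrpkm", masked=masked)


def svd_denoise(z: ZrpkmMatrix, k: int = 3) -> ZrpkmMatrix:
    """Zero out the ``k`` largest singular values and reconstruct.

    ``k=0`` is the identity; ``k`` must be smaller than min(samples, targets).
    """
    if z.stage != "zrpkm":
        raise ValueError("svd_denoise expects a zrpkm-stage matrix")
    if k < 0:
        raise ValueError("k must be nonnegative")
    n, t = z.values.shape
    if k >= min(n, t):
        raise ValueError(f"k={k} must be < min(n_samples={n}, n_targets={t})")
    if k == 0:
        values = z.values.copy()
    else:
        u, s, vt = np.linalg.svd(z.values, full_matrices=False)
        s = s.copy()
        s[:k] = 0.0
        values = (u * s) @ vt
    return ZrpkmMatrix(samples=list(z.samples), targets=list(z.targets),
                       values=values, stage="svd_zrpkm", masked=z.masked.copy(),
                       removed_components=k)


def call_cnvs(
    z: ZrpkmMatrix,
    threshold: float = 1.5,
    min_targets: int = 2,
) -> list[CnvCall]:
    """Threshold the denoised matrix into contiguous-target CNV calls.

    Per sample, maximal runs of >= ``min_targets`` consecutive unmasked
    targets with value <= -threshold become deletions (>= +threshold,
    duplications).  Masked targets break runs.
    """
    if z.stage != "svd_zrpkm":
        raise ValueError("call_cnvs expects an svd_zrpkm-stage matrix")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    calls: list[CnvCall] = []
    state = np.zeros(z.values.shape, dtype=int)
    state[z.values <= -threshold] = -1
    state[z.values >= threshold] = 1
    state[:, z.masked] = 0
    for si, sample in enumerate(z.samples):
        row = state[si]
        t = 0
        n = len(row)
        while t < n:
            if row[t] == 0:
                t += 1
                continue
            sgn = row[t]
            start = t
            while t < n and row[t] == sgn:
                t += 1
            if t - start >= min_targets:
                calls.append(CnvCall(
                    sample_id=sample, first_target=start, last_target=t - 1,
                    direction="deletion" if sgn < 0 else "duplication",
                    mean_signal=float(z.values[si, start:t].mean()),
                ))
    return calls


def detect_deletions(
    m: CoverageMatrix,
    k: int = 3,
    threshold: float = 1.5,
    min_targets: int = 2,
) -> tuple[list[CnvCall], ZrpkmMatrix]:
    """Full chain: RPKM → ZRPKM → SVD denoising → thresholded calls."""
    z = svd_denoise(compute_zrpkm(compute_rpkm(m)), k=k)
    return call_cnvs(z, threshold=threshold, min_targets=min_targets), z


def plot_sample_signal(z: ZrpkmMatrix, sample_id: str, path) -> None:
    """Write a per-sample signal plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    si = z.samples.index(sample_id)
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(z.values[si], drawstyle="steps-mid")
    ax.axhline(-1.5, color="red", ls="--", lw=0.8)
    ax.axhline(1.5, color="red", ls="--", lw=0.8)
    ax.set_xlabel("target index")
    ax.set_ylabel(f"{z.stage} signal")
    ax.set_title(sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
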