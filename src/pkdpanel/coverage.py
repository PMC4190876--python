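"""Capture-panel coverage auditing.

Capture panels lose specific targets — typically high-GC first exons — and a
sample without a reportable mutation may simply have its mutation sitting in
an unsequenced region.  This module computes per-gene/per-exon coverage
summaries from per-base depth tracks, reports maximal low-coverage
sub-intervals as BED-style intervals, and raises a "screen by orthogonal
sequencing" flag for samples in which the pipeline found nothing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

Interval = tuple[str, int, int]


class IntervalError(ValueError):
    pass


@dataclass
class DepthTrack:
    """Per-base depth over the capture targets for one sample.

    ``depths[i]`` holds one nonnegative integer per base of ``targets[i]``;
    targets must not overlap, so every targeted base is covered exactly once.
    """

    sample_id: str
    targets: list[Interval]
    depths: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.targets) != len(self.depths):
            raise ValueError("one depth array per target required")
        self.depths = [np.asarray(d, dtype=int) for d in self.depths]
        for (c, s, e), d in zip(self.targets, self.depths):
            if len(d) != e - s:
                raise ValueError(f"depth array length {len(d)} != target length {e - s}")
            if (d < 0).any():
                raise ValueError("depth must be nonnegative")
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in self.targets:
            by_contig.setdefault(c, []).append((s, e))
        for ivs in by_contig.values():
            ivs.sort()
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError("targets overlap; bases must be covered once")

    def slice(self, contig: str, start: int, end: int) -> np.ndarray:
        """Depth over a sub-interval that lies within a single target."""
        for (c, s, e), d in zip(self.targets, self.depths):
            if c == contig and s <= start and end <= e:
                return d[start - s : end - s]
        raise IntervalError(f"interval {contig}:{start}-{end} not within any target")


@dataclass
class CoverageSummary:
    """Per-gene threshold statistics and per-exon mean depths."""

    per_gene: pd.DataFrame   # index: gene; mean_coverage, pct_0x, pct_ge_* columns
    per_exon: pd.DataFrame   # columns: gene, exon, mean_depth
    thresholds: tuple[int, ...] = (1, 20, 50, 100)


def summarize_coverage(
    track: DepthTrack,
    annotation: pd.DataFrame,
    thresholds: Sequence[int] = (1, 20, 50, 100),
) -> CoverageSummary:
    """Coverage statistics over annotated gene/exon intervals.

    ``annotation`` needs columns ``contig, start, end, gene, exon``; every
    interval must lie within the sample's targets.  Percentages are over
    annotated (targeted) bases; the mean is the arithmetic per-base mean.
    """
    required = {"contig", "start", "end", "gene", "exon"}
    if not required.issubset(annotation.columns):
        raise IntervalError(f"annotation needs columns {sorted(required)}")
    per_gene_depth: dict[str, list[np.ndarray]] = {}
    exon_rows = []
    for row in annotation.itertuples(index=False):
        d = track.slice(row.contig, int(row.start), int(row.end))
        per_gene_depth.setdefault(row.gene, []).append(d)
        exon_rows.append({"gene": row.gene, "exon": row.exon,
                          "mean_depth": float(d.mean())})
    gene_rows = {}
    for gene, chunks in per_gene_depth.items():
        d = np.concatenate(chunks)
        stats = {"mean_coverage": float(d.mean()),
                 "pct_0x": float(100.0 * (d == 0).mean())}
        for t in thresholds:
            stats[f"pct_ge_{t}x"] = float(100.0 * (d >= t).mean())
        gene_rows[gene] = stats
    return CoverageSummary(
        per_gene=pd.DataFrame.from_dict(gene_rows, orient="index"),
        per_exon=pd.DataFrame(exon_rows),
        thresholds=tuple(thresholds),
    )


def low_coverage_regions(track: DepthTrack, min_depth: int = 20) -> list[Interval]:
    """Maximal sub-intervals of the targets where depth < ``min_depth``.

    Adjacent low bases are merged, including across targets that abut on the
    same contig.  The union of the reported intervals is exactly the set of
    targeted bases below the threshold.
    """
    raw: list[Interval] = []
    for (c, s, e), d in zip(track.targets, track.depths):
        low = d < min_depth
        if not low.any():
            continue
        # run-length extraction over the boolean mask
        edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            raw.append((c, s + int(a), s + int(b)))
    raw.sort()
    merged: list[Interval] = []
    for iv in raw:
        if merged and merged[-1][0] == iv[0] and merged[-1][2] == iv[1]:
            merged[-1] = (iv[0], merged[-1][1], iv[2])
        else:
            merged.append(iv)
    return [tuple(iv) for iv in merged]


@dataclass(frozen=True)
class AuditFlag:
    """Follow-up recommendation attached to a sample report."""

    sample_id: str
    sanger_recommended: bool
    regions: tuple[Interval, ...] = ()
    message: str = ""


def flag_missed_mutation_risk(
    sample_id: str,
    reported: Sequence[Interval],
    variants_found: bool,
) -> AuditFlag:
    """Raise the orthogonal-screening flag when a sample has no finding.

    A mutation-negative sample may carry its causal variant in a low-coverage
    region, so the low-coverage intervals are attached with a
    Sanger-sequencing recommendation (even when the region list is empty).
    """
    if variants_found:
        return AuditFlag(sample_id=sample_id, sanger_recommended=False,
                         regions=tuple(reported),
                         message="reportable mutation found; no follow-up required")
    return AuditFlag(
        sample_id=sample_id, sanger_recommended=True, regions=tuple(reported),
        message=(
            "no reportable mutation; screen the listed low-coverage regions by "
            "Sanger sequencing" if reported else
            "no reportable mutation; no low-coverage regions identified"
        ),
    )
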