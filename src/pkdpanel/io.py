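"""Readers/writers for the standard interchange formats (FASTA/BED/TSV/VCF)."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import Consequence, ConsequenceKind
from .cnv import CnvCall, CoverageMatrix, Target
from .coverage import DepthTrack
from .variants import VariantCall

PathLike = Union[str, Path]

# ---------------------------------------------------------------------------
# FASTA / BED


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals: Iterable[Sequence], path: PathLike) -> None:
    """Write (contig, start, end[, name]) tuples as BED."""
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: PathLike) -> list[Target]:
    out: list[Target] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append((f[0], int(f[1]), int(f[2])))
    return out


# ---------------------------------------------------------------------------
# variant-call tables

_CALL_COLUMNS = [
    "sample_id", "contig", "pos", "ref", "alt",
    "fwd_ref", "rev_ref", "fwd_alt", "rev_alt",
    "pop_freqs", "in_pathogenic_db",
    "consequence", "cdna", "protein", "curated_class", "in_duplicated_region",
]


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    rows = []
    for v in calls:
        c = v.consequence
        rows.append({
            "sample_id": v.sample_id, "contig": v.contig, "pos": v.pos,
            "ref": v.ref, "alt": v.alt,
            "fwd_ref": v.fwd_ref, "rev_ref": v.rev_ref,
            "fwd_alt": v.fwd_alt, "rev_alt": v.rev_alt,
            "pop_freqs": json.dumps(v.pop_freqs, sort_keys=True),
            "in_pathogenic_db": v.in_pathogenic_db,
            "consequence": c.kind.value if c else "",
            "cdna": c.cdna_label if c else "",
            "protein": (c.protein_label or "") if c else "",
            "curated_class": v.curated_class or "",
            "in_duplicated_region": v.in_duplicated_region,
        })
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)


def write_calls_tsv(calls: Sequence[VariantCall], path: PathLike) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: PathLike) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    calls = []
    for row in df.itertuples(index=False):
        cons = None
        if row.consequence:
            cons = Consequence(
                ConsequenceKind(row.consequence), row.cdna, row.protein or None
            )
        calls.append(VariantCall(
            sample_id=row.sample_id, contig=row.contig, pos=int(row.pos),
            ref=row.ref, alt=row.alt,
            fwd_ref=int(row.fwd_ref), rev_ref=int(row.rev_ref),
            fwd_alt=int(row.fwd_alt), rev_alt=int(row.rev_alt),
            pop_freqs=json.loads(row.pop_freqs) if row.pop_freqs else {},
            in_pathogenic_db=str(row.in_pathogenic_db) == "True",
            consequence=cons,
            curated_class=row.curated_class or None,
            in_duplicated_region=str(row.in_duplicated_region) == "True",
        ))
    return calls


# ---------------------------------------------------------------------------
# VCF (stranded allele depths in ADF/ADR sample fields)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Forward-strand allelic depths (ref,alt)">
##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Reverse-strand allelic depths (ref,alt)">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Predicted consequence kind">
"""


def write_vcf(calls: Sequence[VariantCall], path: PathLike, contig_lengths: Optional[dict[str, int]] = None) -> None:
    """Render calls as a multi-sample VCF with stranded AD fields."""
    samples = sorted({v.sample_id for v in calls})
    lines = [_VCF_HEADER.rstrip("\n")]
    if contig_lengths:
        for c, ln in contig_lengths.items():
            lines.append(f"##contig=<ID={c},length={ln}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for v in sorted(calls, key=lambda x: (x.contig, x.pos, x.sample_id)):
        info = f"CSQ={v.consequence.kind.value}" if v.consequence else "."
        ref = v.ref if all(ch in "ACGTN" for ch in v.ref) else "N"
        alt = v.alt if v.alt and v.alt[0] != "<" else "<DEL>"
        cells = []
        for s in samples:
            if s == v.sample_id:
                cells.append(f"0/1:{v.fwd_ref},{v.fwd_alt}:{v.rev_ref},{v.rev_alt}")
            else:
                cells.append("./.:.:.")
        lines.append("\t".join([
            v.contig, str(v.pos + 1), ".", ref, alt, ".", ".", info, "GT:ADF:ADR",
        ] + cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_vcf(path: PathLike) -> list[VariantCall]:
    """Read a VCF with ADF/ADR stranded allele depths back into calls."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls = []
    for rec in vcf:
        adf = rec.format("ADF")
        adr = rec.format("ADR")
        if adf is None or adr is None:
            continue
        for i, s in enumerate(samples):
            f, r = adf[i], adr[i]
            if f[0] < 0:  # missing
                continue
            kind = rec.INFO.get("CSQ")
            calls.append(VariantCall(
                sample_id=s, contig=rec.CHROM, pos=rec.POS - 1,
                ref=rec.REF, alt=rec.ALT[0] if rec.ALT else "N",
                fwd_ref=int(f[0]), rev_ref=int(r[0]),
                fwd_alt=int(f[1]), rev_alt=int(r[1]),
                consequence=Consequence(ConsequenceKind(kind), "") if kind else None,
            ))
    return calls


# ---------------------------------------------------------------------------
# coverage matrices and depth tracks


def write_counts_tsv(m: CoverageMatrix, path: PathLike) -> None:
    df = pd.DataFrame(m.counts, index=pd.Index(m.samples, name="sample"),
                      columns=[f"{c}:{s}-{e}" for c, s, e in m.targets])
    df.insert(0, "total_reads", m.totals.astype(int))
    df.to_csv(path, sep="\t")


def read_counts_tsv(path: PathLike) -> CoverageMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    totals = df.pop("total_reads").to_numpy(dtype=float)
    targets = []
    for col in df.columns:
        contig, span = col.rsplit(":", 1)
        s, e = span.split("-")
        targets.append((contig, int(s), int(e)))
    return CoverageMatrix(samples=list(df.index), targets=targets,
                          counts=df.to_numpy(dtype=int), totals=totals)


def write_cnv_calls_tsv(calls: Sequence[CnvCall], targets: Sequence[Target], path: PathLike) -> None:
    rows = []
    for c in calls:
        contig, start, _ = targets[c.first_target]
        _, _, end = targets[c.last_target]
        rows.append({
            "sample_id": c.sample_id, "contig": contig, "start": start, "end": end,
            "first_target": c.first_target, "last_target": c.last_target,
            "direction": c.direction, "mean_signal": round(c.mean_signal, 4),
        })
    pd.DataFrame(rows, columns=["sample_id", "contig", "start", "end",
                                "first_target", "last_target", "direction",
                                "mean_signal"]).to_csv(path, sep="\t", index=False)


def write_depth_tsv(track: DepthTrack, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("contig\tpos\tdepth\n")
        for (c, s, _), d in zip(track.targets, track.depths):
            for i, depth in enumerate(d):
                fh.write(f"{c}\t{s + i}\t{int(depth)}\n")


def read_depth_tsv(path: PathLike, sample_id: str) -> DepthTrack:
    df = pd.read_csv(path, sep="\t")
    targets: list[Target] = []
    depths: list[np.ndarray] = []
    for contig, sub in df.groupby("contig", sort=True):
        pos = sub["pos"].to_numpy()
        dep = sub["depth"].to_numpy()
        order = np.argsort(pos)
        pos, dep = pos[order], dep[order]
        breaks = np.flatnonzero(np.diff(pos) != 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [len(pos)]))
        for a, b in zip(starts, ends):
            targets.append((contig, int(pos[a]), int(pos[b - 1]) + 1))
            depths.append(dep[a:b])
    return DepthTrack(sample_id=sample_id, targets=targets, depths=depths)
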