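"""lncRNA 5'-boundary audit by stitching and junction-read evidence.

Many mono-exonic lncRNA models may really be unannotated 3'-UTR extensions of
upstream protein-coding genes.  The audit proceeds in four steps:

1. select lncRNAs with no same-strand CAGE peak within a radius (default
   500 nt) of their annotated TSS — candidates lacking independent 5'
   support;
2. provisionally "stitch" each to the 3' end of every protein-coding gene on
   the same strand whose 3' end lies upstream within a maximum gap (default
   5827 nt, the 80th percentile of protein-coding intron lengths, recomputable
   from any gene set via :func:`intron_length_percentile`);
3. score each stitch with spliced junction reads that overlap a gene exon on
   one flank and an lncRNA exon on the other by at least ``min_overlap``
   (default 2 nt) each, discarding junctions whose flank cannot be assigned
   unambiguously because a gene exon and an lncRNA exon overlap there;
4. bin the supported stitches by total junction reads (1-10, 11-100, >100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .peakdb import PeakIndex
from .query import FeatureTSS, nearest_across_samples

__all__ = [
    "TranscriptModel",
    "Junction",
    "StitchCandidate",
    "read_bed12_transcripts",
    "read_gtf_transcripts",
    "read_junctions_bed12",
    "intron_length_percentile",
    "select_unsupported",
    "stitch_candidates",
    "junction_support",
    "bin_support",
    "overlap_fraction_stats",
]

CAGE_RADIUS_DEFAULT = 500
MAX_GAP_DEFAULT = 5_827
MIN_OVERLAP_DEFAULT = 2

LNCRNA = "lncRNA"
PROTEIN_CODING = "protein_coding"


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an exon chain (0-based half-open exons, sorted)."""

    transcript_id: str
    gene_id: str
    biotype: str  # 'lncRNA' or 'protein_coding'
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < 0:
                raise ValueError(f"invalid exon [{s}, {e})")
            if s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def mono_exonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def tss(self) -> int:
        """1-based 5' position: smallest coordinate on '+', largest on '-'."""
        return self.exons[0][0] + 1 if self.strand == "+" else self.exons[-1][1]

    @property
    def end3(self) -> int:
        """1-based 3' position."""
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0] + 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class Junction:
    """A spliced read junction: two aligned flanks bridging an intron.

    ``donor_end`` is the 0-based last base of the upstream (smaller
    coordinate) flank, ``acceptor_start`` the 0-based first base of the
    downstream flank.  ``read_count`` is the number of supporting reads.
    """

    chrom: str
    donor_end: int
    acceptor_start: int
    strand: str
    flank5_len: int
    flank3_len: int
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValueError("donor_end must precede acceptor_start")
        if self.flank5_len < 1 or self.flank3_len < 1:
            raise ValueError("flank lengths must be >= 1")

    @property
    def left_flank(self) -> tuple[int, int]:
        """Genomic-left flank interval, 0-based half-open."""
        return (self.donor_end - self.flank5_len + 1, self.donor_end + 1)

    @property
    def right_flank(self) -> tuple[int, int]:
        return (self.acceptor_start, self.acceptor_start + self.flank3_len)


@dataclass
class StitchCandidate:
    """An lncRNA provisionally joined to an upstream protein-coding gene."""

    lncrna: TranscriptModel
    gene: TranscriptModel
    gap: int
    supporting_junctions: list[Junction] = field(default_factory=list)
    total_junction_reads: int = 0


# ---------------------------------------------------------------------------
# parsers


def read_bed12_transcripts(path: str | Path, biotype: str) -> list[TranscriptModel]:
    """Read transcript models from BED12; the name column is used as both
    gene_id and transcript_id (BED carries no gene grouping)."""
    out: list[TranscriptModel] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: BED12 requires 12 columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            offsets = [int(x) for x in f[11].rstrip(",").split(",") if x]
            if len(sizes) != int(f[9]) or len(offsets) != int(f[9]):
                raise ValueError(f"{path}: line {lineno}: block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            out.append(TranscriptModel(name, name, biotype, chrom, strand, exons))
    return out


def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_transcripts(path: str | Path, default_biotype: str | None = None) -> list[TranscriptModel]:
    """Read a minimal GTF subset: exon features with gene_id / transcript_id
    and a biotype attribute (``gene_biotype``, ``transcript_biotype`` or
    ``biotype``; ``default_biotype`` covers files without one)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: line {lineno}: GTF requires 9 columns")
            if f[2] != "exon":
                continue
            attrs = _gtf_attributes(f[8])
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid)
            if tid is None:
                raise ValueError(f"{path}: line {lineno}: exon without transcript_id")
            biotype = (
                attrs.get("transcript_biotype")
                or attrs.get("gene_biotype")
                or attrs.get("biotype")
                or default_biotype
            )
            if biotype is None:
                raise ValueError(f"{path}: line {lineno}: no biotype attribute")
            exons.setdefault(tid, []).append((int(f[3]) - 1, int(f[4])))
            meta[tid] = (gid, biotype, f[0], f[6])
    out = []
    for tid, ivs in exons.items():
        gid, biotype, chrom, strand = meta[tid]
        out.append(TranscriptModel(tid, gid, biotype, chrom, strand, tuple(sorted(ivs))))
    return out


def read_junctions_bed12(path: str | Path) -> list[Junction]:
    """Read junctions in the BED12 dialect emitted by spliced aligners
    (TopHat junctions.bed): two blocks whose sizes are the flank lengths and
    whose score is the supporting read count."""
    out: list[Junction] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: BED12 requires 12 columns")
            chrom, start, strand = f[0], int(f[1]), f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            offsets = [int(x) for x in f[11].rstrip(",").split(",") if x]
            if len(sizes) != 2 or len(offsets) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: junction records need exactly 2 blocks"
                )
            out.append(
                Junction(
                    chrom=chrom,
                    donor_end=start + sizes[0] - 1,
                    acceptor_start=start + offsets[1],
                    strand=strand,
                    flank5_len=sizes[0],
                    flank3_len=sizes[1],
                    read_count=int(float(f[4])),
                )
            )
    return out


# ---------------------------------------------------------------------------
# the audit


def intron_length_percentile(genes: Sequence[TranscriptModel], q: float = 80) -> int:
    """q-th percentile of intron lengths over all transcripts (nearest-rank).

    Used to derive the stitching gap bound from a protein-coding gene set.
    """
    lengths = sorted(e - s for g in genes for s, e in g.introns)
    if not lengths:
        raise ValueError("no introns: need at least one multi-exonic transcript")
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    k = max(1, math.ceil(q / 100 * len(lengths)))
    return lengths[k - 1]


def select_unsupported(
    lncrnas: Sequence[TranscriptModel],
    cage_index: PeakIndex,
    radius: int = CAGE_RADIUS_DEFAULT,
) -> list[TranscriptModel]:
    """lncRNAs with no same-strand CAGE peak within ``radius`` nt of their
    TSS in any sample (inclusive bound: |distance| <= radius counts as
    supported)."""
    out = []
    for lnc in lncrnas:
        tss = FeatureTSS(lnc.chrom, lnc.tss, lnc.strand, label=lnc.transcript_id)
        hit = nearest_across_samples(tss, cage_index)
        if hit.is_missing or abs(hit.distance) > radius:
            out.append(lnc)
    return out


def stitch_candidates(
    unsupported: Sequence[TranscriptModel],
    genes: Sequence[TranscriptModel],
    max_gap: int = MAX_GAP_DEFAULT,
) -> list[StitchCandidate]:
    """All (lncRNA, gene) pairs on one chromosome and strand where the gene's
    3' end lies upstream of the lncRNA TSS with gap in [0, max_gap].

    The gap is measured in transcription direction from the gene's 3' end to
    the lncRNA TSS; a gene overlapping or downstream of the TSS never
    qualifies.  Every qualifying gene yields its own candidate.
    """
    by_key: dict[tuple[str, str], list[TranscriptModel]] = {}
    for g in genes:
        if g.biotype != PROTEIN_CODING:
            continue
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    out: list[StitchCandidate] = []
    for lnc in unsupported:
        for g in by_key.get((lnc.chrom, lnc.strand), ()):
            gap = lnc.tss - g.end3 if lnc.strand == "+" else g.end3 - lnc.tss
            if 0 <= gap <= max_gap:
                out.append(StitchCandidate(lnc, g, gap))
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _max_exon_overlap(flank: tuple[int, int], model: TranscriptModel) -> int:
    return max((_overlap(flank, exon) for exon in model.exons), default=0)


def junction_support(
    cand: StitchCandidate,
    junctions: Sequence[Junction],
    lncrna_universe: Sequence[TranscriptModel],
    min_overlap: int = MIN_OVERLAP_DEFAULT,
    gene_universe: Sequence[TranscriptModel] | None = None,
) -> StitchCandidate:
    """Attach the junction evidence for one candidate.

    A junction supports the stitch when its gene-side flank overlaps an exon
    of the candidate gene and its lncRNA-side flank overlaps an exon of the
    candidate lncRNA, each by >= ``min_overlap`` nt.  On '+' the gene-side
    flank is the genomic-left one; on '-' the flanks swap.  A junction whose
    flank overlaps exons of both an lncRNA and a protein-coding gene (over
    the full universes) cannot be assigned and is discarded as ambiguous.
    """
    gene_universe = gene_universe if gene_universe is not None else [cand.gene]
    strand = cand.lncrna.strand
    lnc_models = [
        m for m in lncrna_universe if m.chrom == cand.lncrna.chrom and m.strand == strand
    ]
    gene_models = [
        m
        for m in gene_universe
        if m.biotype == PROTEIN_CODING and m.chrom == cand.lncrna.chrom and m.strand == strand
    ]

    def ambiguous(flank: tuple[int, int]) -> bool:
        hits_lnc = any(_max_exon_overlap(flank, m) >= min_overlap for m in lnc_models)
        hits_gene = any(_max_exon_overlap(flank, m) >= min_overlap for m in gene_models)
        return hits_lnc and hits_gene

    retained: list[Junction] = []
    for j in junctions:
        if j.chrom != cand.lncrna.chrom or j.strand != strand:
            continue
        gene_flank, lnc_flank = (
            (j.left_flank, j.right_flank) if strand == "+" else (j.right_flank, j.left_flank)
        )
        if _max_exon_overlap(gene_flank, cand.gene) < min_overlap:
            continue
        if _max_exon_overlap(lnc_flank, cand.lncrna) < min_overlap:
            continue
        if ambiguous(gene_flank) or ambiguous(lnc_flank):
            continue
        retained.append(j)
    return StitchCandidate(
        lncrna=cand.lncrna,
        gene=cand.gene,
        gap=cand.gap,
        supporting_junctions=retained,
        total_junction_reads=sum(j.read_count for j in retained),
    )


_BINS = [("1<=JR<=10", 1, 10), ("11<=JR<=100", 11, 100), ("JR>100", 101, None)]


def bin_support(cands: Sequence[StitchCandidate]) -> pd.DataFrame:
    """Count supported stitches per biotype class and junction-read bin.

    Each lncRNA counts once (its maximum-support candidate); candidates with
    zero supporting reads are excluded.  Bins partition the positive
    integers: [1, 10], [11, 100], (100, inf).
    """
    best: dict[str, StitchCandidate] = {}
    for c in cands:
        key = c.lncrna.transcript_id
        if key not in best or c.total_junction_reads > best[key].total_junction_reads:
            best[key] = c
    classes = {"mono-exonic": [], "multi-exonic": []}
    for c in best.values():
        if c.total_junction_reads < 1:
            continue
        classes["mono-exonic" if c.lncrna.mono_exonic else "multi-exonic"].append(
            c.total_junction_reads
        )
    rows = {}
    for cls, reads in classes.items():
        counts = []
        for _, lo, hi in _BINS:
            counts.append(sum(1 for r in reads if r >= lo and (hi is None or r <= hi)))
        rows[cls] = counts + [len(reads)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[name for name, _, _ in _BINS] + ["total"]
    )


def overlap_fraction_stats(cands: Sequence[StitchCandidate]) -> tuple[float, float]:
    """Fractions of retained junctions whose gene-side / lncRNA-side flank
    lies entirely within a gene / lncRNA exon of its candidate pair."""
    n = full_gene = full_lnc = 0
    for c in cands:
        strand = c.lncrna.strand
        for j in c.supporting_junctions:
            gene_flank, lnc_flank = (
                (j.left_flank, j.right_flank) if strand == "+" else (j.right_flank, j.left_flank)
            )
            n += 1
            full_gene += any(
                s <= gene_flank[0] and gene_flank[1] <= e for s, e in c.gene.exons
            )
            full_lnc += any(
                s <= lnc_flank[0] and lnc_flank[1] <= e for s, e in c.lncrna.exons
            )
    if n == 0:
        raise ValueError("no retained junctions")
    return full_gene / n, full_lnc / n
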