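"""Seeded generators for every fixture the pipeline consumes.

These stand in for the real public peak databases (CAGE/ChIP/DNase
compendia), exclusion tracks and transcript catalogues: small chromosomes,
peaks planted at controlled signed distances from known TSSs, exclusion
intervals, toy gene/lncRNA models and junction records with configurable
overlap geometry.  Every scenario records a truth table (each feature's
intended nearest peak and signed distance; each stitch case's expected fate)
so downstream outputs can be asserted exactly, and every draw flows from a
single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .peakdb import CAGE, Peak, PeakIndex, build_index
from .query import FeatureTSS
from .stats import ExclusionSet
from .stitch import LNCRNA, PROTEIN_CODING, Junction, TranscriptModel

__all__ = [
    "ScenarioSpec",
    "Scenario",
    "make_scenario",
    "StitchCase",
    "StitchScenarioSpec",
    "StitchScenario",
    "make_stitch_scenario",
]


# ---------------------------------------------------------------------------
# zipper scenarios


@dataclass
class ScenarioSpec:
    """Controls for one synthetic zipper scenario.

    ``offset`` is the per-feature signed TSS-to-peak distance rule:
    ``("point", d)`` plants every peak at exactly signed distance d,
    ``("uniform", lo, hi)`` draws magnitudes uniformly in [lo, hi] with a
    random sign, ``("absent",)`` plants no peak for the feature.
    """

    chrom_sizes: dict[str, int]
    n_features: dict[str, int]
    assay: str = "DNase"
    n_samples: int = 1
    offset: tuple = ("point", 0)
    width: tuple = ("uniform", 50, 300)
    strand_mix: float = 0.5
    enrichment: tuple = ("uniform", 1.0, 10.0)
    exclusion_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not 0 <= self.exclusion_fraction < 1:
            raise ValueError("exclusion_fraction must be in [0, 1)")
        for chrom in self.n_features:
            if chrom not in self.chrom_sizes:
                raise ValueError(f"n_features chromosome {chrom!r} not in chrom_sizes")


@dataclass
class Scenario:
    """A generated scenario: in-memory objects plus (optionally) the files."""

    spec: ScenarioSpec
    features: list[FeatureTSS]
    peaks: list[Peak]
    index: PeakIndex
    chrom_sizes: dict[str, int]
    exclusions: ExclusionSet
    truth: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _draw(rule: tuple, rng: np.random.Generator) -> float:
    kind = rule[0]
    if kind == "point":
        return rule[1]
    if kind == "uniform":
        lo, hi = rule[1], rule[2]
        if isinstance(lo, int) and isinstance(hi, int):
            return int(rng.integers(lo, hi + 1))
        return float(rng.uniform(lo, hi))
    raise ValueError(f"unknown distribution {rule!r}")


def _max_offset(rule: tuple) -> int:
    if rule[0] == "point":
        return abs(int(rule[1]))
    if rule[0] == "uniform":
        return int(rule[2])
    return 0  # absent


def _max_width(rule: tuple) -> int:
    return int(rule[2]) if rule[0] == "uniform" else int(rule[1])


def _plant_peak(q: int, strand: str, d: int, width: int, length: int) -> tuple[int, int]:
    """Peak interval whose signed distance to the TSS (0-based ``q``) is
    exactly ``d`` under the strand-aware convention."""
    if d == 0:
        start = max(0, q - width // 2)
        if q >= start + width:
            start = q - width + 1
    elif (d > 0) == (strand == "+"):  # peak at greater coordinates
        start = q + abs(d)
    else:  # peak at smaller coordinates: q - end + 1 = |d|
        start = (q - abs(d) + 1) - width
    end = start + width
    if start < 0 or end > length:
        raise ValueError(
            f"infeasible placement: peak [{start}, {end}) outside chromosome of length {length}"
        )
    return start, end


def make_scenario(spec: ScenarioSpec, outdir: str | Path | None = None) -> Scenario:
    """Generate features, per-sample peaks, exclusion intervals and the truth
    table; write the file dialects when ``outdir`` is given."""
    rng = np.random.default_rng(spec.seed)
    margin = _max_offset(spec.offset) + _max_width(spec.width) + 2

    excl_intervals: dict[str, list[tuple[int, int]]] = {}
    features: list[FeatureTSS] = []
    for chrom in sorted(spec.n_features):
        n = spec.n_features[chrom]
        length = spec.chrom_sizes[chrom]
        excl_end = int(spec.exclusion_fraction * length)
        if excl_end > 0:
            excl_intervals[chrom] = [(0, excl_end)]
        lo = excl_end + margin
        hi = length - margin
        if n <= 0:
            continue
        spacing = (hi - lo) // n
        if spacing < 2 * margin + 2:
            raise ValueError(
                f"infeasible placement on {chrom}: {n} features need spacing "
                f">= {2 * margin + 2}, got {spacing}"
            )
        jitter = rng.integers(0, spacing - 2 * margin - 1, size=n)
        for i in range(n):
            q = lo + i * spacing + margin + int(jitter[i])
            strand = "+" if rng.random() < spec.strand_mix else "-"
            features.append(FeatureTSS(chrom, q + 1, strand, f"{chrom}_tss_{i + 1}"))

    sample_ids = [f"{spec.assay.replace(':', '_')}_s{k + 1}" for k in range(spec.n_samples)]
    peaks: list[Peak] = []
    truth_rows = []
    for sid in sample_ids:
        for t in features:
            q = t.pos - 1
            length = spec.chrom_sizes[t.chrom]
            enr = float(_draw(spec.enrichment, rng))
            if spec.offset[0] == "absent":
                truth_rows.append(
                    {"label": t.label, "chrom": t.chrom, "pos": t.pos, "strand": t.strand,
                     "sample_id": sid, "distance": pd.NA, "width": pd.NA, "enrichment": pd.NA}
                )
                continue
            d = int(_draw(spec.offset, rng))
            if spec.offset[0] == "uniform" and d != 0:
                d = int(d if rng.random() < 0.5 else -d)
            width = int(_draw(spec.width, rng))
            start, end = _plant_peak(q, t.strand, d, width, length)
            if spec.assay == CAGE:
                peak = Peak(t.chrom, start, end, t.strand, enr, tpm=enr,
                            sample_id=sid, assay=CAGE)
            else:
                peak = Peak(t.chrom, start, end, ".", enr, neglog10_qvalue=5.0,
                            sample_id=sid, assay=spec.assay)
            peaks.append(peak)
            truth_rows.append(
                {"label": t.label, "chrom": t.chrom, "pos": t.pos, "strand": t.strand,
                 "sample_id": sid, "distance": d, "width": width, "enrichment": enr}
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["label", "chrom", "pos", "strand", "sample_id", "distance", "width", "enrichment"],
    )
    truth["distance"] = truth["distance"].astype("Int64")
    truth["width"] = truth["width"].astype("Int64")
    index = build_index(peaks, spec.chrom_sizes, assay=spec.assay)
    for sid in sample_ids:
        index.add_sample(sid)
    exclusions = ExclusionSet(excl_intervals)

    scenario = Scenario(
        spec=spec,
        features=features,
        peaks=peaks,
        index=index,
        chrom_sizes=dict(spec.chrom_sizes),
        exclusions=exclusions,
        truth=truth,
        paths={},
    )
    if outdir is not None:
        _write_scenario(scenario, Path(outdir), sample_ids, excl_intervals)
    return scenario


def _write_scenario(
    sc: Scenario,
    outdir: Path,
    sample_ids: list[str],
    excl_intervals: dict[str, list[tuple[int, int]]],
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    spec = sc.spec

    feat = outdir / "features.tsv"
    with open(feat, "wt", encoding="utf-8") as fh:
        for t in sc.features:
            fh.write(f"{t.chrom}\t{t.pos}\t{t.strand}\t{t.label}\n")
    sizes = outdir / "chrom.sizes"
    with open(sizes, "wt", encoding="utf-8") as fh:
        for chrom in sorted(spec.chrom_sizes):
            fh.write(f"{chrom}\t{spec.chrom_sizes[chrom]}\n")
    excl = outdir / "exclude.bed"
    with open(excl, "wt", encoding="utf-8") as fh:
        for chrom in sorted(excl_intervals):
            for s, e in excl_intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")

    by_sample: dict[str, list[Peak]] = {sid: [] for sid in sample_ids}
    for p in sc.peaks:
        by_sample[p.sample_id].append(p)
    catalog = outdir / "catalog.tsv"
    with open(catalog, "wt", encoding="utf-8") as cat:
        for sid in sample_ids:
            plist = sorted(by_sample[sid], key=lambda p: (p.chrom, p.start, p.end))
            if spec.assay == CAGE:
                fname = f"{sid}.cage.tsv"
                with open(outdir / fname, "wt", encoding="utf-8") as fh:
                    fh.write(f"#chrom\tstart\tend\tname\tscore\tstrand\t{sid}\n")
                    for k, p in enumerate(plist):
                        fh.write(
                            f"{p.chrom}\t{p.start}\t{p.end}\tcage_{k + 1}\t0\t{p.strand}\t{p.tpm:g}\n"
                        )
            else:
                fname = f"{sid}.narrowPeak"
                with open(outdir / fname, "wt", encoding="utf-8") as fh:
                    for k, p in enumerate(plist):
                        fh.write(
                            f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{k + 1}\t0\t.\t"
                            f"{p.signal_value:g}\t-1\t{p.neglog10_qvalue:g}\t-1\n"
                        )
            cat.write(f"{sid}\t{spec.assay}\t{sid}\t{fname}\n")

    truth_path = outdir / "truth.tsv"
    sc.truth.to_csv(truth_path, sep="\t", na_rep="NA", index=False)
    sc.paths = {
        "features": feat,
        "chrom_sizes": sizes,
        "exclude": excl,
        "catalog": catalog,
        "truth": truth_path,
        "outdir": outdir,
    }


# ---------------------------------------------------------------------------
# stitch scenarios


@dataclass
class StitchCase:
    """One gene/lncRNA pair with controlled stitch and junction geometry.

    ``gene_overlap`` / ``lnc_overlap`` are the nt of the junction flanks
    falling inside the respective exons (the flank lengths themselves, since
    generated flanks sit inside the exons); ``ambiguous`` adds a decoy lncRNA
    whose exon covers the gene-side flank region, making the junction
    unassignable; ``cage_distance`` plants a same-strand CAGE peak at that
    distance from the lncRNA TSS (None = no CAGE peak).
    """

    gap: int
    mono: bool = True
    gene_overlap: int = 8
    lnc_overlap: int = 8
    reads: int = 5
    ambiguous: bool = False
    strand: str = "+"
    has_junction: bool = True
    cage_distance: int | None = None


@dataclass
class StitchScenarioSpec:
    cases: list[StitchCase]
    chrom_size: int = 100_000
    max_gap: int = 5_827
    cage_radius: int = 500
    min_overlap: int = 2
    seed: int = 0


@dataclass
class StitchScenario:
    spec: StitchScenarioSpec
    genes: list[TranscriptModel]
    lncrnas: list[TranscriptModel]
    junctions: list[Junction]
    cage_index: PeakIndex
    chrom_sizes: dict[str, int]
    truth: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def make_stitch_scenario(
    spec: StitchScenarioSpec, outdir: str | Path | None = None
) -> StitchScenario:
    """One chromosome per case; truth records whether the pair must survive
    the CAGE filter, the stitching gap bound, and the junction-support filter."""
    genes: list[TranscriptModel] = []
    lncrnas: list[TranscriptModel] = []
    junctions: list[Junction] = []
    cage_peaks: list[Peak] = []
    chrom_sizes: dict[str, int] = {}
    truth_rows = []

    for i, case in enumerate(spec.cases):
        chrom = f"chrS{i + 1}"
        chrom_sizes[chrom] = spec.chrom_size
        cid = f"case{i + 1}"
        if case.strand == "+":
            gene_exons = ((1000, 1400), (2000, 3000))
            gene_end0 = 3000  # 0-based exclusive end of the 3'-most exon
            tss0 = gene_end0 + case.gap - 1  # gap = lnc.tss - gene.end3
            if case.mono:
                lnc_exons = ((tss0, tss0 + 500),)
            else:
                lnc_exons = ((tss0, tss0 + 300), (tss0 + 900, tss0 + 1200))
        else:
            lnc_end0 = 3000  # lnc TSS (1-based) = 3000 on '-'
            tss0 = lnc_end0 - 1
            if case.mono:
                lnc_exons = ((lnc_end0 - 500, lnc_end0),)
            else:
                lnc_exons = ((lnc_end0 - 1200, lnc_end0 - 900), (lnc_end0 - 300, lnc_end0))
            gene_start0 = lnc_end0 + case.gap - 1  # gap = gene.end3 - lnc.tss
            gene_exons = ((gene_start0, gene_start0 + 1000),
                          (gene_start0 + 1600, gene_start0 + 2000))

        gene = TranscriptModel(f"pcg_{cid}", f"pcg_{cid}", PROTEIN_CODING,
                               chrom, case.strand, gene_exons)
        lnc = TranscriptModel(f"lnc_{cid}", f"lnc_{cid}", LNCRNA,
                              chrom, case.strand, lnc_exons)
        genes.append(gene)
        lncrnas.append(lnc)

        if case.ambiguous:
            # decoy lncRNA exon covering the gene-side flank region; its own
            # TSS sits upstream of the gene 3' end so it never stitches itself
            if case.strand == "+":
                decoy_exons = ((2500, 3000),)
            else:
                g0 = gene_exons[0][0]
                decoy_exons = ((g0, g0 + 500),)
            decoy = TranscriptModel(f"decoy_{cid}", f"decoy_{cid}", LNCRNA,
                                    chrom, case.strand, decoy_exons)
            lncrnas.append(decoy)

        if case.cage_distance is not None:
            q = lnc.tss - 1
            d = case.cage_distance
            if d == 0:
                start, end = q - 10, q + 10
            elif case.strand == "+":
                start, end = q + d, q + d + 50  # downstream: distance = start - q
            else:
                end = q - d + 1  # downstream for '-': smaller coordinates
                start = end - 50
            cage_peaks.append(Peak(chrom, start, end, case.strand, 3.0, tpm=3.0,
                                   sample_id="cage_1", assay=CAGE))

        if case.has_junction:
            go, lo = max(1, case.gene_overlap), max(1, case.lnc_overlap)
            if case.strand == "+":
                gene_flank = (gene_end0 - 3 - go, gene_end0 - 3)
                lnc_flank = (tss0 + 3, tss0 + 3 + lo)
                donor_end = gene_flank[1] - 1
                acceptor_start = lnc_flank[0]
                f5, f3 = go, lo
            else:
                lnc_flank = (lnc_end0 - 3 - lo, lnc_end0 - 3)
                gene_flank = (gene_exons[0][0] + 3, gene_exons[0][0] + 3 + go)
                donor_end = lnc_flank[1] - 1
                acceptor_start = gene_flank[0]
                f5, f3 = lo, go
            junctions.append(
                Junction(chrom, donor_end, acceptor_start, case.strand, f5, f3,
                         read_count=case.reads)
            )

        cage_supported = (
            case.cage_distance is not None and case.cage_distance <= spec.cage_radius
        )
        stitched = (not cage_supported) and 0 <= case.gap <= spec.max_gap
        supported = (
            stitched
            and case.has_junction
            and case.gene_overlap >= spec.min_overlap
            and case.lnc_overlap >= spec.min_overlap
            and not case.ambiguous
        )
        truth_rows.append(
            {"case_id": cid, "lncrna": lnc.transcript_id, "gene": gene.transcript_id,
             "chrom": chrom, "strand": case.strand, "mono": case.mono, "gap": case.gap,
             "cage_supported": cage_supported, "stitched": stitched,
             "supported": supported, "reads": case.reads if supported else 0}
        )

    cage_index = build_index(cage_peaks, chrom_sizes, assay=CAGE)
    cage_index.add_sample("cage_1")
    truth = pd.DataFrame(truth_rows)
    scenario = StitchScenario(
        spec=spec,
        genes=genes,
        lncrnas=lncrnas,
        junctions=junctions,
        cage_index=cage_index,
        chrom_sizes=chrom_sizes,
        truth=truth,
    )
    if outdir is not None:
        _write_stitch_scenario(scenario, Path(outdir), cage_peaks)
    return scenario


def _bed12_line(t: TranscriptModel) -> str:
    start, end = t.exons[0][0], t.exons[-1][1]
    sizes = ",".join(str(e - s) for s, e in t.exons)
    offsets = ",".join(str(s - start) for s, _ in t.exons)
    return (
        f"{t.chrom}\t{start}\t{end}\t{t.transcript_id}\t0\t{t.strand}\t"
        f"{start}\t{end}\t0\t{len(t.exons)}\t{sizes}\t{offsets}"
    )


def _write_stitch_scenario(sc: StitchScenario, outdir: Path, cage_peaks: list[Peak]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    genes_bed = outdir / "genes.bed"
    genes_bed.write_text("".join(_bed12_line(t) + "\n" for t in sc.genes))
    lnc_bed = outdir / "lncrnas.bed"
    lnc_bed.write_text("".join(_bed12_line(t) + "\n" for t in sc.lncrnas))

    junc_bed = outdir / "junctions.bed"
    with open(junc_bed, "wt", encoding="utf-8") as fh:
        for k, j in enumerate(sc.junctions):
            start = j.left_flank[0]
            end = j.right_flank[1]
            offsets = f"0,{j.acceptor_start - start}"
            fh.write(
                f"{j.chrom}\t{start}\t{end}\tjunc_{k + 1}\t{j.read_count}\t{j.strand}\t"
                f"{start}\t{end}\t0\t2\t{j.flank5_len},{j.flank3_len}\t{offsets}\n"
            )

    cage = outdir / "cage_1.cage.tsv"
    with open(cage, "wt", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tcage_1\n")
        for k, p in enumerate(sorted(cage_peaks, key=lambda p: (p.chrom, p.start))):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tcage_{k + 1}\t0\t{p.strand}\t{p.tpm:g}\n")

    sizes = outdir / "chrom.sizes"
    with open(sizes, "wt", encoding="utf-8") as fh:
        for chrom in sorted(sc.chrom_sizes):
            fh.write(f"{chrom}\t{sc.chrom_sizes[chrom]}\n")

    truth_path = outdir / "truth.tsv"
    sc.truth.to_csv(truth_path, sep="\t", index=False)
    sc.paths = {
        "genes": genes_bed,
        "lncrnas": lnc_bed,
        "junctions": junc_bed,
        "cage": cage,
        "chrom_sizes": sizes,
        "truth": truth_path,
        "outdir": outdir,
    }
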