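"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from zipperplot.peakdb import CAGE, Peak, build_index
from zipperplot.query import FeatureTSS, PeakHit, signed_distance


def make_peak(chrom="chr1", start=100, end=250, sample_id="s1", assay="DNase",
              strand=".", signal=1.0, q=5.0, tpm=None):
    if assay == CAGE:
        tpm = 1.0 if tpm is None else tpm
        return Peak(chrom, start, end, strand, signal, tpm=tpm,
                    sample_id=sample_id, assay=CAGE)
    return Peak(chrom, start, end, ".", signal, neglog10_qvalue=q,
                sample_id=sample_id, assay=assay)


def make_hit(distance, strand="+", chrom="chr1", pos=1000, label=None,
             sample_id="s1", width=100, enrichment=2.0):
    """A PeakHit with a given signed distance (geometry-consistent peak)."""
    if distance is not None:
        pos = max(pos, abs(distance) + width + 2)  # keep the peak on-chromosome
    feature = FeatureTSS(chrom, pos, strand, label)
    if distance is None:
        return PeakHit(feature, None, None, sample_id)
    q = pos - 1
    if distance == 0:
        start = max(0, q - width // 2)
        if q >= start + width:
            start = q - width + 1
    elif (distance > 0) == (strand == "+"):
        start = q + abs(distance)
    else:
        start = (q - abs(distance) + 1) - width
    peak = Peak(chrom, start, start + width, ".", enrichment,
                neglog10_qvalue=5.0, sample_id=sample_id, assay="DNase")
    assert signed_distance(feature, peak) == distance
    return PeakHit(feature, peak, distance, sample_id)


def brute_force_nearest(tss, peaks, stranded):
    """Linear-scan oracle for the nearest-peak query, with the documented
    tie rule (min |d|; then downstream; then smallest start, smallest end)."""
    cands = []
    for p in peaks:
        if p.chrom != tss.chrom:
            continue
        if stranded and p.strand != tss.strand:
            continue
        d = signed_distance(tss, p)
        cands.append((abs(d), 0 if d >= 0 else 1, p.start, p.end, d, p))
    if not cands:
        return None
    cands.sort(key=lambda c: c[:4])
    best = cands[0]
    return best[5], best[4]


def random_index_and_features(rng, n_peaks=40, n_features=25, n_samples=2,
                              assay="DNase", chrom_sizes=None):
    """A random small index plus random TSSs for oracle-equivalence checks."""
    chrom_sizes = chrom_sizes or {"chr1": 50_000, "chr2": 30_000}
    chroms = sorted(chrom_sizes)
    peaks = []
    for k in range(n_samples):
        sid = f"s{k + 1}"
        for _ in range(n_peaks):
            chrom = chroms[rng.integers(len(chroms))]
            size = chrom_sizes[chrom]
            start = int(rng.integers(0, size - 500))
            width = int(rng.integers(1, 400))
            strand = "+" if rng.random() < 0.5 else "-"
            peaks.append(make_peak(chrom, start, start + width, sid, assay,
                                   strand=strand if assay == CAGE else ".",
                                   signal=float(rng.uniform(0.5, 9))))
    features = []
    for i in range(n_features):
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(1, chrom_sizes[chrom] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(FeatureTSS(chrom, pos, strand, f"f{i}"))
    index = build_index(peaks, chrom_sizes, assay=assay)
    return index, features, peaks


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
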