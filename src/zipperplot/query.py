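"""Signed TSS-to-peak distances and nearest-peak retrieval.

Distance convention (strand-aware, in feature orientation):

* a TSS is a 1-based genomic position; internally it is converted to the
  0-based frame of the BED peaks (``q = pos - 1``);
* distance 0 means the TSS lies inside the peak interval ``[start, end)``
  (half-open: a TSS at ``end`` is outside);
* otherwise the magnitude is the distance from the TSS to the nearest peak
  edge (``start - q`` when the peak is at greater coordinates,
  ``q - end + 1`` when at smaller coordinates), and the sign is positive when
  that edge lies downstream of the feature: greater coordinates for a
  '+' feature, smaller coordinates for a '-' feature.

CAGE queries are strand-matched: only peaks on the feature's strand are
eligible.  ChIP/DNase peaks are unstranded and always eligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .peakdb import CAGE, Peak, PeakIndex, _Bucket

__all__ = [
    "FeatureTSS",
    "PeakHit",
    "FeatureFileError",
    "read_features",
    "signed_distance",
    "nearest_peak",
    "nearest_across_samples",
    "batch_query",
]

MAX_FEATURES_DEFAULT = 20_000


class FeatureFileError(ValueError):
    """A feature (TSS) file could not be parsed or exceeds the cap."""


@dataclass(frozen=True)
class FeatureTSS:
    """One user-supplied stranded TSS position (1-based)."""

    chrom: str
    pos: int
    strand: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos < 1:
            raise ValueError(f"TSS position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class PeakHit:
    """The closest peak to one TSS, or a missing hit when no peak is eligible."""

    feature: FeatureTSS
    peak: Peak | None
    distance: int | None
    sample_id: str | None

    @property
    def is_missing(self) -> bool:
        return self.peak is None

    @property
    def peak_width(self) -> int | None:
        return None if self.peak is None else self.peak.width

    @property
    def enrichment(self) -> float | None:
        return None if self.peak is None else self.peak.enrichment


def read_features(
    path: str | Path, max_features: int = MAX_FEATURES_DEFAULT
) -> list[FeatureTSS]:
    """Read the user TSS file: 3 or 4 tab-separated fields per line
    (chromosome, 1-based coordinate, strand[, label]).

    Features without a label get ``feature_<n>`` (1-based).  Files with more
    than ``max_features`` features are rejected outright.
    """
    features: list[FeatureTSS] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4):
                raise FeatureFileError(
                    f"{path}: line {lineno}: expected 3 or 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, strand = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FeatureFileError(
                    f"{path}: line {lineno}: non-integer coordinate {pos_s!r}"
                ) from None
            if strand not in "+-":
                raise FeatureFileError(
                    f"{path}: line {lineno}: strand must be '+' or '-', got {strand!r}"
                )
            label = fields[3] if len(fields) == 4 and fields[3] else f"feature_{len(features) + 1}"
            try:
                features.append(FeatureTSS(chrom, pos, strand, label))
            except ValueError as exc:
                raise FeatureFileError(f"{path}: line {lineno}: {exc}") from None
            if len(features) > max_features:
                raise FeatureFileError(
                    f"{path}: more than {max_features} features (the configured cap); "
                    f"split the input or raise max_features"
                )
    return features


def signed_distance(tss: FeatureTSS, peak: Peak) -> int:
    """Signed distance from a TSS to a peak on the same chromosome.

    0 iff the TSS lies inside the half-open peak interval; otherwise the gap
    to the nearest peak edge, positive when the peak is downstream of the
    feature (greater coordinate for '+', smaller for '-').
    """
    if tss.chrom != peak.chrom:
        raise ValueError(
            f"TSS on {tss.chrom!r} vs peak on {peak.chrom!r}: different chromosomes"
        )
    q = tss.pos - 1
    if peak.start <= q < peak.end:
        return 0
    if q < peak.start:  # peak at greater coordinates
        mag = peak.start - q
        downstream = tss.strand == "+"
    else:  # peak at smaller coordinates
        mag = q - peak.end + 1
        downstream = tss.strand == "-"
    return mag if downstream else -mag


def _bucket_nearest(bucket: _Bucket, q: int, strand: str) -> tuple[int, int] | None:
    """(peak index, signed distance) of the nearest peak in one bucket.

    Overlaps win at distance 0 (smallest start among overlapping peaks);
    otherwise the smaller gap wins and an exact tie goes to the downstream
    peak in feature orientation.
    """
    n = len(bucket)
    if n == 0:
        return None
    starts = bucket.starts
    i = int(np.searchsorted(starts, q, side="right"))  # peaks[0..i) have start <= q
    if i > 0 and bucket.pmax_end[i - 1] > q:
        # overlapping peak exists; first index whose running-max end passes q
        j = int(np.searchsorted(bucket.pmax_end[:i], q, side="right"))
        return j, 0
    left = None  # (magnitude, index), peak at smaller coordinates
    if i > 0:
        left = (int(q - bucket.pmax_end[i - 1] + 1), int(bucket.pmax_arg[i - 1]))
    right = None  # peak at greater coordinates
    if i < n:
        right = (int(starts[i] - q), i)
    if left is None and right is None:
        return None
    if left is None:
        mag, idx = right
        return idx, mag if strand == "+" else -mag
    if right is None:
        mag, idx = left
        return idx, mag if strand == "-" else -mag
    if right[0] < left[0] or (right[0] == left[0] and strand == "+"):
        mag, idx = right
        return idx, mag if strand == "+" else -mag
    mag, idx = left
    return idx, mag if strand == "-" else -mag


def nearest_peak(tss: FeatureTSS, index: PeakIndex, sample_id: str) -> PeakHit:
    """Closest peak to ``tss`` within one sample (strand-matched for CAGE)."""
    if sample_id not in index.sample_ids:
        raise KeyError(f"unknown sample_id {sample_id!r} for assay {index.assay}")
    bucket = index.bucket(sample_id, tss.chrom, tss.strand)
    if bucket is None:
        return PeakHit(tss, None, None, sample_id)
    found = _bucket_nearest(bucket, tss.pos - 1, tss.strand)
    if found is None:
        return PeakHit(tss, None, None, sample_id)
    idx, dist = found
    return PeakHit(tss, bucket.peaks[idx], dist, sample_id)


def nearest_across_samples(tss: FeatureTSS, index: PeakIndex) -> PeakHit:
    """Best hit over all samples: minimal |distance|, ties to the
    lexicographically smallest sample_id."""
    best: PeakHit | None = None
    for sid in index.sample_ids:  # sorted, so strict improvement = tie rule
        hit = nearest_peak(tss, index, sid)
        if hit.is_missing:
            continue
        if best is None or abs(hit.distance) < abs(best.distance):
            best = hit
    if best is None:
        return PeakHit(tss, None, None, None)
    return best


def batch_query(
    features: Sequence[FeatureTSS],
    index: PeakIndex,
    sample_id: str | None = None,
) -> list[PeakHit]:
    """One :class:`PeakHit` per feature, order preserved.

    ``sample_id=None`` runs the all-samples workflow (per feature, the sample
    whose peak is closest is retained); otherwise only that sample is queried.
    """
    if not features:
        raise ValueError("batch_query requires a non-empty feature list")
    if sample_id is None:
        return [nearest_across_samples(t, index) for t in features]
    return [nearest_peak(t, index, sample_id) for t in features]


def _distances(
    features: Sequence[FeatureTSS],
    index: PeakIndex,
    sample_id: str | None = None,
) -> list[int | None]:
    """Lean distance-only query path used by the permutation null."""
    sids = index.sample_ids if sample_id is None else [sample_id]
    out: list[int | None] = []
    for t in features:
        q = t.pos - 1
        best: int | None = None
        for sid in sids:
            bucket = index.bucket(sid, t.chrom, t.strand)
            if bucket is None:
                continue
            found = _bucket_nearest(bucket, q, t.strand)
            if found is not None and (best is None or abs(found[1]) < abs(best)):
                best = found[1]
        out.append(best)
    return out


def hits_to_tsv(hits: Iterable[PeakHit], path: str | Path) -> Path:
    """Export hits as TSV (label, chrom, pos, strand, sample_id, peak_start,
    peak_end, distance, peak_width, enrichment); missing fields as NA."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(
            "label\tchrom\tpos\tstrand\tsample_id\tpeak_start\tpeak_end\t"
            "distance\tpeak_width\tenrichment\n"
        )
        for h in hits:
            f = h.feature
            if h.is_missing:
                tail = "\t".join(["NA"] * 5)
                sid = h.sample_id or "NA"
            else:
                sid = h.sample_id
                tail = (
                    f"{h.peak.start}\t{h.peak.end}\t{h.distance}\t"
                    f"{h.peak_width}\t{h.enrichment:g}"
                )
            fh.write(f"{f.label or ''}\t{f.chrom}\t{f.pos}\t{f.strand}\t{sid}\t{tail}\n")
    return path
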