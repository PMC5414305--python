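"""Peak database: parsing, filtering and indexing of assay peak files.

Peaks come from three families of evidence for transcriptional activity:

* CAGE-seq — stranded 5'-end tag clusters with a per-sample tpm
  (tags per million) expression value;
* ChIP-seq — histone-mark enrichment intervals (unstranded);
* DNase-seq — open-chromatin hypersensitive sites (unstranded).

ChIP/DNase peaks arrive as ENCODE narrowPeak / broadPeak / gappedPeak files,
CAGE peaks as a BED6-plus-tpm-columns table.  All peaks are stored 0-based
half-open (BED convention); conversion to 1-based user coordinates happens in
:mod:`zipperplot.query` only.

The index groups peaks per (sample, chromosome[, strand]) into start-sorted
arrays augmented with a running maximum of interval ends, which is what makes
nearest-peak retrieval a pair of binary searches even when peak widths vary.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

CAGE = "CAGE"
DNASE = "DNase"

__all__ = [
    "CAGE",
    "DNASE",
    "Peak",
    "PeakIndex",
    "SampleCatalog",
    "PeakFileError",
    "PeakFileWarning",
    "read_narrowpeak",
    "read_broadpeak",
    "read_gappedpeak",
    "read_cage_peaks",
    "filter_by_fdr",
    "filter_by_tpm",
    "build_index",
    "read_chrom_sizes",
    "read_catalog",
]


class PeakFileError(ValueError):
    """A peak file could not be parsed."""


class PeakFileWarning(UserWarning):
    """A record was rejected or a dialect irregularity tolerated."""


@dataclass(frozen=True)
class Peak:
    """One assay interval with its enrichment metadata.

    ``signal_value`` carries the overall enrichment (signalValue for
    ChIP/DNase); ``tpm`` is present exactly for CAGE peaks.  ``strand`` is
    '+'/'-' for CAGE and '.' for the unstranded assays.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    signal_value: float = 0.0
    neglog10_qvalue: float | None = None
    tpm: float | None = None
    sample_id: str = ""
    assay: str = "ChIP"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.assay == CAGE:
            if self.strand not in "+-":
                raise ValueError("CAGE peaks must be stranded (+/-)")
            if self.tpm is None:
                raise ValueError("CAGE peaks require a tpm value")
        else:
            if self.strand != ".":
                raise ValueError(f"{self.assay} peaks are unstranded")
            if self.tpm is not None:
                raise ValueError("tpm is a CAGE-only attribute")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def enrichment(self) -> float:
        """tpm for CAGE, signalValue otherwise."""
        return float(self.tpm) if self.assay == CAGE else float(self.signal_value)


@dataclass(frozen=True)
class CatalogEntry:
    sample_id: str
    assay: str
    name: str
    path: str


@dataclass
class SampleCatalog:
    """Flat list of (sample, assay, name, file) records driving a DB build."""

    entries: list[CatalogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.assay, e.sample_id)
            if key in seen:
                raise ValueError(f"duplicate sample_id {e.sample_id!r} for assay {e.assay!r}")
            seen.add(key)

    def for_assay(self, assay: str) -> list[CatalogEntry]:
        return [e for e in self.entries if e.assay == assay]


# ---------------------------------------------------------------------------
# file readers


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _int_field(value: str, what: str, path: str | Path, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise PeakFileError(f"{path}: line {lineno}: non-integer {what}: {value!r}") from None


def _float_field(value: str, what: str, path: str | Path, lineno: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise PeakFileError(f"{path}: line {lineno}: non-numeric {what}: {value!r}") from None


def _encode_reader(
    path: str | Path,
    sample_id: str,
    assay: str,
    n_required: int,
    fmt: str,
    signal_col: int,
    qvalue_col: int,
) -> list[Peak]:
    peaks: list[Peak] = []
    warned_extra = False
    for lineno, fields in _data_lines(path):
        if len(fields) < n_required:
            raise PeakFileError(
                f"{path}: line {lineno}: expected >= {n_required} columns for "
                f"{fmt}, got {len(fields)} (not {fmt}?)"
            )
        if len(fields) > n_required and not warned_extra:
            warnings.warn(
                f"{path}: line {lineno}: {len(fields) - n_required} extra trailing "
                f"column(s) beyond the {fmt} standard; ignored",
                PeakFileWarning,
                stacklevel=3,
            )
            warned_extra = True
        chrom = fields[0]
        start = _int_field(fields[1], "start", path, lineno)
        end = _int_field(fields[2], "end", path, lineno)
        if start < 0 or start >= end:
            warnings.warn(
                f"{path}: line {lineno}: invalid interval [{start}, {end}); record rejected",
                PeakFileWarning,
                stacklevel=3,
            )
            continue
        signal = _float_field(fields[signal_col], "signalValue", path, lineno)
        q = _float_field(fields[qvalue_col], "qValue", path, lineno)
        peaks.append(
            Peak(
                chrom=chrom,
                start=start,
                end=end,
                strand=".",
                signal_value=signal,
                neglog10_qvalue=None if q < 0 else q,  # -1 sentinel: unavailable
                sample_id=sample_id,
                assay=assay,
            )
        )
    return peaks


def read_narrowpeak(path: str | Path, sample_id: str, assay: str = "ChIP") -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file.

    Columns 7-9 are signalValue / pValue / qValue with the qValue stored as
    -log10; a -1 sentinel marks it unavailable and is stored as missing.  The
    strand column is ignored: ChIP and DNase peaks are kept unstranded.
    """
    return _encode_reader(path, sample_id, assay, 10, "narrowPeak", 6, 8)


def read_broadpeak(path: str | Path, sample_id: str, assay: str = "ChIP") -> list[Peak]:
    """Read an ENCODE broadPeak (BED6+3) file; no point-source column."""
    return _encode_reader(path, sample_id, assay, 9, "broadPeak", 6, 8)


def read_gappedpeak(path: str | Path, sample_id: str, assay: str = "ChIP") -> list[Peak]:
    """Read an ENCODE gappedPeak (BED12+3) file.

    Only the outer chromStart/chromEnd interval is kept; block structure is
    discarded because distance queries use the peak edge closest to the TSS.
    A blockSizes/blockStarts count mismatch is tolerated with a warning.
    """
    peaks: list[Peak] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 15:
            raise PeakFileError(
                f"{path}: line {lineno}: expected >= 15 columns for gappedPeak, "
                f"got {len(fields)} (not gappedPeak)"
            )
        chrom = fields[0]
        start = _int_field(fields[1], "start", path, lineno)
        end = _int_field(fields[2], "end", path, lineno)
        if start < 0 or start >= end:
            warnings.warn(
                f"{path}: line {lineno}: invalid interval [{start}, {end}); record rejected",
                PeakFileWarning,
                stacklevel=2,
            )
            continue
        n_blocks = _int_field(fields[9], "blockCount", path, lineno)
        sizes = [s for s in fields[10].rstrip(",").split(",") if s]
        starts = [s for s in fields[11].rstrip(",").split(",") if s]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            warnings.warn(
                f"{path}: line {lineno}: blockCount={n_blocks} does not match "
                f"{len(sizes)} sizes / {len(starts)} starts; outer interval kept",
                PeakFileWarning,
                stacklevel=2,
            )
        signal = _float_field(fields[12], "signalValue", path, lineno)
        q = _float_field(fields[14], "qValue", path, lineno)
        peaks.append(
            Peak(
                chrom=chrom,
                start=start,
                end=end,
                strand=".",
                signal_value=signal,
                neglog10_qvalue=None if q < 0 else q,
                sample_id=sample_id,
                assay=assay,
            )
        )
    return peaks


def read_cage_peaks(path: str | Path) -> list[Peak]:
    """Read a CAGE peak table: BED6 interval columns plus one tpm column per
    sample, with a header row naming the samples.

    Returns one :class:`Peak` per (interval, sample) pair.  CAGE peaks must be
    stranded; a missing/other strand or a non-numeric tpm is an error.
    """
    path = Path(path)
    with open(path, "rt", encoding="utf-8") as fh:
        header = None
        for raw in fh:
            if raw.strip():
                header = raw.rstrip("\n").lstrip("#").split("\t")
                break
    if header is None:
        return []
    fixed = ["chrom", "start", "end", "name", "score", "strand"]
    if [h.strip().lower() for h in header[:6]] != fixed:
        raise PeakFileError(
            f"{path}: CAGE header must start with {' '.join(fixed)} (tab-separated)"
        )
    sample_ids = [h.strip() for h in header[6:] if h.strip()]
    if not sample_ids:
        raise PeakFileError(f"{path}: CAGE file has no sample (tpm) columns")

    peaks: list[Peak] = []
    with open(path, "rt", encoding="utf-8") as fh:
        first = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if first:  # header
                first = False
                continue
            fields = line.split("\t")
            if len(fields) != 6 + len(sample_ids):
                raise PeakFileError(
                    f"{path}: line {lineno}: expected {6 + len(sample_ids)} columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            start = _int_field(fields[1], "start", path, lineno)
            end = _int_field(fields[2], "end", path, lineno)
            strand = fields[5]
            if strand not in "+-":
                raise PeakFileError(
                    f"{path}: line {lineno}: CAGE peaks must be stranded, got {strand!r}"
                )
            for sid, col in zip(sample_ids, fields[6:]):
                tpm = _float_field(col, f"tpm ({sid})", path, lineno)
                if tpm < 0:
                    raise PeakFileError(f"{path}: line {lineno}: negative tpm for {sid}")
                peaks.append(
                    Peak(
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        signal_value=tpm,
                        tpm=tpm,
                        sample_id=sid,
                        assay=CAGE,
                    )
                )
    return peaks


# ---------------------------------------------------------------------------
# filters


def filter_by_fdr(
    peaks: Sequence[Peak], alpha: float = 0.05, keep_unscored: bool = False
) -> list[Peak]:
    """Retain peaks whose FDR q-value is <= ``alpha``.

    The narrowPeak family stores -log10(q), so the test is
    ``neglog10_qvalue >= -log10(alpha)``.  Peaks whose q-value is unavailable
    (the -1 sentinel) are dropped unless ``keep_unscored`` is set, since an
    unscored peak cannot pass an FDR filter.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    threshold = -math.log10(alpha)
    out = []
    for p in peaks:
        if p.neglog10_qvalue is None:
            if keep_unscored:
                out.append(p)
        elif p.neglog10_qvalue >= threshold:
            out.append(p)
    return out


def filter_by_tpm(peaks: Sequence[Peak], min_tpm_exclusive: float | None = None) -> list[Peak]:
    """Retain CAGE peaks with tpm strictly greater than the threshold.

    ``None`` (the default) keeps every CAGE peak; ``0`` implements the
    stringent "tpm > 0" option.
    """
    for p in peaks:
        if p.assay != CAGE:
            raise ValueError("filter_by_tpm applies to CAGE peaks only")
    if min_tpm_exclusive is None:
        return list(peaks)
    return [p for p in peaks if p.tpm is not None and p.tpm > min_tpm_exclusive]


# ---------------------------------------------------------------------------
# index


class _Bucket:
    """Start-sorted peaks of one (sample, chrom[, strand]) with prefix-max ends."""

    __slots__ = ("peaks", "starts", "ends", "pmax_end", "pmax_arg")

    def __init__(self, peaks: list[Peak]) -> None:
        peaks = sorted(peaks, key=lambda p: (p.start, p.end))
        self.peaks = peaks
        self.starts = np.asarray([p.start for p in peaks], dtype=np.int64)
        self.ends = np.asarray([p.end for p in peaks], dtype=np.int64)
        self.pmax_end = np.maximum.accumulate(self.ends)
        # index of the first peak achieving each running max end (stable: the
        # smallest start among equally far upstream edges)
        prev = np.concatenate(([np.int64(-1)], self.pmax_end[:-1]))
        arg = np.where(self.ends > prev, np.arange(len(peaks), dtype=np.int64), 0)
        self.pmax_arg = np.maximum.accumulate(arg)

    def __len__(self) -> int:
        return len(self.peaks)


class PeakIndex:
    """Per-assay nearest-peak index.

    Buckets peaks by (sample_id, chrom) — and by strand for CAGE, because CAGE
    queries are strand-matched — each bucket sorted by start with an auxiliary
    running maximum of ends so both overlap detection and nearest-neighbour
    retrieval are binary searches.
    """

    def __init__(self, assay: str, chrom_sizes: Mapping[str, int]) -> None:
        self.assay = assay
        self.chrom_sizes = dict(chrom_sizes)
        self.stranded = assay == CAGE
        self._buckets: dict[tuple[str, str, str], _Bucket] = {}
        self._samples: set[str] = set()

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self._samples)

    @property
    def n_peaks(self) -> int:
        return sum(len(b) for b in self._buckets.values())

    def add_sample(self, sample_id: str) -> None:
        self._samples.add(sample_id)

    def bucket(self, sample_id: str, chrom: str, strand: str) -> _Bucket | None:
        key = (sample_id, chrom, strand if self.stranded else ".")
        return self._buckets.get(key)

    def iter_peaks(self) -> Iterator[Peak]:
        for b in self._buckets.values():
            yield from b.peaks

    # -- persistence (plain-text database directory) ------------------------

    def to_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "assay": self.assay,
            "chrom_sizes": self.chrom_sizes,
            "samples": self.sample_ids,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        with open(path / "peaks.tsv", "wt", encoding="utf-8") as fh:
            fh.write("chrom\tstart\tend\tstrand\tsignal_value\tneglog10_qvalue\ttpm\tsample_id\n")
            for p in sorted(
                self.iter_peaks(), key=lambda p: (p.sample_id, p.chrom, p.start, p.end)
            ):
                q = "NA" if p.neglog10_qvalue is None else repr(p.neglog10_qvalue)
                t = "NA" if p.tpm is None else repr(p.tpm)
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.strand}\t"
                    f"{p.signal_value!r}\t{q}\t{t}\t{p.sample_id}\n"
                )
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "PeakIndex":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        peaks: list[Peak] = []
        with open(path / "peaks.tsv", "rt", encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                chrom, start, end, strand, sig, q, tpm, sid = line.rstrip("\n").split("\t")
                peaks.append(
                    Peak(
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        signal_value=float(sig),
                        neglog10_qvalue=None if q == "NA" else float(q),
                        tpm=None if tpm == "NA" else float(tpm),
                        sample_id=sid,
                        assay=meta["assay"],
                    )
                )
        index = build_index(peaks, meta["chrom_sizes"], assay=meta["assay"])
        for sid in meta["samples"]:
            index.add_sample(sid)
        return index


def build_index(
    peaks: Sequence[Peak],
    chrom_sizes: Mapping[str, int],
    assay: str | None = None,
) -> PeakIndex:
    """Bucket and sort peaks into a :class:`PeakIndex`.

    All peaks must share one assay; a peak on a chromosome absent from
    ``chrom_sizes`` or extending past its length is an error.
    ``assay`` is only needed for an empty peak list.
    """
    assays = {p.assay for p in peaks}
    if len(assays) > 1:
        raise ValueError(f"peaks span multiple assays: {sorted(assays)}")
    if assays:
        assay = assays.pop()
    elif assay is None:
        raise ValueError("assay must be given for an empty peak list")

    index = PeakIndex(assay, chrom_sizes)
    grouped: dict[tuple[str, str, str], list[Peak]] = {}
    for p in peaks:
        size = chrom_sizes.get(p.chrom)
        if size is None:
            raise ValueError(f"peak on unknown chromosome {p.chrom!r}")
        if p.end > size:
            raise ValueError(
                f"peak [{p.start}, {p.end}) exceeds length {size} of chromosome {p.chrom!r}"
            )
        key = (p.sample_id, p.chrom, p.strand if index.stranded else ".")
        grouped.setdefault(key, []).append(p)
        index.add_sample(p.sample_id)
    for key, bucket_peaks in grouped.items():
        index._buckets[key] = _Bucket(bucket_peaks)
    return index


# ---------------------------------------------------------------------------
# ancillary tables


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length (nt)."""
    sizes: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise PeakFileError(f"{path}: line {lineno}: expected 'chrom<TAB>length'")
        sizes[fields[0]] = _int_field(fields[1], "length", path, lineno)
    return sizes


def read_catalog(path: str | Path) -> SampleCatalog:
    """Catalog TSV: sample_id, assay, name, path (one peak file per sample)."""
    entries = []
    base = Path(path).parent
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise PeakFileError(
                f"{path}: line {lineno}: expected 'sample_id<TAB>assay<TAB>name<TAB>path'"
            )
        sid, assay, name, fpath = fields[:4]
        if not Path(fpath).is_absolute():
            fpath = str(base / fpath)
        entries.append(CatalogEntry(sid, assay, name, fpath))
    return SampleCatalog(entries)
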