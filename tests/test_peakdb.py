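"""Peak file parsing, filtering and indexing."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zipperplot.peakdb import (
    CAGE,
    Peak,
    PeakFileError,
    PeakFileWarning,
    PeakIndex,
    build_index,
    filter_by_fdr,
    filter_by_tpm,
    read_broadpeak,
    read_cage_peaks,
    read_chrom_sizes,
    read_gappedpeak,
    read_narrowpeak,
)

from conftest import make_peak


def write(tmp_path, name, lines):
    path = tmp_path / name
    path.write_text("".join(line + "\n" for line in lines))
    return path


NARROW = "chr1\t100\t250\t.\t0\t.\t6.2\t10.1\t2.0\t75"


class TestEncodeReaders:
    def test_narrowpeak_field_mapping(self, tmp_path):
        peaks = read_narrowpeak(write(tmp_path, "a.narrowPeak", [NARROW]), "s1")
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.chrom, p.start, p.end) == ("chr1", 100, 250)
        assert p.signal_value == 6.2
        assert p.neglog10_qvalue == 2.0
        assert p.strand == "."  # ChIP/DNase stored unstranded
        assert p.sample_id == "s1"

    def test_empty_file(self, tmp_path):
        assert read_narrowpeak(write(tmp_path, "e.narrowPeak", []), "s1") == []

    def test_zero_length_interval_rejected_with_warning(self, tmp_path):
        path = write(tmp_path, "z.narrowPeak",
                     ["chr1\t100\t100\t.\t0\t.\t1\t-1\t1\t0", NARROW])
        with pytest.warns(PeakFileWarning, match="invalid interval"):
            peaks = read_narrowpeak(path, "s1")
        assert len(peaks) == 1

    def test_malformed_line_names_line_number(self, tmp_path):
        path = write(tmp_path, "m.narrowPeak", [NARROW, "chr1\tfoo\t2\t.\t0\t.\t1\t1\t1\t0"])
        with pytest.raises(PeakFileError, match="line 2"):
            read_narrowpeak(path, "s1")

    def test_too_few_columns_is_error(self, tmp_path):
        with pytest.raises(PeakFileError, match="expected >= 10"):
            read_narrowpeak(write(tmp_path, "f.narrowPeak", ["chr1\t1\t2"]), "s1")

    def test_broadpeak_accepts_nine_columns(self, tmp_path):
        peaks = read_broadpeak(
            write(tmp_path, "b.broadPeak", ["chr2\t10\t90\t.\t0\t.\t3.5\t-1\t1.7"]), "s2"
        )
        assert peaks[0].signal_value == 3.5
        assert peaks[0].neglog10_qvalue == 1.7

    def test_broadpeak_tolerates_narrowpeak_with_warning(self, tmp_path):
        path = write(tmp_path, "n.broadPeak", [NARROW])
        with pytest.warns(PeakFileWarning, match="extra trailing"):
            peaks = read_broadpeak(path, "s1")
        assert len(peaks) == 1

    def test_negative_start_rejected(self, tmp_path):
        path = write(tmp_path, "neg.broadPeak", ["chr1\t-5\t90\t.\t0\t.\t1\t-1\t1"])
        with pytest.warns(PeakFileWarning, match="invalid interval"):
            assert read_broadpeak(path, "s1") == []

    def test_qvalue_sentinel_stored_missing(self, tmp_path):
        path = write(tmp_path, "q.narrowPeak", ["chr1\t1\t9\t.\t0\t.\t1\t-1\t-1\t4"])
        assert read_narrowpeak(path, "s1")[0].neglog10_qvalue is None


GAPPED = ("chr1\t5000\t9000\t.\t0\t.\t5000\t9000\t0\t2\t"
          "400,300\t0,3700\t7.1\t-1\t2.3")


class TestGappedPeak:
    def test_outer_interval_kept_blocks_discarded(self, tmp_path):
        peaks = read_gappedpeak(write(tmp_path, "g.gappedPeak", [GAPPED]), "s1")
        assert (peaks[0].start, peaks[0].end) == (5000, 9000)
        assert peaks[0].signal_value == 7.1
        assert peaks[0].neglog10_qvalue == 2.3

    def test_block_mismatch_warns_but_loads(self, tmp_path):
        bad = GAPPED.replace("400,300", "400")
        with pytest.warns(PeakFileWarning, match="blockCount"):
            peaks = read_gappedpeak(write(tmp_path, "gm.gappedPeak", [bad]), "s1")
        assert (peaks[0].start, peaks[0].end) == (5000, 9000)

    def test_nine_column_file_rejected(self, tmp_path):
        path = write(tmp_path, "not.gappedPeak", ["chr1\t10\t90\t.\t0\t.\t1\t-1\t1"])
        with pytest.raises(PeakFileError, match="not gappedPeak"):
            read_gappedpeak(path, "s1")


class TestCageReader:
    def test_one_interval_two_samples(self, tmp_path):
        path = write(tmp_path, "c.tsv", [
            "#chrom\tstart\tend\tname\tscore\tstrand\tliver\tbrain",
            "chr1\t500\t520\tp1\t0\t+\t3.1\t0.0",
        ])
        peaks = read_cage_peaks(path)
        assert [(p.sample_id, p.tpm) for p in peaks] == [("liver", 3.1), ("brain", 0.0)]
        assert all(p.assay == CAGE for p in peaks)

    def test_minus_strand_preserved(self, tmp_path):
        path = write(tmp_path, "c2.tsv", [
            "#chrom\tstart\tend\tname\tscore\tstrand\ts1",
            "chr1\t500\t520\tp1\t0\t-\t1.5",
        ])
        assert read_cage_peaks(path)[0].strand == "-"

    def test_no_sample_columns_is_error(self, tmp_path):
        path = write(tmp_path, "c3.tsv", ["#chrom\tstart\tend\tname\tscore\tstrand"])
        with pytest.raises(PeakFileError, match="no sample"):
            read_cage_peaks(path)

    def test_unstranded_record_is_error(self, tmp_path):
        path = write(tmp_path, "c4.tsv", [
            "#chrom\tstart\tend\tname\tscore\tstrand\ts1",
            "chr1\t500\t520\tp1\t0\t.\t1.5",
        ])
        with pytest.raises(PeakFileError, match="stranded"):
            read_cage_peaks(path)

    def test_non_numeric_tpm_is_error(self, tmp_path):
        path = write(tmp_path, "c5.tsv", [
            "#chrom\tstart\tend\tname\tscore\tstrand\ts1",
            "chr1\t500\t520\tp1\t0\t+\tlow",
        ])
        with pytest.raises(PeakFileError, match="tpm"):
            read_cage_peaks(path)


class TestFdrFilter:
    def test_threshold_is_minus_log10_alpha(self):
        # q-values 10^-2, 10^-1, 10^-1.4 -> only 0.01 and ~0.04 pass 0.05
        peaks = [make_peak(start=i * 10, end=i * 10 + 5, q=v)
                 for i, v in enumerate([2.0, 1.0, 1.4])]
        kept = filter_by_fdr(peaks, 0.05)
        assert [p.neglog10_qvalue for p in kept] == [2.0, 1.4]
        for p in kept:
            assert 10 ** (-p.neglog10_qvalue) <= 0.05  # direct-comparison oracle

    def test_alpha_one_keeps_all_scored(self):
        peaks = [make_peak(q=0.0), make_peak(start=200, q=3.0)]
        assert filter_by_fdr(peaks, 1.0) == peaks

    def test_empty_input(self):
        assert filter_by_fdr([], 0.05) == []

    def test_unscored_dropped_unless_flagged(self):
        peaks = [make_peak(q=None)]
        assert filter_by_fdr(peaks, 0.05) == []
        assert filter_by_fdr(peaks, 0.05, keep_unscored=True) == peaks

    @given(st.lists(st.floats(0, 10, allow_nan=False), max_size=30),
           st.floats(0.001, 1), st.floats(0.001, 1))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_monotone(self, qs, a1, a2):
        peaks = [make_peak(start=i * 10, end=i * 10 + 5, q=q) for i, q in enumerate(qs)]
        once = filter_by_fdr(peaks, a1)
        assert filter_by_fdr(once, a1) == once  # idempotent
        lo, hi = min(a1, a2), max(a1, a2)
        assert len(filter_by_fdr(peaks, lo)) <= len(filter_by_fdr(peaks, hi))


class TestTpmFilter:
    def test_default_is_identity(self):
        peaks = [make_peak(assay=CAGE, strand="+", tpm=0.0)]
        assert filter_by_tpm(peaks, None) == peaks

    def test_strictly_greater_than_zero(self):
        peaks = [make_peak(assay=CAGE, strand="+", tpm=0.0),
                 make_peak(start=300, end=350, assay=CAGE, strand="+", tpm=0.2)]
        assert filter_by_tpm(peaks, 0) == [peaks[1]]

    def test_all_zero_gives_empty(self):
        peaks = [make_peak(assay=CAGE, strand="+", tpm=0.0)]
        assert filter_by_tpm(peaks, 0) == []

    def test_non_cage_is_error(self):
        with pytest.raises(ValueError, match="CAGE"):
            filter_by_tpm([make_peak()], 0)


class TestBuildIndex:
    sizes = {"chr1": 10_000, "chr2": 5_000}

    def test_bucket_sorted_by_start(self):
        peaks = [make_peak(start=s, end=s + 10) for s in (500, 100, 300)]
        index = build_index(peaks, self.sizes)
        bucket = index.bucket("s1", "chr1", "+")
        assert list(bucket.starts) == [100, 300, 500]

    def test_two_samples_two_entries(self):
        peaks = [make_peak(sample_id="a"), make_peak(sample_id="b")]
        index = build_index(peaks, self.sizes)
        assert index.sample_ids == ["a", "b"]

    def test_peak_beyond_chromosome_is_error(self):
        with pytest.raises(ValueError, match="chr2"):
            build_index([make_peak(chrom="chr2", start=4990, end=5050)], self.sizes)

    def test_unknown_chromosome_is_error(self):
        with pytest.raises(ValueError, match="chrX"):
            build_index([make_peak(chrom="chrX")], self.sizes)

    def test_full_scan_enumerates_input_multiset(self, rng):
        peaks = []
        for _ in range(60):
            start = int(rng.integers(0, 9000))
            peaks.append(make_peak(start=start, end=start + int(rng.integers(1, 500)),
                                   sample_id=f"s{rng.integers(3)}"))
        index = build_index(peaks, self.sizes)
        assert sorted(index.iter_peaks(), key=lambda p: (p.sample_id, p.start, p.end)) == \
            sorted(peaks, key=lambda p: (p.sample_id, p.start, p.end))

    def test_dir_round_trip(self, tmp_path, rng):
        peaks = [make_peak(start=int(s), end=int(s) + 20, sample_id="s1")
                 for s in rng.integers(0, 9000, size=10)]
        index = build_index(peaks, self.sizes)
        index.to_dir(tmp_path / "db")
        back = PeakIndex.from_dir(tmp_path / "db")
        assert sorted(back.iter_peaks(), key=lambda p: p.start) == \
            sorted(peaks, key=lambda p: p.start)
        assert back.chrom_sizes == self.sizes


def test_round_trip_through_source_dialects(tmp_path):
    """Writing a loaded peak set back to its dialect and re-reading is lossless."""
    np_path = write(tmp_path, "rt.narrowPeak", [NARROW, "chr2\t7\t30\t.\t0\t.\t1.5\t-1\t3.25\t10"])
    first = read_narrowpeak(np_path, "s1")
    out = tmp_path / "rt2.narrowPeak"
    with open(out, "wt") as fh:
        for p in first:
            q = -1 if p.neglog10_qvalue is None else p.neglog10_qvalue
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t.\t0\t.\t{p.signal_value:g}\t-1\t{q:g}\t-1\n")
    assert read_narrowpeak(out, "s1") == first


def test_read_chrom_sizes(tmp_path):
    path = write(tmp_path, "sizes.tsv", ["chr1\t1000", "chr2\t500"])
    assert read_chrom_sizes(path) == {"chr1": 1000, "chr2": 500}
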