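import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromswitch.core_io import (
    Fragment,
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    ParseError,
    SignalTrack,
    ValidationError,
    merge_intervals,
    read_fragments,
    read_genes,
    read_peaks,
    read_signal,
    write_fragments,
    write_genes,
    write_peaks,
)
from conftest import per_base_values, random_track


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end",
        [("chr1", -1, 10), ("chr1", 10, 10), ("chr1", 10, 5), ("", 0, 10)],
    )
    def test_rejects_invalid_coordinates(self, chrom, start, end):
        with pytest.raises(ValidationError):
            GenomicInterval(chrom, start, end)

    def test_book_ended_intervals_do_not_overlap(self):
        a = GenomicInterval("chr1", 0, 10)
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))


class TestReadPeaks:
    def write(self, tmp_path, lines):
        p = tmp_path / "peaks.narrowPeak"
        p.write_text("".join(line + "\n" for line in lines))
        return p

    def test_significance_filter_on_neglog10_p(self, tmp_path):
        """Only peaks passing the P < 1e-5 filter (column 8 above 5) survive."""
        path = self.write(
            tmp_path,
            [
                "chr1\t100\t300\tweak\t0\t.\t0\t4.3\t4.3\t50",
                "chr1\t400\t600\tstrong\t0\t.\t0\t5.3\t5.3\t50",
            ],
        )
        peaks = read_peaks(path, 1e-5)
        assert [p.name for p in peaks] == ["strong"]

    def test_summit_from_offset_and_midpoint(self, tmp_path):
        path = self.write(
            tmp_path,
            [
                "chr1\t100\t300\toff\t0\t.\t0\t9\t9\t50",
                "chr1\t100\t300\tmid\t0\t.\t0\t9\t9\t-1",
            ],
        )
        peaks = read_peaks(path, 1e-5)
        assert peaks[0].summit == 150
        assert peaks[1].summit == 200

    def test_bed6_summit_is_midpoint_and_unfiltered(self, tmp_path):
        path = self.write(tmp_path, ["chr1\t100\t300\tx\t7\t+"])
        (peak,) = read_peaks(path, 1e-5)
        assert peak.summit == 200 and peak.score == 7

    def test_malformed_line_names_line_number(self, tmp_path):
        path = self.write(tmp_path, ["chr1\t100\t300\tok\t0\t.\t0\t9\t9\t50", "chr1\tbad"])
        with pytest.raises(ParseError, match=":2"):
            read_peaks(path, 1e-5)

    def test_summit_offset_beyond_length_rejected(self, tmp_path):
        path = self.write(tmp_path, ["chr1\t100\t300\tx\t0\t.\t0\t9\t9\t250"])
        with pytest.raises(ValidationError):
            read_peaks(path, 1e-5)

    def test_output_sorted_by_position(self, tmp_path):
        path = self.write(
            tmp_path,
            ["chr2\t0\t10\tb\t0\t.\t0\t9\t9\t5", "chr1\t50\t60\ta\t0\t.\t0\t9\t9\t5"],
        )
        assert [p.name for p in read_peaks(path)] == ["a", "b"]


class TestSignalTrack:
    def test_length_weighted_mean(self):
        t = SignalTrack.from_records([("chr1", 0, 10, 2.0), ("chr1", 10, 20, 4.0)])
        assert t.mean("chr1", 0, 20) == 3.0

    def test_uncovered_query_is_zero(self):
        t = SignalTrack.from_records([("chr1", 0, 10, 2.0)])
        assert t.mean("chr1", 20, 30) == 0.0
        assert t.mean("chr2", 0, 10) == 0.0

    def test_partial_overlap_counts_uncovered_as_zero(self):
        t = SignalTrack.from_records([("chr1", 0, 10, 2.0)])
        assert t.mean("chr1", 5, 15) == pytest.approx(1.0)

    def test_overlapping_runs_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            SignalTrack.from_records([("chr1", 0, 10, 1.0), ("chr1", 5, 15, 2.0)])

    def test_negative_value_rejected(self):
        with pytest.raises(ValidationError):
            SignalTrack.from_records([("chr1", 0, 10, -1.0)])

    @pytest.mark.parametrize("seed", range(5))
    def test_interval_mean_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        track = random_track(rng, span=10_000)
        arr = per_base_values(track, "chr1", 10_000)
        for _ in range(50):
            s = int(rng.integers(0, 9_999))
            e = int(rng.integers(s + 1, 10_001))
            assert track.mean("chr1", s, e) == pytest.approx(arr[s:e].mean())

    def test_bedgraph_reader_accepts_unsorted_runs(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t10\t20\t4\nchr1\t0\t10\t2\n")
        assert read_signal(p).mean("chr1", 0, 20) == 3.0


class TestRoundTrips:
    def test_peaks_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        peaks = []
        for i in range(100):
            start = int(rng.integers(0, 10_000))
            end = start + int(rng.integers(10, 500))
            summit = int(rng.integers(start, end))
            from chromswitch.core_io import Peak

            peaks.append(
                Peak(GenomicInterval("chr1", start, end), summit,
                     float(rng.integers(5, 50)), f"p{i}")
            )
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
        path = tmp_path / "p.narrowPeak"
        write_peaks(peaks, path)
        assert read_peaks(path, None) == peaks

    def test_fragments_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        frs = [
            Fragment(GenomicInterval("chr1", s, s + int(rng.integers(20, 200))))
            for s in map(int, rng.integers(0, 100_000, size=100))
        ]
        path = tmp_path / "f.bed"
        write_fragments(frs, path)
        assert read_fragments(path) == frs

    def test_genes_round_trip(self, tmp_path):
        genes = [
            GeneModel("g1", GenomicInterval("chr1", 1000, 2000, "+")),
            GeneModel("g2", GenomicInterval("chr2", 5000, 9000, "-")),
        ]
        path = tmp_path / "genes.tsv"
        write_genes(genes, path)
        assert read_genes(path) == genes

    def test_minus_strand_tss_is_interval_end_minus_one(self):
        g = GeneModel("g", GenomicInterval("chr1", 1000, 2000, "-"))
        assert g.tss == 1999

    def test_unknown_strand_rejected(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("gene_id\tchrom\tstart\tend\tstrand\ng1\tchr1\t0\t10\t*\n")
        with pytest.raises(ParseError):
            read_genes(path)


class TestMergeIntervals:
    def test_overlapping_merged_book_ended_kept(self):
        merged = merge_intervals(
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 15)]
        )
        assert merged == [GenomicInterval("chr1", 0, 15)]
        kept = merge_intervals(
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)]
        )
        assert len(kept) == 2

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 50)),
            min_size=0,
            max_size=60,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_union_of_bases_preserved_and_idempotent(self, raw):
        ivs = [GenomicInterval("chr1", s, s + ln) for s, ln in raw]
        merged = merge_intervals(ivs)
        truth = set()
        for iv in ivs:
            truth.update(range(iv.start, iv.end))
        got = set()
        for iv in merged:
            assert not got & set(range(iv.start, iv.end))  # disjoint
            got.update(range(iv.start, iv.end))
        assert got == truth
        assert merge_intervals(merged) == merged

    def test_thousand_random_intervals_match_base_set_oracle(self):
        rng = np.random.default_rng(0)
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + int(ln))
            for s, ln in zip(rng.integers(0, 50_000, 1000), rng.integers(1, 300, 1000))
        ]
        merged = merge_intervals(ivs)
        n_bases = sum(iv.length for iv in merged)
        truth = set()
        for iv in ivs:
            truth.update(range(iv.start, iv.end))
        assert n_bases == len(truth)


class TestIntervalIndex:
    @pytest.mark.parametrize("seed", range(3))
    def test_overlap_queries_match_pairwise_scan(self, seed):
        rng = np.random.default_rng(seed)
        stored = [
            GenomicInterval("chr1", int(s), int(s) + int(ln))
            for s, ln in zip(rng.integers(0, 5000, 100), rng.integers(1, 100, 100))
        ]
        idx = IntervalIndex(stored)
        for _ in range(200):
            s = int(rng.integers(0, 5000))
            e = s + int(rng.integers(1, 100))
            q = GenomicInterval("chr1", s, e)
            assert idx.overlaps_interval(q) == any(q.overlaps(o) for o in stored)
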