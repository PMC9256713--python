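"""Seed-and-extend mapper, pair classification, depth statistics, SAM I/O."""
import math

import numpy as np
import pytest

import tdnakit as tk
from tdnakit.mapping import (EndAlignment, ReferenceIndex, average_target_depth,
                             classify_pair, coverage_calibrator, general_depth,
                             map_pair, map_read, read_sam, write_sam)
from tdnakit.refmodel import GenomicInterval, SequenceRecord, revcomp


def _record(n, seed, name="ref"):
    rng = np.random.default_rng(seed)
    return SequenceRecord(name, "".join("ACGT"[i] for i in rng.integers(0, 4, n)))


@pytest.fixture(scope="module")
def ref5k():
    return _record(5_000, 0)


@pytest.fixture(scope="module")
def index5k(ref5k):
    return ReferenceIndex([ref5k])


class TestMapRead:
    def test_exact_substring_maps_uniquely(self, ref5k, index5k):
        read = ref5k.seq[1234:1334]
        hits = map_read(read, index5k)
        assert len(hits) == 1
        h = hits[0]
        assert (h.ref_id, h.pos, h.strand, h.mismatches, h.unique) == \
            ("ref", 1234, "+", 0, True)

    def test_reverse_strand_hit(self, ref5k, index5k):
        read = revcomp(ref5k.seq[2000:2100])
        h = map_read(read, index5k)[0]
        assert (h.pos, h.strand) == (2000, "-")

    def test_two_substitutions_counted(self, ref5k, index5k):
        read = list(ref5k.seq[800:900])
        for i in (10, 60):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        h = map_read("".join(read), index5k, max_mismatch_frac=0.1)[0]
        assert h.mismatches == 2 and h.pos == 800

    def test_random_read_unmapped(self, index5k):
        rng = np.random.default_rng(99)
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        assert map_read(read, index5k) == []

    def test_duplicated_segment_flagged_non_unique(self):
        rng = np.random.default_rng(5)
        core = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        filler = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        ref = SequenceRecord("r", filler + core + filler[::-1] + core)
        hits = map_read(core[:100], ReferenceIndex([ref]))
        assert len(hits) == 2 and all(not h.unique for h in hits)

    def test_agrees_with_brute_force_on_fixture(self, ref5k, index5k):
        """Full-scan oracle: all positions, both strands, counted mismatches."""
        from numpy.lib.stride_tricks import sliding_window_view

        code = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            code[b] = i
        arr = code[np.frombuffer(ref5k.seq.encode(), dtype=np.uint8)]
        windows = sliding_window_view(arr, 100)

        def brute(read):
            best = 101
            hits = []
            for strand, s in (("+", read), ("-", revcomp(read))):
                r = code[np.frombuffer(s.encode(), dtype=np.uint8)]
                mm = (windows != r).sum(axis=1)
                m = int(mm.min())
                if m < best:
                    best, hits = m, [(int(p), strand) for p in np.nonzero(mm == m)[0]]
                elif m == best:
                    hits += [(int(p), strand) for p in np.nonzero(mm == m)[0]]
            return (best, sorted(hits)) if best <= 10 else (None, [])

        genome = SequenceRecord("g", ref5k.seq)
        cfg = tk.SimConfig(depth=2.0, seed=17, random_read_prob=0.0,
                           mut_rate=0.0, n_read_prob=0.0)
        reads = [s for p in tk.simulate_reads(genome, cfg)[:40]
                 for s in (p.seq1, p.seq2)]
        for read in reads:
            hits = map_read(read, index5k)
            exp_mm, exp_hits = brute(read)
            if exp_mm is None:
                assert hits == []
            else:
                assert sorted((h.pos, h.strand) for h in hits) == exp_hits
                assert all(h.mismatches == exp_mm for h in hits)


class TestClassifyPair:
    def _hit(self, ref, pos=0):
        return EndAlignment(ref, pos, "+", 100, 0, True, True)

    def test_host_plus_plasmid_is_chimeric(self):
        pa = classify_pair("p", [self._hit("chr1", 10)], [self._hit("plasmid", 5)],
                           {"plasmid"})
        assert pa.pair_class == "chimeric_host_plasmid"
        assert pa.host_end.ref_id == "chr1" and pa.plasmid_end.ref_id == "plasmid"

    def test_symmetric_in_end_order(self):
        h, p = [self._hit("chr1")], [self._hit("plasmid")]
        assert classify_pair("a", h, p, {"plasmid"}).pair_class == \
            classify_pair("b", p, h, {"plasmid"}).pair_class

    @pytest.mark.parametrize(
        "hits1, hits2, expected",
        [
            (["chr1"], ["chr1"], "both_host"),
            (["plasmid"], ["plasmid"], "both_plasmid"),
            ([], ["plasmid"], "one_unmapped"),
            ([], [], "both_unmapped"),
            (["chr1", "plasmid"], ["chr1"], "chimeric_host_plasmid"),
        ],
    )
    def test_pair_classes(self, hits1, hits2, expected):
        mk = lambda refs: [self._hit(r) for r in refs]
        assert classify_pair("p", mk(hits1), mk(hits2), {"plasmid"}).pair_class == expected


class TestDepthStats:
    def test_coverage_calibrator_reproduces_mapped_fractions(self):
        assert round(coverage_calibrator(53_545_140, 54_130_964), 3) == 0.989
        assert round(coverage_calibrator(54_233_374, 54_819_968), 3) == 0.989
        assert coverage_calibrator(7, 7) == 1.0

    def test_coverage_calibrator_input_validation(self):
        with pytest.raises(ValueError):
            coverage_calibrator(1, 0)
        with pytest.raises(ValueError):
            coverage_calibrator(5, 4)

    def test_general_depth(self):
        assert general_depth(15_000, 100, 100_000) == 30.0
        assert general_depth(0, 100, 5_000) == 0.0
        assert general_depth(30_000, 100, 100_000) == 2 * general_depth(15_000, 100, 100_000)

    def test_average_target_depth_arithmetic(self):
        iv = GenomicInterval("chr1", 1000, 1200)
        assert average_target_depth([], iv) == 0.0
        one = [EndAlignment("chr1", 1050, "+", 100, 0, True, True)]
        assert average_target_depth(one, iv) == 0.5

        class ZeroWidth:  # GenomicInterval itself cannot represent this
            ref_id, start, end = "chr1", 5, 5

        with pytest.raises(ValueError):
            average_target_depth(one, ZeroWidth())

    def test_average_target_depth_matches_poisson_coverage(self):
        genome = _record(30_000, 21, "chr1")
        cfg = tk.SimConfig(depth=30.0, seed=22, random_read_prob=0.0,
                           mut_rate=0.0, n_read_prob=0.0)
        index = ReferenceIndex([genome])
        ends = []
        for p in tk.simulate_reads(genome, cfg):
            for s in (p.seq1, p.seq2):
                hits = map_read(s, index)
                if hits:
                    ends.append(hits[0])
        iv = GenomicInterval("chr1", 10_000, 11_000)
        adt = average_target_depth(ends, iv)
        # ~ (len+read)/read * depth reads overlap; Poisson 3 sigma on that count
        n_reads = 1100 / 100 * 30
        assert abs(adt - 30.0) < 3 * 30.0 / math.sqrt(n_reads)


class TestSamRoundTrip:
    def test_round_trip_preserves_classes_and_placements(self, ref5k, tmp_path):
        plasmid = _record(2_000, 33, "plasmid")
        index = ReferenceIndex([ref5k, plasmid])
        pairs = [
            map_pair("p1", ref5k.seq[100:200], revcomp(ref5k.seq[400:500]),
                     index, {"plasmid"}),
            map_pair("p2", ref5k.seq[900:1000], plasmid.seq[300:400],
                     index, {"plasmid"}),
            map_pair("p3", ref5k.seq[2000:2100], "N" * 100, index, {"plasmid"}),
        ]
        path = tmp_path / "out.sam"
        write_sam(pairs, path, {"ref": 5000, "plasmid": 2000})
        back = read_sam(path, {"plasmid"})
        assert [p.pair_class for p in back] == [p.pair_class for p in pairs]
        for a, b in zip(back, pairs):
            assert (a.end1.ref_id, a.end1.pos, a.end1.strand) == \
                (b.end1.ref_id, b.end1.pos, b.end1.strand)

    def test_sam_one_based_pos_and_unmapped_flag(self, tmp_path):
        sam = tmp_path / "hand.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:1000\n"
            "q\t73\tref\t11\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
            "q\t133\t*\t0\t0\t*\t*\t0\t0\t" + "C" * 100 + "\t*\n"
        )
        pairs = read_sam(sam, set())
        assert len(pairs) == 1
        pa = pairs[0]
        assert pa.end1.pos == 10 and pa.end1.matched_len == 100  # SAM is 1-based
        assert not pa.end2.mapped
        assert pa.pair_class == "one_unmapped"

    def test_missing_mate_rejected(self, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:1000\n"
            "q\t73\tref\t11\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
        )
        with pytest.raises(ValueError, match="missing its mate"):
            read_sam(sam, set())
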