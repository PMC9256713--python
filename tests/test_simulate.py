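"""Event-genome construction and paired-end read simulation."""
import math

import numpy as np
import pytest

import tdnakit as tk
from tdnakit.mapping import ReferenceIndex, map_read
from tdnakit.refmodel import SequenceRecord, revcomp
from tdnakit.simulate import junction_ambiguous, mutate_genome, _insert_context


def _random_record(n, seed, name="g"):
    rng = np.random.default_rng(seed)
    return SequenceRecord(name, "".join("ACGT"[i] for i in rng.integers(0, 4, n)))


CLEAN = dict(err_start=0.0, err_end=0.0, random_read_prob=0.0,
             mut_rate=0.0, n_read_prob=0.0)


class TestBuildEventGenome:
    def test_zero_copies_leaves_genome_unchanged(self, refs60):
        hosts, pmap, _ = refs60
        genome, truth = tk.build_event_genome(hosts[0], pmap, 30_000, 0, "single", 36)
        assert genome.seq == hosts[0].seq
        assert truth.inserted_seq == "" and truth.deletion_len == 0

    def test_length_bookkeeping_two_copies(self, refs60, event60):
        hosts, pmap, _ = refs60
        genome, _ = event60
        tdna_len = pmap.tdna[1] - pmap.tdna[0]
        assert len(genome) == len(hosts[0]) - 36 + 2 * tdna_len

    def test_head_to_head_mirror_structure(self, refs60):
        hosts, pmap, _ = refs60
        _, truth = tk.build_event_genome(hosts[0], pmap, 30_000, 2, "head_to_head", 0)
        t = pmap.tdna_seq
        assert truth.inserted_seq[:50] == t[:50]
        # the 50 bp before the 3' host flank mirror the T-DNA start
        assert truth.inserted_seq[-50:] == revcomp(t[:50])

    def test_site_out_of_bounds_rejected(self, refs60):
        hosts, pmap, _ = refs60
        with pytest.raises(ValueError):
            tk.build_event_genome(hosts[0], pmap, len(hosts[0]) - 10, 1, "single", 36)

    def test_pick_clean_site_yields_unambiguous_junctions(self, refs60):
        hosts, pmap, _ = refs60
        rng = np.random.default_rng(0)
        site = tk.pick_clean_site(hosts[0], pmap, rng, deletion_len=36)
        insert = tk.simulate.make_insert(pmap, 2, "head_to_head")
        ctx = _insert_context(pmap, 2, "head_to_head")
        assert not junction_ambiguous(hosts[0], site, 36, insert, ctx)


class TestBuildCisgenicGenome:
    def test_native_fragment_insertion_adds_its_length(self):
        host = _random_record(30_000, 1)
        genome, truth = tk.build_cisgenic_genome(host, (5_000, 7_052), 20_000)
        assert len(genome) == len(host) + 2052
        assert truth.deletion_len == 0 and truth.copies == 1

    def test_empty_donor_rejected(self):
        host = _random_record(10_000, 1)
        with pytest.raises(ValueError, match="empty"):
            tk.build_cisgenic_genome(host, (5_000, 5_000), 8_000)

    def test_insertion_at_own_locus_rejected(self):
        host = _random_record(10_000, 1)
        with pytest.raises(ValueError, match="insert size"):
            tk.build_cisgenic_genome(host, (5_000, 6_000), 5_200)


class TestSimulateReads:
    def test_pair_count_formula(self):
        g = _random_record(100_000, 2)
        pairs = tk.simulate_reads(g, tk.SimConfig(depth=30.0, seed=1, **CLEAN))
        assert len(pairs) == 15_000

    def test_same_seed_is_byte_identical(self, tmp_path):
        g = _random_record(20_000, 3)
        cfg = tk.SimConfig(depth=5.0, seed=42)
        a, b = tk.simulate_reads(g, cfg), tk.simulate_reads(g, cfg)
        assert a == b
        tk.write_fastq_pair(a, tmp_path / "a1.fq", tmp_path / "a2.fq")
        tk.write_fastq_pair(b, tmp_path / "b1.fq", tmp_path / "b2.fq")
        assert (tmp_path / "a1.fq").read_bytes() == (tmp_path / "b1.fq").read_bytes()
        assert (tmp_path / "a2.fq").read_bytes() == (tmp_path / "b2.fq").read_bytes()

    def test_noise_free_reads_are_exact_substrings(self):
        g = _random_record(15_000, 4)
        pairs = tk.simulate_reads(g, tk.SimConfig(depth=3.0, seed=9, **CLEAN))
        fwd = g.seq
        for p in pairs:
            assert p.seq1 in fwd
            assert revcomp(p.seq2) in fwd

    def test_observed_error_rate_matches_ramp_mean(self):
        # binomial oracle: the linear 0.1%->4% ramp averages 2.05% per base
        g = _random_record(20_000, 5)
        cfg = tk.SimConfig(depth=10.0, seed=6, random_read_prob=0.0,
                           mut_rate=0.0, n_read_prob=0.0)
        pairs = tk.simulate_reads(g, cfg)
        index = ReferenceIndex([g])
        n_bases = mismatches = 0
        for p in pairs[:600]:
            for s in (p.seq1, p.seq2):
                hits = map_read(s, index, max_mismatch_frac=0.2)
                if hits:
                    mismatches += hits[0].mismatches
                    n_bases += 100
        rate = mismatches / n_bases
        expected = (0.001 + 0.04) / 2
        sigma = math.sqrt(expected * (1 - expected) / n_bases)
        assert abs(rate - expected) < 3 * sigma

    def test_insert_size_mean_within_tolerance(self):
        g = _random_record(30_000, 7)
        cfg = tk.SimConfig(depth=8.0, seed=8, **CLEAN)
        pairs = tk.simulate_reads(g, cfg)
        # recover insert length from the fragment the two ends delimit
        total = n = 0
        for p in pairs[:500]:
            i1 = g.seq.find(p.seq1)
            i2 = g.seq.find(revcomp(p.seq2))
            if i1 >= 0 and i2 >= 0 and i2 >= i1:
                total += i2 + 100 - i1
                n += 1
        mean = total / n
        assert abs(mean - 500.0) < 3 * 10.0 / math.sqrt(n)

    def test_max_one_n_per_read(self):
        g = _random_record(15_000, 8)
        pairs = tk.simulate_reads(g, tk.SimConfig(depth=5.0, seed=3, n_read_prob=0.5))
        assert max(p.seq1.count("N") for p in pairs) <= 1
        assert max(p.seq2.count("N") for p in pairs) <= 1

    def test_genome_too_short_rejected(self):
        g = _random_record(500, 9)
        with pytest.raises(ValueError, match="too short"):
            tk.simulate_reads(g, tk.SimConfig(depth=5.0, seed=1))


class TestMutateGenome:
    def test_zero_rate_is_identity(self):
        g = _random_record(5_000, 10)
        cfg = tk.SimConfig(mut_rate=0.0)
        assert mutate_genome(g.seq, cfg, np.random.default_rng(0)) == g.seq

    def test_mutation_count_scales_with_rate(self):
        g = _random_record(100_000, 11)
        cfg = tk.SimConfig(mut_rate=0.001, indel_frac=0.0)
        out = mutate_genome(g.seq, cfg, np.random.default_rng(1))
        diffs = sum(a != b for a, b in zip(g.seq, out))
        assert 60 <= diffs <= 145  # Poisson(100) within ~4 sigma


class TestSpikeReads:
    def _pairs(self, n, prefix):
        return [tk.ReadPair(f"{prefix}:{i}", "A" * 100, "I" * 100, "C" * 100, "I" * 100)
                for i in range(n)]

    def test_merge_counts_and_determinism(self):
        bg, sp = self._pairs(100, "bg"), self._pairs(10, "sp")
        merged = tk.spike_reads(bg, sp, seed=5)
        assert len(merged) == 110
        assert merged == tk.spike_reads(bg, sp, seed=5)
        assert {p.pair_id for p in merged} == {p.pair_id for p in bg + sp}

    def test_empty_spike_preserves_content(self):
        bg = self._pairs(50, "bg")
        merged = tk.spike_reads(bg, [], seed=1)
        assert sorted(p.pair_id for p in merged) == sorted(p.pair_id for p in bg)

    def test_id_collision_rejected(self):
        bg = self._pairs(5, "x")
        with pytest.raises(ValueError, match="collision"):
            tk.spike_reads(bg, self._pairs(2, "x"), seed=0)


def test_fastq_round_trip(tmp_path):
    g = _random_record(10_000, 12)
    pairs = tk.simulate_reads(g, tk.SimConfig(depth=2.0, seed=13))
    tk.write_fastq_pair(pairs, tmp_path / "r1.fq", tmp_path / "r2.fq")
    back = tk.read_fastq_pair(tmp_path / "r1.fq", tmp_path / "r2.fq")
    assert [(p.pair_id, p.seq1, p.seq2) for p in back] == \
        [(p.pair_id, p.seq1, p.seq2) for p in pairs]
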