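"""Greedy assembly, split alignment of junction contigs, arrangement calls."""
import numpy as np
import pytest

from tdnakit.assembly import (IntegrationCall, SplitAligner, assemble_contigs,
                              call_integration, call_junction, infer_arrangement,
                              polish_contigs)
from tdnakit.refmodel import (PlasmidElement, PlasmidMap, SequenceRecord,
                              revcomp)


def _seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# Greedy overlap assembly
# ---------------------------------------------------------------------------

class TestAssembleContigs:
    def test_single_read_returned_verbatim(self):
        r = _seq(100, 0)
        assert assemble_contigs([r]) == [r]

    def test_tiling_reads_reconstruct_template(self):
        template = _seq(478, 1)
        reads = [template[i : i + 100] for i in range(0, 378, 20)] + [template[-100:]]
        contigs = assemble_contigs(reads)
        assert contigs == [template]

    def test_mixed_orientations_still_reconstruct(self):
        template = _seq(478, 2)
        reads = [template[i : i + 100] for i in range(0, 378, 20)] + [template[-100:]]
        reads = [r if i % 2 else revcomp(r) for i, r in enumerate(reads)]
        contigs = assemble_contigs(reads)
        assert len(contigs) == 1
        assert contigs[0] in (template, revcomp(template))

    def test_disjoint_reads_stay_separate(self):
        a, b = _seq(100, 3), _seq(100, 4)
        assert sorted(assemble_contigs([a, b])) == sorted([a, b])

    def test_deterministic(self):
        template = _seq(400, 5)
        reads = [template[i : i + 100] for i in range(0, 300, 30)]
        assert assemble_contigs(reads) == assemble_contigs(list(reads))

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exhaustive_merge_oracle(self, seed):
        """Brute-force oracle: same greedy policy, overlaps found by direct
        string comparison over every candidate length and orientation."""
        rng = np.random.default_rng(seed)
        template = _seq(300, 100 + seed)
        n = int(rng.integers(2, 9))
        reads = []
        for _ in range(n):
            start = int(rng.integers(0, 200))
            r = template[start : start + 100]
            reads.append(r if rng.random() < 0.5 else revcomp(r))

        def oracle_best(a, b, min_overlap=30):
            best = None
            for bb in (b, revcomp(b)):
                la, lb = len(a), len(bb)
                for s in range(-lb + 1, la):
                    lo, hi = max(0, s), min(la, s + lb)
                    o = hi - lo
                    if o < min_overlap:
                        continue
                    if a[lo:hi] != bb[lo - s : hi - s]:
                        continue  # error-free reads: exact agreement only
                    if s >= 0 and s + lb <= la:
                        merged = a
                    elif s <= 0 and -s + la <= lb:
                        merged = bb
                    elif s > 0:
                        merged = a + bb[o:]
                    else:
                        merged = bb + a[o:]
                    cand = (o, merged)
                    if best is None or cand[0] > best[0] or \
                            (cand[0] == best[0] and cand[1] < best[1]):
                        best = cand
            return best

        def oracle_assemble(seqs):
            active = list(seqs)
            while True:
                top = None
                for i in range(len(active)):
                    for j in range(i + 1, len(active)):
                        cand = oracle_best(active[i], active[j])
                        if cand and (top is None or cand[0] > top[0][0]
                                     or (cand[0] == top[0][0] and cand[1] < top[0][1])):
                            top = (cand, i, j)
                if top is None:
                    return sorted(active, key=lambda c: (-len(c), c))
                (o, merged), i, j = top
                active = [s for k, s in enumerate(active) if k not in (i, j)]
                active.append(merged)

        got = assemble_contigs(reads, min_overlap=30, min_identity=1.0)
        expected = oracle_assemble(reads)
        canon = lambda cs: sorted(min(c, revcomp(c)) for c in cs)
        assert canon(got) == canon(expected)


def test_polish_repairs_sporadic_errors():
    template = _seq(400, 9)
    reads = [template[i : i + 100] for i in range(0, 300, 10)]
    draft = list(template)
    for pos in (50, 210, 340):
        draft[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[draft[pos]]
    polished = polish_contigs(["".join(draft)], reads)[0]
    assert polished == template


# ---------------------------------------------------------------------------
# Junction calling
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy_refs():
    host = SequenceRecord("chr1", _seq(20_000, 10))
    plasmid_seq = _seq(10_000, 11)
    plasmid = SequenceRecord("plasmid", plasmid_seq, circular=True)
    pmap = PlasmidMap(
        plasmid, (1_000, 9_000),
        [PlasmidElement("RB", 1_000, 1_025),
         PlasmidElement("GeneA", 1_100, 3_000),
         PlasmidElement("LB", 8_975, 9_000)],
    )
    # pick junction coordinates without micro-homology, so the breakpoint
    # representation (and therefore the expected value) is unique
    h, p = host.seq, plasmid_seq
    comp = lambda b: revcomp(b)

    def clean(c):
        r = c + 36
        return (h[c] != p[1_000] and h[c - 1] != p[999]          # vs T-DNA start
                and h[r - 1] != p[8_999] and h[r] != p[9_000]    # vs T-DNA end
                and h[c] != comp(p[8_999]) and h[c - 1] != comp(p[9_000]))

    cut = next(c for c in range(5_000, 5_200) if clean(c))
    return host, pmap, SplitAligner([host], pmap), cut, cut + 36


class TestCallJunction:
    def test_constructed_left_junction_breakpoint_exact(self, toy_refs):
        host, pmap, aligner, cut, _ = toy_refs
        contig = host.seq[cut - 200 : cut] + pmap.plasmid.seq[1_000:1_200]
        j = call_junction(contig, aligner)
        assert j is not None and j.side == "left"
        assert j.breakpoint_host == cut
        assert j.junction_element == "RB" and j.plasmid_strand == "+"
        assert j.tdna_terminus == "5p"

    def test_pure_host_contig_yields_none(self, toy_refs):
        host, _, aligner, _, _ = toy_refs
        assert call_junction(host.seq[3_000:3_400], aligner) is None

    def test_pure_plasmid_contig_yields_none(self, toy_refs):
        _, pmap, aligner, _, _ = toy_refs
        assert call_junction(pmap.plasmid.seq[2_000:2_400], aligner) is None

    def test_reverse_complement_plasmid_part_detected(self, toy_refs):
        host, pmap, aligner, cut, _ = toy_refs
        contig = host.seq[cut - 200 : cut] + revcomp(pmap.plasmid.seq[8_800:9_000])
        j = call_junction(contig, aligner)
        assert j is not None and j.side == "left"
        assert j.breakpoint_host == cut
        assert j.plasmid_strand == "-" and j.junction_element == "LB"
        assert j.tdna_terminus == "3p"

    def test_right_junction_and_deletion_recovered(self, toy_refs):
        host, pmap, aligner, cut, resume = toy_refs
        t = pmap.tdna_seq
        left = host.seq[cut - 200 : cut] + t[:200]
        right = t[-200:] + host.seq[resume : resume + 200]
        jl, jr = call_junction(left, aligner), call_junction(right, aligner)
        assert jl.side == "left" and jr.side == "right"
        call = call_integration([jl, jr], copy_number=1.02)
        assert call.locus == cut            # 1-based last retained host base
        assert call.deletion_len == 36
        assert call.arrangement == "single"

    def test_single_flank_reports_deletion_missing(self, toy_refs):
        host, pmap, aligner, cut, _ = toy_refs
        j = call_junction(host.seq[cut - 200 : cut] + pmap.tdna_seq[:200], aligner)
        call = call_integration([j], copy_number=2.0)
        assert call.deletion_len is None
        assert call.arrangement == "unresolved"

    def test_conflicting_chromosomes_rejected(self, toy_refs):
        host, pmap, aligner, cut, _ = toy_refs
        j = call_junction(host.seq[cut - 200 : cut] + pmap.tdna_seq[:200], aligner)
        import dataclasses
        j2 = dataclasses.replace(j, host_ref="chr2")
        with pytest.raises(ValueError, match="conflicting chromosomes"):
            call_integration([j, j2])


class TestInferArrangement:
    def _call(self, t5, t3, s5, s3, e5="X", e3="X"):
        return IntegrationCall("chr1", 100, 0, e5, e3, s5, s3, t5, t3,
                               "unresolved", None)

    def test_head_to_head_same_terminus_opposite_strands(self):
        call = self._call("5p", "5p", "+", "-")
        assert infer_arrangement(call, 2.0) == "head_to_head"

    def test_single_copy_opposite_termini(self):
        call = self._call("5p", "3p", "+", "+", "RB-side", "LB-side")
        assert infer_arrangement(call, 1.0) == "single"

    def test_tandem_two_copies_opposite_termini_same_strand(self):
        call = self._call("5p", "3p", "+", "+")
        assert infer_arrangement(call, 2.1) == "tandem_head_to_tail"

    def test_inconsistent_evidence_unresolved(self):
        assert infer_arrangement(self._call("5p", "5p", "+", "+"), 2.0) == "unresolved"
        assert infer_arrangement(self._call("5p", "3p", "+", "+"), None) == "unresolved"
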