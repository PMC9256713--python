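"""Junction contig assembly, integration calling, arrangement inference.

Candidate reads (cluster members plus their mates) are assembled by a
deterministic greedy overlap-layout: the pair of sequences with the longest
suffix-prefix overlap (either orientation, identity >= 0.95) is merged
repeatedly until no overlap of at least ``min_overlap`` remains.  Contigs
are then split-aligned — a prefix to the host and the complement to the
plasmid (either strand), or vice versa — to locate the breakpoint, the host
deletion, and the plasmid element present at each junction.  The overall
event structure (single copy, tandem head-to-tail, head-to-head) is composed
from the two flank calls plus the depth-based copy number, because a
multi-copy insert cannot be walked end-to-end with short reads.

Breakpoint convention: the reported locus is the 1-based coordinate of the
last retained host base on the 5' flank; the deletion length is the gap
between the 5' and 3' host breakpoints.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mapping import ReferenceIndex
from .refmodel import PlasmidMap, SequenceRecord, revcomp

__all__ = [
    "IntegrationCall",
    "JunctionContig",
    "SplitAligner",
    "assemble_contigs",
    "call_integration",
    "call_junction",
    "format_report",
    "infer_arrangement",
    "polish_contigs",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Greedy overlap assembly
# ---------------------------------------------------------------------------

_OV_K = 15  # candidate-overlap seed size; overlaps shorter than this are
            # still found because min_overlap >= _OV_K in all defaults


class _Seq:
    """Active assembly sequence with cached arrays and seed positions."""

    __slots__ = ("s", "arr", "rc", "rc_arr", "kmers", "rc_kmers")

    def __init__(self, s: str):
        self.s = s
        self.arr = _encode(s)
        self.rc = revcomp(s)
        self.rc_arr = _encode(self.rc)
        self.kmers = self._index(s)
        self.rc_kmers = self._index(self.rc)

    @staticmethod
    def _index(s: str) -> dict[bytes, list[int]]:
        data = s.encode()
        d: dict[bytes, list[int]] = {}
        for p in range(len(data) - _OV_K + 1):
            d.setdefault(data[p : p + _OV_K], []).append(p)
        return d


def _pair_best(a: _Seq, b: _Seq, min_overlap: int, min_identity: float):
    """Best merge of a with b (trying b in both orientations).

    Returns ``(score, merged_seq)`` or ``None``.  Score is the overlap
    length (the contained sequence's length for containments).  Ties prefer
    the lexicographically smallest merged sequence, making assembly
    deterministic.
    """
    best: tuple[int, str] | None = None
    la = len(a.s)

    for b_s, b_arr, b_kmers in ((b.s, b.arr, b.kmers), (b.rc, b.rc_arr, b.rc_kmers)):
        lb = len(b_s)
        shifts: set[int] = set()
        # iterate the smaller seed table, probe the larger
        if len(b_kmers) <= len(a.kmers):
            for kmer, pbs in b_kmers.items():
                pas = a.kmers.get(kmer)
                if pas:
                    for pa in pas:
                        for pb in pbs:
                            shifts.add(pa - pb)
        else:
            for kmer, pas in a.kmers.items():
                pbs = b_kmers.get(kmer)
                if pbs:
                    for pa in pas:
                        for pb in pbs:
                            shifts.add(pa - pb)
        for s in shifts:
            if s >= 0 and s + lb <= la:          # b contained in a
                o, ax, ay, bx, by = lb, s, s + lb, 0, lb
                merged = a.s
            elif s <= 0 and -s + la <= lb:       # a contained in b
                o, ax, ay, bx, by = la, 0, la, -s, -s + la
                merged = b_s
            elif s > 0:                          # suffix(a) / prefix(b)
                o = la - s
                if o < min_overlap:
                    continue
                ax, ay, bx, by = s, la, 0, o
                merged = a.s + b_s[o:]
            else:                                # suffix(b) / prefix(a)
                o = lb + s
                if o < min_overlap:
                    continue
                ax, ay, bx, by = 0, o, -s, lb
                merged = b_s + a.s[o:]
            mm = int(np.count_nonzero(a.arr[ax:ay] != b_arr[bx:by]))
            if o - mm < min_identity * o:
                continue
            cand = (o, merged)
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
    return best


def assemble_contigs(
    reads: Sequence[str],
    min_overlap: int = 30,
    min_identity: float = 0.95,
) -> list[str]:
    """Greedy overlap-layout assembly of a read set into contigs.

    Repeatedly merges the globally best-overlapping pair (both orientations
    considered; contained sequences are absorbed) until no merge with an
    overlap of at least ``min_overlap`` at ``min_identity`` remains.
    Returns contigs longest-first.
    """
    if min_overlap < _OV_K:
        raise ValueError(f"min_overlap must be >= {_OV_K}")
    active: dict[int, _Seq] = {i: _Seq(r.upper()) for i, r in enumerate(reads)}
    next_id = len(reads)
    cache: dict[tuple[int, int], tuple[int, str] | None] = {}
    ids = sorted(active)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            cache[(ids[i], ids[j])] = _pair_best(
                active[ids[i]], active[ids[j]], min_overlap, min_identity
            )
    while True:
        best_key, best_val = None, None
        for key in sorted(cache):
            val = cache[key]
            if val is None:
                continue
            if (best_val is None or val[0] > best_val[0]
                    or (val[0] == best_val[0] and val[1] < best_val[1])):
                best_key, best_val = key, val
        if best_val is None:
            break
        i, j = best_key
        merged = _Seq(best_val[1])
        del active[i], active[j]
        cache = {k: v for k, v in cache.items() if i not in k and j not in k}
        for other_id, other in active.items():
            key = (other_id, next_id) if other_id < next_id else (next_id, other_id)
            cache[key] = _pair_best(other, merged, min_overlap, min_identity)
        active[next_id] = merged
        next_id += 1
    return sorted((s.s for s in active.values()), key=lambda c: (-len(c), c))


def polish_contigs(contigs: Sequence[str], reads: Sequence[str], k: int = 15) -> list[str]:
    """Per-column majority polish of contigs using the original reads.

    Reads are anchored to each contig by shared k-mers (both orientations,
    best shift by vote) and contribute base counts; each column takes the
    majority base, with the draft base breaking ties.  Removes the sporadic
    sequencing errors that the first-come greedy merge bakes into a draft.
    """
    out = []
    for contig in contigs:
        carr = _encode(contig)
        n = len(contig)
        counts = np.zeros((5, n), dtype=np.int32)
        cindex: dict[bytes, list[int]] = {}
        data = contig.encode()
        for p in range(n - k + 1):
            cindex.setdefault(data[p : p + k], []).append(p)
        for read in reads:
            placed = None
            for seq in (read, revcomp(read)):
                rdata = seq.encode()
                votes: dict[int, int] = {}
                for off in range(0, max(1, len(seq) - k + 1), 7):
                    for p in cindex.get(rdata[off : off + k], ()):
                        shift = p - off
                        votes[shift] = votes.get(shift, 0) + 1
                if votes:
                    shift, v = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
                    if placed is None or v > placed[2]:
                        placed = (seq, shift, v)
            if placed is None:
                continue
            seq, shift, _ = placed
            rarr = _encode(seq)
            lo, hi = max(0, shift), min(n, shift + len(seq))
            if hi <= lo:
                continue
            window = rarr[lo - shift : hi - shift]
            mm = int(np.count_nonzero(window != carr[lo:hi]))
            if mm > 0.3 * (hi - lo):
                continue
            cols = np.arange(lo, hi)
            counts[window, cols] += 1
        counts[4, :] = 0  # N never wins a column
        best = counts.argmax(axis=0)
        maxc = counts.max(axis=0)
        draft_support = counts[carr, np.arange(n)]
        keep_draft = (maxc == 0) | (draft_support == maxc)
        final = np.where(keep_draft, carr, best).astype(np.uint8)
        out.append(_encode_inv(final))
    return out


_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _encode_inv(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Split alignment of contigs across a junction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionContig:
    """A contig spanning one host-plasmid junction."""

    seq: str                      # orientation with the host part on its forward strand
    side: str                     # "left": host prefix; "right": host suffix
    host_ref: str
    host_start: int
    host_end: int                 # half-open host interval covered by the contig
    contig_host: tuple[int, int]  # contig offsets of the host segment
    plasmid_interval: tuple[int, int]
    plasmid_strand: str
    contig_plasmid: tuple[int, int]
    breakpoint_host: int          # 0-based: exclusive end (left) / first retained (right)
    junction_element: str
    tdna_terminus: str            # "5p" or "3p": which T-DNA end abuts the host


@dataclass
class IntegrationCall:
    chrom: str
    locus: int                    # 1-based last retained 5' host base
    deletion_len: int | None
    element_5p: str | None
    element_3p: str | None
    strand_5p: str | None
    strand_3p: str | None
    terminus_5p: str | None
    terminus_3p: str | None
    arrangement: str
    copy_number: float | None
    contigs: list[JunctionContig] = field(default_factory=list)


class SplitAligner:
    """Diagonal search tables for split-aligning contigs to host + plasmid."""

    K = 15

    def __init__(self, hosts: Sequence[SequenceRecord], plasmid_map: PlasmidMap):
        self.hosts = {r.id: _encode(r.seq) for r in hosts}
        self.plasmid_map = plasmid_map
        p = plasmid_map.plasmid.seq
        self.plen = len(p)
        self.plasmid = {"+": _encode(p + p), "-": _encode(revcomp(p) + revcomp(p))}
        self.host_idx = {rid: self._index(rec) for rid, rec in
                         ((r.id, r.seq) for r in hosts)}
        self.plasmid_idx = {
            "+": self._index(p + p[: self.K - 1], circular_len=self.plen),
            "-": self._index(revcomp(p) + revcomp(p)[: self.K - 1], circular_len=self.plen),
        }

    @classmethod
    def _index(cls, seq: str, circular_len: int | None = None) -> dict[bytes, list[int]]:
        data = seq.encode()
        n = circular_len if circular_len is not None else len(data) - cls.K + 1
        d: dict[bytes, list[int]] = {}
        for p in range(n):
            d.setdefault(data[p : p + cls.K], []).append(p)
        return d

    def diagonals(self, query: bytes, idx: dict[bytes, list[int]]) -> dict[int, int]:
        """Map diagonal -> seed votes for query against one reference table."""
        votes: dict[int, int] = {}
        lq = len(query)
        offsets = list(range(0, lq - self.K + 1, 5))
        if offsets and offsets[-1] != lq - self.K:
            offsets.append(lq - self.K)
        for off in offsets:
            for p in idx.get(query[off : off + self.K], ()):
                d = p - off
                votes[d] = votes.get(d, 0) + 1
        return votes


def _anchored_extents(qarr: np.ndarray, rarr: np.ndarray, diag: int,
                      max_err: float) -> tuple[int, int, np.ndarray | None]:
    """(max prefix len, max suffix len, per-position match vector) on a diagonal.

    The match vector covers the whole query; positions where the diagonal
    runs off the reference count as mismatches.
    """
    lq, lr = len(qarr), len(rarr)
    match = np.zeros(lq, dtype=bool)
    q_lo, q_hi = max(0, -diag), min(lq, lr - diag)
    if q_hi <= q_lo:
        return 0, 0, None
    seg_q = qarr[q_lo:q_hi]
    seg_r = rarr[q_lo + diag : q_hi + diag]
    match[q_lo:q_hi] = (seg_q == seg_r) & (seg_q != 4)
    mism = ~match
    cum = np.concatenate([[0], np.cumsum(mism)])
    lens = np.arange(1, lq + 1)
    pref_ok = cum[1:] <= max_err * lens
    prefix = int(lens[pref_ok].max()) if pref_ok.any() else 0
    suf_mm = cum[lq] - cum[lq - lens]
    suf_ok = suf_mm <= max_err * lens
    suffix = int(lens[suf_ok].max()) if suf_ok.any() else 0
    # trim ragged tails: the cumulative criterion lets an extent coast past
    # the true boundary on chance matches; require the local tail window to
    # still look aligned
    prefix = _trim_prefix(match, prefix)
    suffix = _trim_suffix(match, suffix)
    return prefix, suffix, match


_TRIM_W, _TRIM_MIN = 6, 5
_MIN_SEGMENT = 20  # smallest clean diagonal segment worth chaining


def _trim_prefix(match: np.ndarray, a: int) -> int:
    # the extent's last base must match and its local window must align
    while a > 0:
        lo = max(0, a - _TRIM_W)
        if match[a - 1] and match[lo:a].sum() >= min(_TRIM_MIN, a - lo):
            break
        a -= 1
    return a


def _trim_suffix(match: np.ndarray, s: int) -> int:
    lq = len(match)
    while s > 0:
        hi = min(lq, lq - s + _TRIM_W)
        if match[lq - s] and match[lq - s : hi].sum() >= min(_TRIM_MIN, hi - (lq - s)):
            break
        s -= 1
    return s


def call_junction(
    contig: str,
    aligner: SplitAligner,
    min_overlap: int = 30,
    min_identity: float = 0.95,
    max_gap: int = 25,
) -> JunctionContig | None:
    """Split a contig into a host part and a plasmid part across a junction.

    Tries both contig orientations and both split layouts (host prefix +
    plasmid suffix, or plasmid prefix + host suffix); each part must reach
    ``min_overlap`` bases at ``min_identity``, and the parts must abut on
    the contig within ``max_gap`` bases.  The exact split point maximises
    total matched bases along the two chosen diagonals, which pins the
    breakpoint to the base when the junction is not micro-homologous.
    Returns ``None`` for pure-host or pure-plasmid contigs.
    """
    max_err = 1.0 - min_identity
    pm = aligner.plasmid_map
    plen = aligner.plen
    best = None  # (score, record)

    for orient_seq in (contig, revcomp(contig)):
        qarr = _encode(orient_seq)
        qbytes = orient_seq.encode()
        lq = len(orient_seq)
        if lq < 2 * min_overlap:
            continue

        host_cover = np.zeros(lq, dtype=bool)
        host_hits = []  # (prefix, suffix, match, ref, diag)
        for rid, idx in aligner.host_idx.items():
            for diag in aligner.diagonals(qbytes, idx):
                pre, suf, match = _anchored_extents(qarr, aligner.hosts[rid], diag, max_err)
                if match is None:
                    continue
                host_cover |= match
                s_, e_ = _clean_region(match)
                # interior segments (zero anchored extent) still join chains
                if pre or suf or e_ - s_ >= _MIN_SEGMENT:
                    host_hits.append((pre, suf, match, rid, diag))
        # a contig one reference explains end to end is not a junction:
        # pure host flank, pure insert, or a host-homologous element
        if any(h[0] >= lq or h[1] >= lq for h in host_hits):
            continue
        plas_cover = np.zeros(lq, dtype=bool)
        plas_hits = []  # (prefix, suffix, match, strand, diag)
        for strand, idx in aligner.plasmid_idx.items():
            # circular reference: wrap diagonals so the query never starts
            # before the (doubled) plasmid array
            diags = {d % plen for d in aligner.diagonals(qbytes, idx)}
            for diag in diags:
                pre, suf, match = _anchored_extents(qarr, aligner.plasmid[strand], diag, max_err)
                if match is None:
                    continue
                plas_cover |= match
                s_, e_ = _clean_region(match)
                if pre or suf or e_ - s_ >= _MIN_SEGMENT:
                    plas_hits.append((pre, suf, match, strand, diag))
        if any(p[0] >= lq or p[1] >= lq for p in plas_hits):
            continue
        if not host_hits or not plas_hits:
            continue
        # the two references must jointly explain the contig (an indel in a
        # flank splits one side over two diagonals; the union still covers)
        explained = int((host_cover | plas_cover).sum())
        if explained < lq - max_gap:
            continue

        # each flank side is a chain of clean diagonal regions anchored at a
        # contig end (an indel inside a flank splits its diagonal in two);
        # the split point is refined on the chain's last diagonal — the one
        # whose clean match region abuts the junction
        lo, hi = min_overlap, lq - min_overlap

        # layout A: host prefix + plasmid suffix ("left" flank)
        reach, hd = _chain_forward(host_hits, lq, max_gap)
        pstart, pd = _chain_backward(plas_hits, lq, max_gap)
        if hd is not None and pd is not None \
                and reach >= min_overlap and lq - pstart >= min_overlap:
            scores = np.cumsum(hd[2]) + (int(pd[2].sum()) - np.cumsum(pd[2]))
            window = scores[lo - 1 : hi]  # scores[x-1] = score of split x
            # tie-break toward the largest split (host part maximal), but
            # never past the clean reach of the split diagonal
            x = lo + (len(window) - 1 - int(np.argmax(window[::-1])))
            x = min(x, reach)
            if lo <= x <= lq - min_overlap:
                cand_score = int(scores[x - 1])
                rec = _make_left(orient_seq, x, hd, pd, pm, plen)
                if rec is not None and (best is None or cand_score > best[0]):
                    best = (cand_score, rec)

        # layout B: plasmid prefix + host suffix ("right" flank)
        hstart, hd = _chain_backward(host_hits, lq, max_gap)
        preach, pd = _chain_forward(plas_hits, lq, max_gap)
        if hd is not None and pd is not None \
                and lq - hstart >= min_overlap and preach >= min_overlap:
            hcum = np.cumsum(hd[2])
            scores = np.cumsum(pd[2]) + (int(hcum[-1]) - hcum)
            window = scores[lo - 1 : hi]
            # tie-break toward the smallest split (host part maximal), but
            # never before the clean start of the split diagonal
            x = lo + int(np.argmax(window))
            x = max(x, hstart)
            if lo <= x <= hi:
                cand_score = int(scores[x - 1])
                rec = _make_right(orient_seq, x, hd, pd, pm, plen)
                if rec is not None and (best is None or cand_score > best[0]):
                    best = (cand_score, rec)

    return best[1] if best else None


def _clean_region(match: np.ndarray) -> tuple[int, int]:
    """Longest well-aligned half-open region of a diagonal's match vector.

    A windowed match density separates the diagonal's true segment from the
    ~25% background of chance matches elsewhere; boundaries are tightened to
    exact-matching bases.
    """
    w, thr = 11, 8
    conv = np.convolve(match.astype(np.int32), np.ones(w, dtype=np.int32), mode="same")
    ok = conv >= thr
    if not ok.any():
        return 0, 0
    bounds = np.flatnonzero(np.diff(np.concatenate([[0], ok.astype(np.int8), [0]])))
    runs = list(zip(bounds[::2], bounds[1::2]))
    s, e = max(runs, key=lambda r: r[1] - r[0])
    s, e = int(s), int(e)
    lq = len(match)
    # the windowed density erodes ~w/2 bases at the true edges; walk back
    # out through exact matches, then tighten any mismatching rim
    while s > 0 and match[s - 1]:
        s -= 1
    while e < lq and match[e]:
        e += 1
    while s < e and not match[s]:
        s += 1
    while e > s and not match[e - 1]:
        e -= 1
    return s, e


def _chain_forward(hits, lq: int, gap: int):
    """Chain clean regions from the contig start; the chain's last hit abuts
    the junction.  Returns (chained reach, that hit)."""
    regions = [(*_clean_region(h[2]), h) for h in hits]
    cur, last = 0, None
    while True:
        cands = [r for r in regions if r[0] <= cur + gap and r[1] > cur]
        if not cands:
            break
        start, reach, hit = max(cands, key=lambda r: r[1])
        cur, last = reach, hit
    return cur, last


def _chain_backward(hits, lq: int, gap: int):
    """Chain clean regions from the contig end toward the junction."""
    regions = [(*_clean_region(h[2]), h) for h in hits]
    cur, last = lq, None
    while True:
        cands = [r for r in regions if r[1] >= cur - gap and r[0] < cur]
        if not cands:
            break
        start, reach, hit = min(cands, key=lambda r: r[0])
        cur, last = start, hit
    return cur, last


def _plasmid_coord(pos_on_strand: int, strand: str, plen: int) -> int:
    pos = pos_on_strand % plen
    return pos if strand == "+" else (plen - 1 - pos) % plen


def _terminus(pm: PlasmidMap, pos: int) -> str:
    s, e = pm.tdna
    plen = len(pm.plasmid)
    d5 = min((pos - s) % plen, (s - pos) % plen)
    d3 = min((pos - (e - 1)) % plen, ((e - 1) - pos) % plen)
    return "5p" if d5 <= d3 else "3p"


def _make_left(seq, x, h, p, pm, plen):
    pre, _, _, rid, hdiag = h
    _, suf, _, strand, pdiag = p
    host_start, host_end = hdiag, hdiag + x
    if host_start < 0:
        return None
    pb = _plasmid_coord(pdiag + x, strand, plen)
    pb_end = _plasmid_coord(pdiag + len(seq) - 1, strand, plen)
    iv = (min(pb, pb_end), max(pb, pb_end) + 1)
    return JunctionContig(
        seq=seq, side="left", host_ref=rid,
        host_start=host_start, host_end=host_end, contig_host=(0, x),
        plasmid_interval=iv, plasmid_strand=strand, contig_plasmid=(x, len(seq)),
        breakpoint_host=host_end, junction_element=pm.element_at(pb),
        tdna_terminus=_terminus(pm, pb),
    )


def _make_right(seq, x, h, p, pm, plen):
    _, suf, _, rid, hdiag = h
    pre, _, _, strand, pdiag = p
    host_start, host_end = hdiag + x, hdiag + len(seq)
    if host_start < 0:
        return None
    pb = _plasmid_coord(pdiag + x - 1, strand, plen)
    pb_start = _plasmid_coord(pdiag, strand, plen)
    iv = (min(pb, pb_start), max(pb, pb_start) + 1)
    return JunctionContig(
        seq=seq, side="right", host_ref=rid,
        host_start=host_start, host_end=host_end, contig_host=(x, len(seq)),
        plasmid_interval=iv, plasmid_strand=strand, contig_plasmid=(0, x),
        breakpoint_host=host_start, junction_element=pm.element_at(pb),
        tdna_terminus=_terminus(pm, pb),
    )


# ---------------------------------------------------------------------------
# Integration call and arrangement
# ---------------------------------------------------------------------------

def call_integration(
    junction_contigs: Sequence[JunctionContig],
    copy_number: float | None = None,
) -> IntegrationCall:
    """Compose flank calls into one integration call.

    The locus is the 1-based coordinate of the last retained 5' host base;
    the deletion length is the distance between the 5' breakpoint (exclusive
    end of the retained prefix) and the 3' breakpoint (first retained host
    base).  With a single recovered flank the deletion is reported missing,
    not zero.  Junctions on different chromosomes raise a conflict.
    """
    if not junction_contigs:
        raise ValueError("no junction contigs to call from")
    chroms = {j.host_ref for j in junction_contigs}
    if len(chroms) > 1:
        raise ValueError(f"junction contigs on conflicting chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()

    def pick(side: str) -> JunctionContig | None:
        cands = [j for j in junction_contigs if j.side == side]
        if not cands:
            return None
        return max(cands, key=lambda j: j.host_end - j.host_start)

    left, right = pick("left"), pick("right")
    locus = None
    deletion = None
    if left is not None:
        locus = left.breakpoint_host  # 0-based exclusive end == 1-based last base
    if left is not None and right is not None:
        deletion = right.breakpoint_host - left.breakpoint_host
    if locus is None and right is not None:
        locus = right.breakpoint_host  # fall back to the 3' flank position

    call = IntegrationCall(
        chrom=chrom,
        locus=int(locus),
        deletion_len=int(deletion) if deletion is not None else None,
        element_5p=left.junction_element if left else None,
        element_3p=right.junction_element if right else None,
        strand_5p=left.plasmid_strand if left else None,
        strand_3p=right.plasmid_strand if right else None,
        terminus_5p=left.tdna_terminus if left else None,
        terminus_3p=right.tdna_terminus if right else None,
        arrangement="unresolved",
        copy_number=copy_number,
        contigs=list(junction_contigs),
    )
    call.arrangement = infer_arrangement(call, copy_number)
    return call


def infer_arrangement(call: IntegrationCall, copy_number: float | None) -> str:
    """Classify the insert structure from flank elements and copy number.

    One copy with the two flanks at opposite T-DNA termini is a single
    insert; two copies presenting the same terminus on both flanks on
    opposite strands form a head-to-head (inverted) repeat; two copies with
    opposite termini on the same strand form a tandem head-to-tail repeat.
    Anything else — including single-flank evidence — is unresolved.
    """
    if (copy_number is None or call.terminus_5p is None or call.terminus_3p is None
            or call.strand_5p is None or call.strand_3p is None):
        return "unresolved"
    copies = int(round(copy_number))
    same_terminus = call.terminus_5p == call.terminus_3p
    same_strand = call.strand_5p == call.strand_3p
    if copies == 1 and not same_terminus:
        return "single"
    if copies == 2 and same_terminus and not same_strand \
            and call.element_5p == call.element_3p:
        return "head_to_head"
    if copies == 2 and not same_terminus and same_strand:
        return "tandem_head_to_tail"
    return "unresolved"


def format_report(call: IntegrationCall) -> str:
    """Human-readable schematic of the called integration."""
    lines = [
        f"chromosome      : {call.chrom}",
        f"locus (1-based) : {call.locus:,}",
        f"host deletion   : "
        + (f"{call.deletion_len} bp" if call.deletion_len is not None else "unresolved"),
        f"copy number     : "
        + (f"{call.copy_number:.2f}" if call.copy_number is not None else "n/a"),
        f"arrangement     : {call.arrangement}",
    ]
    chain = ["host(5')"]
    if call.element_5p:
        chain.append(f"{call.element_5p}({call.strand_5p},{call.terminus_5p})")
    if call.arrangement == "head_to_head":
        chain.append("...T-DNA >< T-DNA (inverted)...")
    elif call.arrangement == "tandem_head_to_tail":
        chain.append("...T-DNA > T-DNA > ...")
    elif call.arrangement == "single":
        chain.append("...T-DNA...")
    else:
        chain.append("...")
    if call.element_3p:
        chain.append(f"{call.element_3p}({call.strand_3p},{call.terminus_3p})")
    chain.append("host(3')")
    lines.append("structure       : " + " - ".join(chain))
    return "\n".join(lines)
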