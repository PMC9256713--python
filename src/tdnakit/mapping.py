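"""Minimal seed-and-extend paired-end read mapping and depth statistics.

The mapper locates exact k-mer seeds (default k=31) in a prebuilt index over
host and plasmid references and scores full-length ungapped extensions,
counting mismatches.  It reports *all* best-scoring placements: a read whose
best score is achieved at more than one location is retained but flagged
non-unique, which downstream stages use to discard homology-driven
candidates.  Gapped alignment is deliberately absent — 100 bp reads with a
few percent substitution error resolve junctions by assembly, not by CIGAR.

Depth statistics follow the fold-coverage bookkeeping used for copy-number
estimation: the general depth D is computed from *total* read pairs against
the host length, the coverage calibrator R = mapped pairs / total pairs
corrects for the unmapped fraction separately, and ADT is the average
per-base aligned coverage over a target element.

SAM import/export (via pysam) covers a minimal dialect — @SQ headers, the
basic FLAG bits, ungapped M CIGARs — for interoperability with external
aligner runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .refmodel import GenomicInterval, SequenceRecord, revcomp

__all__ = [
    "DepthStats",
    "EndAlignment",
    "PairAlignment",
    "ReferenceIndex",
    "average_target_depth",
    "classify_pair",
    "coverage_calibrator",
    "general_depth",
    "map_pair",
    "map_read",
    "read_sam",
    "write_sam",
]

PAIR_CLASSES = ("both_host", "both_plasmid", "chimeric_host_plasmid",
                "one_unmapped", "both_unmapped")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i

_N_CODE = 4
_CIRCULAR_PAD = 300  # must exceed read length; lets plasmid reads span the origin


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class EndAlignment:
    """One end's placement: 0-based leftmost position on a reference."""

    ref_id: str | None
    pos: int
    strand: str
    matched_len: int
    mismatches: int
    mapped: bool
    unique: bool
    seq: str | None = None

    @classmethod
    def unmapped_end(cls, seq: str | None = None) -> "EndAlignment":
        return cls(None, -1, ".", 0, 0, False, False, seq)


@dataclass
class PairAlignment:
    """A read pair's two chosen placements plus its reference-class label."""

    pair_id: str
    end1: EndAlignment
    end2: EndAlignment
    pair_class: str
    host_end: EndAlignment | None = None
    plasmid_end: EndAlignment | None = None


@dataclass
class DepthStats:
    """Genome depth D (fold), coverage calibrator R, per-element ADT map."""

    d: float
    r: float
    adt: dict[str, float] = field(default_factory=dict)


class ReferenceIndex:
    """Exact k-mer index over a reference set (forward strand).

    Circular references are padded with their own prefix so seeds and
    extensions may wrap the origin; reported positions are mod length.
    """

    RESCUE_K = 13  # reseeding word for reads whose errors break every k-mer

    def __init__(self, records: Sequence[SequenceRecord], k: int = 31):
        if not records:
            raise ValueError("cannot build an index over an empty reference set")
        self.k = k
        self.records = {r.id: r for r in records}
        self.lengths = {r.id: len(r) for r in records}
        self.arrays: dict[str, np.ndarray] = {}
        self.index: dict[bytes, list[tuple[str, int]]] = {}
        self.rescue: dict[bytes, list[tuple[str, int]]] = {}
        k2 = self.RESCUE_K
        for rec in records:
            seq = rec.seq + (rec.seq[:_CIRCULAR_PAD] if rec.circular else "")
            if len(rec) < k:
                raise ValueError(f"reference {rec.id!r} shorter than k={k}")
            self.arrays[rec.id] = _encode(seq)
            data = seq.encode()
            n = len(rec)  # index one seed per original position only
            for p in range(0, n if rec.circular else n - k + 1):
                self.index.setdefault(data[p : p + k], []).append((rec.id, p))
            for p in range(0, n if rec.circular else n - k2 + 1):
                self.rescue.setdefault(data[p : p + k2], []).append((rec.id, p))

    def mismatches(self, ref_id: str, pos: int, read: np.ndarray, read_has_n: bool) -> int:
        """Ungapped mismatch count of ``read`` placed at ``pos``; N never matches."""
        arr = self.arrays[ref_id]
        window = arr[pos : pos + len(read)]
        if len(window) < len(read):
            return len(read)  # runs off a linear reference end
        mm = int(np.count_nonzero(window != read))
        if read_has_n:
            mm += int(np.count_nonzero((window == read) & (read == _N_CODE)))
        return mm


def map_read(
    seq: str,
    index: ReferenceIndex,
    max_mismatch_frac: float = 0.1,
    seed_stride: int = 17,
) -> list[EndAlignment]:
    """Best ungapped placement(s) of a read on both strands.

    Seeds are taken at a stride along the read (all offsets are retried when
    the strided seeds find nothing, so a read with clustered errors still
    maps).  Returns every placement achieving the minimum mismatch count, or
    an empty list if that minimum exceeds ``max_mismatch_frac``.
    """
    L = len(seq)
    k = index.k
    if L < k:
        raise ValueError(f"read shorter than seed size k={k}")
    max_mm = int(max_mismatch_frac * L)
    variants = {"+": seq, "-": revcomp(seq)}
    encoded = {s: _encode(v) for s, v in variants.items()}
    raw = {s: v.encode() for s, v in variants.items()}
    has_n = {s: bool((encoded[s] == _N_CODE).any()) for s in variants}

    def candidates(offsets, table, word) -> set[tuple[str, int, str]]:
        cands: set[tuple[str, int, str]] = set()
        for strand in ("+", "-"):
            data = raw[strand]
            for off in offsets:
                hits = table.get(data[off : off + word])
                if hits:
                    for ref_id, p in hits:
                        start = p - off
                        if start >= 0 or index.records[ref_id].circular:
                            cands.add((ref_id, start, strand))
        return cands

    offs = list(range(0, L - k + 1, seed_stride))
    if offs[-1] != L - k:
        offs.append(L - k)
    cands = candidates(offs, index.index, k)
    if not cands:
        cands = candidates(range(L - k + 1), index.index, k)
    if not cands:
        # reseed with a short word: a read within the mismatch budget can
        # still have errors that break every full-size seed
        k2 = index.RESCUE_K
        cands = candidates(range(L - k2 + 1), index.rescue, k2)
    if not cands:
        return []

    best_mm = max_mm + 1
    best: list[tuple[str, int, str]] = []
    for ref_id, start, strand in sorted(cands):
        n = index.lengths[ref_id]
        probe = start % n if index.records[ref_id].circular else start
        if probe < 0 or (not index.records[ref_id].circular and probe + L > n):
            continue
        mm = index.mismatches(ref_id, probe, encoded[strand], has_n[strand])
        if mm < best_mm:
            best_mm, best = mm, [(ref_id, probe, strand)]
        elif mm == best_mm:
            if (ref_id, probe, strand) not in best:
                best.append((ref_id, probe, strand))
    if best_mm > max_mm:
        return []
    unique = len(best) == 1
    return [
        EndAlignment(ref_id, pos, strand, L, best_mm, True, unique, seq)
        for ref_id, pos, strand in best
    ]


def classify_pair(
    pair_id: str,
    hits1: Sequence[EndAlignment],
    hits2: Sequence[EndAlignment],
    plasmid_ids: frozenset[str] | set[str],
    seq1: str | None = None,
    seq2: str | None = None,
) -> PairAlignment:
    """Label a pair by the reference categories of its two ends.

    An end counts as plasmid-capable when *any* best-scoring placement lies
    on a plasmid reference — ties between a native host locus and its
    plasmid homolog are deliberately treated as plasmid evidence here and
    removed later by the homology blacklist, mirroring the over-extraction
    of the unfiltered pipeline.
    """

    def category(hits: Sequence[EndAlignment]) -> str:
        if not hits:
            return "unmapped"
        return "plasmid" if any(h.ref_id in plasmid_ids for h in hits) else "host"

    def representative(hits: Sequence[EndAlignment], want_plasmid: bool, seq) -> EndAlignment:
        if not hits:
            return EndAlignment.unmapped_end(seq)
        pool = [h for h in hits if (h.ref_id in plasmid_ids) == want_plasmid] or list(hits)
        rep = sorted(pool, key=lambda h: (h.ref_id, h.pos, h.strand))[0]
        return replace(rep, unique=len(hits) == 1, seq=seq if seq is not None else rep.seq)

    c1, c2 = category(hits1), category(hits2)
    if c1 == c2 == "unmapped":
        pair_class = "both_unmapped"
    elif "unmapped" in (c1, c2):
        pair_class = "one_unmapped"
    elif c1 == c2 == "host":
        pair_class = "both_host"
    elif c1 == c2 == "plasmid":
        pair_class = "both_plasmid"
    else:
        pair_class = "chimeric_host_plasmid"

    e1 = representative(hits1, c1 == "plasmid", seq1)
    e2 = representative(hits2, c2 == "plasmid", seq2)
    pa = PairAlignment(pair_id, e1, e2, pair_class)
    if pair_class == "chimeric_host_plasmid":
        pa.host_end = e1 if c1 == "host" else e2
        pa.plasmid_end = e1 if c1 == "plasmid" else e2
    return pa


def map_pair(
    pair_id: str,
    seq1: str,
    seq2: str,
    index: ReferenceIndex,
    plasmid_ids: frozenset[str] | set[str],
    max_mismatch_frac: float = 0.1,
) -> PairAlignment:
    hits1 = map_read(seq1, index, max_mismatch_frac)
    hits2 = map_read(seq2, index, max_mismatch_frac)
    return classify_pair(pair_id, hits1, hits2, plasmid_ids, seq1, seq2)


# ---------------------------------------------------------------------------
# Depth statistics
# ---------------------------------------------------------------------------

def coverage_calibrator(mapped_pairs: int, total_pairs: int) -> float:
    """R = pairs with both ends mapped to the host / total trimmed pairs."""
    if total_pairs <= 0:
        raise ValueError("total_pairs must be positive")
    if mapped_pairs > total_pairs:
        raise ValueError("mapped_pairs cannot exceed total_pairs")
    return mapped_pairs / total_pairs


def general_depth(total_pairs: int, read_len: int, ref_len: int) -> float:
    """Fold coverage D = 2 * read_len * total_pairs / ref_len.

    Uses total (trimmed) pairs, not mapped pairs; R corrects separately.
    """
    if read_len <= 0 or ref_len <= 0:
        raise ValueError("read_len and ref_len must be positive")
    return 2.0 * read_len * total_pairs / ref_len


def average_target_depth(
    alignments: Iterable[EndAlignment],
    interval: GenomicInterval,
) -> float:
    """ADT: mean per-base aligned-read coverage over ``interval``.

    Only mapped ends on the interval's reference contribute; each
    contributes the length of its overlap with the interval.
    """
    width = interval.end - interval.start
    if width <= 0:
        raise ValueError("zero-length interval")
    total = 0
    for a in alignments:
        if not a.mapped or a.ref_id != interval.ref_id:
            continue
        lo = max(a.pos, interval.start)
        hi = min(a.pos + a.matched_len, interval.end)
        if hi > lo:
            total += hi - lo
    return total / width


# ---------------------------------------------------------------------------
# SAM interoperability
# ---------------------------------------------------------------------------

def write_sam(
    pairs: Iterable[PairAlignment],
    path: str | Path,
    reference_lengths: Mapping[str, int],
) -> None:
    """Export pairs in a minimal SAM dialect (ungapped M CIGARs, NM/XU tags)."""
    names = list(reference_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(reference_lengths[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for pa in pairs:
            for end, mate, first in ((pa.end1, pa.end2, True), (pa.end2, pa.end1, False)):
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = pa.pair_id
                seg.query_sequence = end.seq
                flag = 0x1 | (0x40 if first else 0x80)
                if not end.mapped:
                    flag |= 0x4
                else:
                    if end.strand == "-":
                        flag |= 0x10
                    seg.reference_id = tid[end.ref_id]
                    seg.reference_start = end.pos
                    seg.cigartuples = [(0, end.matched_len)]
                    seg.set_tag("NM", end.mismatches)
                    seg.set_tag("XU", 1 if end.unique else 0)
                if not mate.mapped:
                    flag |= 0x8
                elif mate.strand == "-":
                    flag |= 0x20
                seg.flag = flag
                out.write(seg)


def read_sam(path: str | Path, plasmid_ids: frozenset[str] | set[str]) -> list[PairAlignment]:
    """Import a SAM file, pairing records by QNAME and re-deriving pair classes.

    Requires both mates of every pair; CIGARs may use M/I/D/S, and the
    matched length is the sum of M operations.
    """
    by_name: dict[str, dict[bool, EndAlignment]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            if seg.is_unmapped:
                end = EndAlignment.unmapped_end(seg.query_sequence)
            else:
                matched = sum(n for op, n in (seg.cigartuples or []) if op == 0)
                end = EndAlignment(
                    ref_id=seg.reference_name,
                    pos=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    matched_len=matched,
                    mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                    mapped=True,
                    unique=bool(seg.get_tag("XU")) if seg.has_tag("XU") else True,
                    seq=seg.query_sequence,
                )
            slot = by_name.setdefault(seg.query_name, {})
            slot[bool(seg.flag & 0x40)] = end
    pairs = []
    for name, ends in sorted(by_name.items()):
        if True not in ends or False not in ends:
            raise ValueError(f"SAM record {name!r} is missing its mate")
        e1, e2 = ends[True], ends[False]
        pa = classify_pair(name, [e1] if e1.mapped else [], [e2] if e2.mapped else [],
                           plasmid_ids, e1.seq, e2.seq)
        # classify_pair marks singleton hit lists unique; restore imported flags
        pa.end1 = replace(pa.end1, unique=e1.unique) if e1.mapped else pa.end1
        pa.end2 = replace(pa.end2, unique=e2.unique) if e2.mapped else pa.end2
        if pa.pair_class == "chimeric_host_plasmid":
            if pa.end1.ref_id in plasmid_ids:
                pa.plasmid_end, pa.host_end = pa.end1, pa.end2
            else:
                pa.plasmid_end, pa.host_end = pa.end2, pa.end1
        pairs.append(pa)
    return pairs
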