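"""Plasmid-to-host homology search and the native-read exclusion blacklist.

Constructs whose elements are recycled from the recipient genome (native
promoters, RNAi triggers against endogenous genes) produce chimeric-looking
read pairs from wild-type DNA: one end maps to the native locus, the mate
ties between that locus and the identical plasmid element.  To remove them,
homologous blocks between the whole (circular) plasmid and the host are
located by exact-word seeding plus ungapped X-drop extension, expanded by a
margin equal to the library insert size, and merged into a per-reference
blacklist; the junction stage drops chimeric pairs whose host-side position
falls inside it.
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .refmodel import GenomicInterval, SequenceRecord, revcomp

__all__ = [
    "Blacklist",
    "HomologyBlock",
    "build_blacklist",
    "find_homology_blocks",
    "import_blast_tab",
    "in_blacklist",
    "merge_intervals",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class HomologyBlock:
    """One homologous block: a host interval paired with a plasmid interval."""

    host: GenomicInterval
    plasmid_start: int
    plasmid_end: int
    strand: str      # plasmid strand relative to host forward
    identity: float
    length: int


@dataclass
class Blacklist:
    """Margin-expanded, merged exclusion intervals per reference."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    margin: int = 500

    def total_bases(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and non-overlapping."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def find_homology_blocks(
    plasmid: SequenceRecord,
    hosts: Sequence[SequenceRecord],
    word_size: int = 16,
    min_identity: float = 0.9,
    min_block_len: int = 50,
    xdrop: int = 12,
) -> list[HomologyBlock]:
    """Locate homologous blocks between the whole plasmid and the host genome.

    Exact ``word_size``-mers seed diagonals on both plasmid strands (the
    plasmid is treated as circular, so seeds may wrap the origin); each
    diagonal is extended ungapped with an X-drop, and blocks shorter than
    ``min_block_len`` or below ``min_identity`` are dropped.  Isolated
    random word hits therefore never survive: their extensions stall at
    roughly the word size.
    """
    w = word_size
    if w > len(plasmid):
        raise ValueError("word_size exceeds plasmid length")
    host_index: dict[bytes, list[tuple[int, int]]] = {}
    host_arrs = []
    for hi, rec in enumerate(hosts):
        host_arrs.append(_encode(rec.seq))
        data = rec.seq.encode()
        for p in range(len(data) - w + 1):
            host_index.setdefault(data[p : p + w], []).append((hi, p))

    L = len(plasmid)
    blocks: list[HomologyBlock] = []
    seen: set[tuple] = set()
    for strand in ("+", "-"):
        pseq = plasmid.seq if strand == "+" else revcomp(plasmid.seq)
        doubled = pseq + pseq if plasmid.circular else pseq
        parr = _encode(doubled)
        data = doubled.encode()
        # group seeds by (host record, diagonal)
        diagonals: dict[tuple[int, int], list[int]] = {}
        for i in range(L if plasmid.circular else L - w + 1):
            hits = host_index.get(data[i : i + w])
            if hits:
                for hi, hp in hits:
                    diagonals.setdefault((hi, hp - i), []).append(i)
        for (hi, diag), seeds in diagonals.items():
            harr = host_arrs[hi]
            i0, i1 = min(seeds), max(seeds) + w  # plasmid coords of seed core
            lo = max(0, -diag)
            hi_lim = min(len(parr), len(harr) - diag)
            # X-drop extension: +1 match, -3 mismatch
            def extend(start: int, step: int, limit: int) -> int:
                # returns the new boundary: exclusive end for step=+1,
                # inclusive start for step=-1
                best_pos = start + (0 if step > 0 else 1)
                score, best_score = 0, 0
                p = start
                while p != limit:
                    score += 1 if parr[p] == harr[p + diag] and parr[p] != 4 else -3
                    if score > best_score:
                        best_score = score
                        best_pos = p + 1 if step > 0 else p
                    elif best_score - score > xdrop:
                        break
                    p += step
                return best_pos

            start = extend(i0 - 1, -1, lo - 1) if i0 > lo else i0
            end = extend(i1, 1, hi_lim) if i1 < hi_lim else i1
            length = end - start
            if length < min_block_len:
                continue
            seg_p = parr[start:end]
            seg_h = harr[start + diag : end + diag]
            ident = float(np.count_nonzero((seg_p == seg_h) & (seg_p != 4))) / length
            if ident < min_identity:
                continue
            host_iv = GenomicInterval(hosts[hi].id, start + diag, end + diag)
            # map plasmid coords back to the forward strand of the plasmid
            if strand == "+":
                ps = start % L
            else:
                # position c on the reverse-strand sequence maps to forward
                # coordinate L-1-c, so [start,end) maps to [(L-end) mod L, +length)
                ps = (L - end) % L
            pe = ps + length  # pe may exceed L: the block wraps the origin
            key = (hosts[hi].id, host_iv.start, host_iv.end, ps, strand)
            if key in seen:
                continue
            seen.add(key)
            blocks.append(HomologyBlock(host_iv, ps, pe, strand, ident, length))
    blocks.sort(key=lambda b: (b.host.ref_id, b.host.start, -b.length))
    return blocks


def build_blacklist(
    blocks: Iterable[HomologyBlock],
    margin: int,
    ref_lengths: Mapping[str, int],
    plasmid_id: str,
) -> Blacklist:
    """Expand each block by ``margin`` on both sides, clip, and merge.

    The margin defaults to the library insert size in callers: a chimeric
    pair caused by a homologous segment has its host-side end within one
    insert of the segment.  Both the host-side and plasmid-side intervals
    are stored; which side is consulted is the junction stage's choice.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    per_ref: dict[str, list[tuple[int, int]]] = {}
    plen = ref_lengths.get(plasmid_id)
    for b in blocks:
        n = ref_lengths[b.host.ref_id]
        per_ref.setdefault(b.host.ref_id, []).append(
            (max(0, b.host.start - margin), min(n, b.host.end + margin))
        )
        if plen is not None:
            s = b.plasmid_start - margin
            e = b.plasmid_end + margin
            # clip circularly: wrap overhangs to the other side of the origin
            pieces = []
            if e - s >= plen:
                pieces.append((0, plen))
            else:
                s_m, e_m = s % plen, e % plen if e % plen else plen
                if s_m < e_m:
                    pieces.append((s_m, e_m))
                else:
                    pieces.extend([(s_m, plen), (0, e_m)])
            per_ref.setdefault(plasmid_id, []).extend(pieces)
    return Blacklist(
        intervals={ref: merge_intervals(ivs) for ref, ivs in per_ref.items()},
        margin=margin,
    )


def in_blacklist(blacklist: Blacklist, ref_id: str, pos: int) -> bool:
    """True iff ``pos`` lies inside a stored interval for ``ref_id``."""
    ivs = blacklist.intervals.get(ref_id)
    if not ivs:
        return False
    i = bisect_right(ivs, (pos, float("inf"))) - 1
    return i >= 0 and ivs[i][0] <= pos < ivs[i][1]


# ---------------------------------------------------------------------------
# Import/export
# ---------------------------------------------------------------------------

def import_blast_tab(path: str | Path, plasmid_id: str = "plasmid") -> list[HomologyBlock]:
    """Read BLASTN ``-outfmt 6`` (qseqid=plasmid, sseqid=host) into blocks.

    Coordinates in the table are 1-based inclusive and are converted to the
    internal 0-based half-open convention; a subject interval with start >
    end denotes a reverse-strand hit.
    """
    blocks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            sseq, pident, length = f[1], float(f[2]), int(f[3])
            qs, qe, ss, se = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            strand = "+" if ss <= se else "-"
            if strand == "-":
                ss, se = se, ss
            blocks.append(
                HomologyBlock(
                    host=GenomicInterval(sseq, ss - 1, se),
                    plasmid_start=qs - 1,
                    plasmid_end=qe,
                    strand=strand,
                    identity=pident / 100.0,
                    length=length,
                )
            )
    return blocks


def export_blocks_tsv(blocks: Sequence[HomologyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("host_chr\thost_start\thost_end\tplasmid_start\tplasmid_end\tidentity\tstrand\n")
        for b in blocks:
            fh.write(
                f"{b.host.ref_id}\t{b.host.start}\t{b.host.end}\t"
                f"{b.plasmid_start}\t{b.plasmid_end}\t{b.identity:.4f}\t{b.strand}\n"
            )


def export_blacklist(bl: Blacklist, bed_path: str | Path, plasmid_id: str,
                     plasmid_tsv: str | Path | None = None) -> None:
    """Host intervals as BED, plasmid intervals as a 2-column TSV."""
    with open(bed_path, "w") as fh:
        for ref, ivs in sorted(bl.intervals.items()):
            if ref == plasmid_id:
                continue
            for s, e in ivs:
                fh.write(f"{ref}\t{s}\t{e}\tblacklist\t0\t.\n")
    if plasmid_tsv is not None:
        with open(plasmid_tsv, "w") as fh:
            for s, e in bl.intervals.get(plasmid_id, []):
                fh.write(f"{s}\t{e}\n")
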