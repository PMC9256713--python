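"""Reference model: domain types, coordinate conventions, FASTA/TSV/BED I/O.

All internal coordinates are 0-based half-open.  Conversion to the 1-based
inclusive convention used in human-readable reports happens only at the
report boundary, via :func:`to_one_based`.

Plasmids are circular: the vector backbone is defined as the circular
complement of the T-DNA interval, and downstream stages may wrap reads and
homology blocks across the origin.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DNA_ALPHABET",
    "FastaFormatError",
    "GenomicInterval",
    "PlasmidElement",
    "PlasmidMap",
    "SequenceRecord",
    "parse_plasmid_map",
    "read_elements_tsv",
    "read_fasta",
    "revcomp",
    "to_one_based",
    "write_bed6",
    "write_fasta",
]

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; the message names the line."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence.

    Parameters
    ----------
    id:
        Unique identifier within a reference set.
    seq:
        Upper-case string over ``{A, C, G, T, N}``; never empty.
    circular:
        Transformation plasmids are circular; host chromosomes are linear.
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has an empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence record {self.id!r} contains non-ACGTN characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named reference."""

    ref_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.ref_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def to_one_based(interval: GenomicInterval) -> tuple[int, int]:
    """Convert to the 1-based inclusive coordinates used in reports.

    A 0-based half-open ``[start, end)`` becomes ``(start + 1, end)``; a
    single-base interval ``[p, p+1)`` is reported as locus ``p + 1``.
    """
    return interval.start + 1, interval.end


@dataclass(frozen=True)
class PlasmidElement:
    """An annotated functional element on the plasmid (promoter, gene, border...)."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PlasmidMap:
    """Transformation plasmid with its T-DNA interval and named elements.

    The backbone is the circular complement of the T-DNA: zero, one, or two
    half-open intervals whose lengths sum with the T-DNA to the plasmid
    length.
    """

    plasmid: SequenceRecord
    tdna: tuple[int, int]
    elements: list[PlasmidElement] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.plasmid)
        s, e = self.tdna
        if not (0 <= s < e <= n):
            raise ValueError(f"T-DNA interval [{s},{e}) out of plasmid bounds (len {n})")
        for el in self.elements:
            if not (0 <= el.start < el.end <= n):
                raise ValueError(
                    f"element {el.name!r} [{el.start},{el.end}) out of plasmid "
                    f"bounds (len {n})"
                )

    @property
    def backbone(self) -> list[tuple[int, int]]:
        """Circular complement of the T-DNA, as 0..2 forward-strand intervals."""
        n = len(self.plasmid)
        s, e = self.tdna
        out = []
        if e < n:
            out.append((e, n))
        if s > 0:
            out.append((0, s))
        return out

    @property
    def backbone_len(self) -> int:
        return len(self.plasmid) - (self.tdna[1] - self.tdna[0])

    @property
    def tdna_seq(self) -> str:
        return self.plasmid.seq[self.tdna[0] : self.tdna[1]]

    def element_at(self, pos: int, max_dist: int = 50) -> str:
        """Name of the element containing ``pos`` (mod plasmid length).

        Breakpoints falling in unannotated gaps report the nearest element
        within ``max_dist`` bases, else ``"unannotated"``.
        """
        pos = pos % len(self.plasmid)
        containing = [el for el in self.elements if el.start <= pos < el.end]
        if containing:
            # smallest containing annotation wins (most specific)
            return min(containing, key=len).name
        best, best_d = None, max_dist + 1
        for el in self.elements:
            d = el.start - pos if pos < el.start else pos - (el.end - 1)
            if 0 < d < best_d:
                best, best_d = el.name, d
        return best if best is not None else "unannotated"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, circular: bool = False) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file.

    Sequences are upper-cased; characters outside ACGTN are rejected and the
    diagnostic names the offending line.
    """
    records: list[SequenceRecord] = []
    cur_id: str | None = None
    cur_header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()

    def flush() -> None:
        nonlocal cur_id, chunks
        if cur_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaFormatError(
                f"{path}: record {cur_id!r} (header at line {cur_header_line}) "
                "has an empty sequence"
            )
        records.append(SequenceRecord(cur_id, seq, circular=circular))
        cur_id, chunks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
                if name in seen:
                    raise FastaFormatError(
                        f"{path}: duplicate record id {name!r} at line {lineno}"
                    )
                seen.add(name)
                cur_id, cur_header_line = name, lineno
            else:
                if cur_id is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                up = line.upper()
                bad = set(up) - DNA_ALPHABET
                if bad:
                    raise FastaFormatError(
                        f"{path}: invalid character(s) {sorted(bad)} at line {lineno}"
                    )
                chunks.append(up)
    flush()
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Element tables and BED
# ---------------------------------------------------------------------------

def read_elements_tsv(path: str | Path) -> list[PlasmidElement]:
    """Read the element table: ``name<TAB>start<TAB>end<TAB>strand`` (0-based half-open)."""
    elements: list[PlasmidElement] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: expected 4 tab-separated columns at line {lineno}, "
                    f"got {len(fields)}"
                )
            name, start, end, strand = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise ValueError(f"{path}: empty interval for {name!r} at line {lineno}")
            elements.append(PlasmidElement(name, start, end, strand))
    return elements


def parse_plasmid_map(fasta_path: str | Path, elements_tsv: str | Path) -> PlasmidMap:
    """Load a plasmid FASTA plus its element table into a :class:`PlasmidMap`.

    The table must contain exactly one row named ``T-DNA``, which defines the
    transferred region; the remaining rows are named elements.
    """
    records = read_fasta(fasta_path, circular=True)
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected a single plasmid record, got {len(records)}")
    plasmid = records[0]
    elements = read_elements_tsv(elements_tsv)
    tdna_rows = [el for el in elements if el.name == "T-DNA"]
    if len(tdna_rows) != 1:
        raise ValueError(
            f"{elements_tsv}: expected exactly one element named 'T-DNA', "
            f"found {len(tdna_rows)}"
        )
    tdna = tdna_rows[0]
    rest = [el for el in elements if el.name != "T-DNA"]
    return PlasmidMap(plasmid=plasmid, tdna=(tdna.start, tdna.end), elements=rest)


def write_bed6(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Export intervals as BED6 (0-based half-open, as BED requires)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            strand = iv.strand if iv.strand != "." else "."
            fh.write(f"{iv.ref_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n")
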