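"""Ground-truthed genome construction and paired-end read simulation.

Builds transgenic / cisgenic genomes with a known insertion (locus, host
deletion, copy count, arrangement) and generates 100 bp paired-end reads with
an Illumina-like error profile: a per-position substitution probability that
ramps linearly from 0.1% at cycle 1 to 4% at cycle 100, a 5% chance for a
read to be replaced by uniform random bases, at most one N per read, and
fragments whose insert size is Normal(500, 10).  A mutated haplotype
(substitutions plus geometric-length indels at overall rate 1e-3) is derived
from the reference before fragments are sampled, so reads are internally
consistent with a genome that differs slightly from the mapping reference —
as real resequencing data does.

Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .refmodel import PlasmidMap, SequenceRecord, revcomp

__all__ = [
    "EventTruth",
    "ReadPair",
    "SimConfig",
    "build_cisgenic_genome",
    "build_event_genome",
    "make_insert",
    "make_references",
    "mutate_genome",
    "pick_clean_site",
    "read_fastq_pair",
    "simulate_reads",
    "spike_reads",
    "write_fastq_pair",
]

ARRANGEMENTS = ("single", "tandem_head_to_tail", "head_to_head")

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP_CODES = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


@dataclass(frozen=True)
class EventTruth:
    """Ground truth for one constructed integration event.

    ``locus`` is the 0-based host breakpoint: the event genome is
    ``host[:locus] + inserted_seq + host[locus + deletion_len:]``.  Reports
    use the 1-based coordinate of the last retained 5' host base, which is
    numerically equal to ``locus``.
    """

    host_chr: str
    locus: int
    deletion_len: int
    copies: int
    arrangement: str
    inserted_seq: str

    @property
    def locus_1based(self) -> int:
        return self.locus

    def to_json(self) -> str:
        d = {
            "chr": self.host_chr,
            "locus_1based": self.locus_1based,
            "deletion_len": self.deletion_len,
            "copies": self.copies,
            "arrangement": self.arrangement,
            "inserted_len": len(self.inserted_seq),
        }
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class SimConfig:
    """Read-simulation parameters (defaults are the study conditions)."""

    read_len: int = 100
    insert_mean: float = 500.0
    insert_sd: float = 10.0
    depth: float = 29.0
    err_start: float = 0.001
    err_end: float = 0.04
    random_read_prob: float = 0.05
    max_n_per_read: int = 1
    n_read_prob: float = 0.02  # chance a read carries its (single) N call
    mut_rate: float = 0.001
    indel_frac: float = 0.1
    indel_ext_prob: float = 0.3
    min_indel: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.err_start <= self.err_end < 1.0):
            raise ValueError("need 0 <= err_start <= err_end < 1")
        for name in ("random_read_prob", "n_read_prob", "mut_rate", "indel_frac", "indel_ext_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_len >= self.insert_mean:
            raise ValueError("read_len must be smaller than insert_mean")


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


# ---------------------------------------------------------------------------
# Event genome construction
# ---------------------------------------------------------------------------

def make_insert(plasmid_map: PlasmidMap, copies: int, arrangement: str) -> str:
    """Inserted sequence for a given copy count and arrangement.

    head-to-head is the T-DNA followed by its own reverse complement, so both
    host flanks abut the same T-DNA terminus on opposite strands.
    """
    if copies == 0:
        return ""
    t = plasmid_map.tdna_seq
    if not t:
        raise ValueError("copies > 0 requires a non-empty T-DNA")
    if arrangement not in ARRANGEMENTS:
        raise ValueError(f"unknown arrangement {arrangement!r}")
    if copies == 1:
        if arrangement != "single":
            raise ValueError("one copy implies arrangement='single'")
        return t
    if copies == 2:
        if arrangement == "head_to_head":
            return t + revcomp(t)
        if arrangement == "tandem_head_to_tail":
            return t + t
        raise ValueError("two copies require head_to_head or tandem_head_to_tail")
    raise ValueError("only 0, 1 or 2 copies are supported")


def _insert_context(plasmid_map: PlasmidMap, copies: int, arrangement: str) -> tuple[str, str]:
    """Plasmid bases flanking the insert in plasmid context (before start, after end).

    Used to detect junction micro-homology: an alignment can slide across a
    junction when the host flank happens to continue the plasmid sequence (or
    vice versa), making the breakpoint representation non-unique.
    """
    p = plasmid_map.plasmid.seq
    n = len(p)
    s, e = plasmid_map.tdna
    before_start = p[(s - 1) % n]
    after_end = p[e % n]
    if arrangement == "head_to_head" and copies == 2:
        # insert ends with revcomp(T-DNA); the base continuing past it on the
        # reverse plasmid strand is the complement of the base before T-DNA.
        after = revcomp(before_start)
    else:
        after = after_end
    return before_start, after


def junction_ambiguous(
    host: SequenceRecord,
    site: int,
    deletion_len: int,
    insert: str,
    context: tuple[str, str],
) -> bool:
    """True if either junction of the event admits more than one breakpoint.

    Checks the four junction-adjacent base comparisons; if any pair matches,
    an aligner (and indeed any textual representation of the event) can shift
    the breakpoint by at least one base.
    """
    h = host.seq
    pre, post = context
    r = site + deletion_len
    if r >= len(h) or site < 1 or not insert:
        return True
    return (
        insert[0] == h[site]          # host diagonal continues into insert
        or h[site - 1] == pre         # plasmid diagonal extends into 5' host
        or insert[-1] == h[r - 1]     # host diagonal extends into insert end
        or h[r] == post               # plasmid diagonal continues into 3' host
    )


def pick_clean_site(
    host: SequenceRecord,
    plasmid_map: PlasmidMap,
    rng: np.random.Generator,
    copies: int = 2,
    arrangement: str = "head_to_head",
    deletion_len: int = 36,
    lo: int = 2000,
    hi: int | None = None,
    exclude: Sequence[tuple[int, int]] = (),
    pad: int = 2000,
    max_tries: int = 1000,
) -> int:
    """Draw a random insertion site whose junctions are unambiguous.

    Rejection-samples uniform sites in ``[lo, hi)`` until
    :func:`junction_ambiguous` is false and the site is at least ``pad``
    bases away from every excluded interval (e.g. planted homology blocks).
    """
    if hi is None:
        hi = len(host) - 2000 - deletion_len
    insert = make_insert(plasmid_map, copies, arrangement)
    ctx = _insert_context(plasmid_map, copies, arrangement)
    for _ in range(max_tries):
        site = int(rng.integers(lo, hi))
        if any(s - pad <= site <= e + pad for s, e in exclude):
            continue
        if not junction_ambiguous(host, site, deletion_len, insert, ctx):
            return site
    raise RuntimeError("could not find an unambiguous insertion site")


def build_event_genome(
    host: SequenceRecord,
    plasmid_map: PlasmidMap,
    site: int,
    copies: int,
    arrangement: str,
    deletion_len: int = 0,
) -> tuple[SequenceRecord, EventTruth]:
    """Insert ``copies`` T-DNAs at ``site``, deleting ``deletion_len`` host bases.

    With ``copies=0`` the genome is returned unchanged and the truth records
    an empty insert.
    """
    if deletion_len < 0:
        raise ValueError("deletion_len must be >= 0")
    if site < 0 or site + deletion_len > len(host):
        raise ValueError("site + deletion_len outside the host chromosome")
    insert = make_insert(plasmid_map, copies, arrangement)
    truth = EventTruth(host.id, site, deletion_len if copies else 0, copies,
                       arrangement if copies else "single", insert)
    if copies == 0:
        return host, truth
    read_len = 100
    around = host.seq[max(0, site - read_len) : site + deletion_len + read_len]
    if "N" * (read_len + 1) in around:
        warnings.warn("insertion site lies in an N-run longer than a read; junction unrecoverable")
    ctx = _insert_context(plasmid_map, copies, arrangement)
    if junction_ambiguous(host, site, deletion_len, insert, ctx):
        warnings.warn(
            "junction-adjacent bases coincide with the insert/plasmid context; "
            "the breakpoint representation is not unique at this site"
        )
    seq = host.seq[:site] + insert + host.seq[site + deletion_len :]
    return SequenceRecord(host.id, seq), truth


def build_cisgenic_genome(
    host: SequenceRecord,
    donor_interval: tuple[int, int],
    insert_site: int,
    insert_mean: int = 500,
) -> tuple[SequenceRecord, EventTruth]:
    """Insert a host-native fragment (the cis gene) elsewhere in the host.

    No host bases are deleted.  The donor region and the insertion site must
    be separated by more than the library insert size, otherwise junction
    pairs are indistinguishable from native pairs.
    """
    ds, de = donor_interval
    if ds >= de:
        raise ValueError("donor interval is empty")
    if not (0 <= ds < de <= len(host)):
        raise ValueError("donor interval outside the host chromosome")
    if ds - insert_mean <= insert_site <= de + insert_mean:
        raise ValueError(
            "insertion site within one insert size of the donor region; "
            "junctions would be indistinguishable from native sequence"
        )
    if not (0 <= insert_site <= len(host)):
        raise ValueError("insertion site outside the host chromosome")
    fragment = host.seq[ds:de]
    seq = host.seq[:insert_site] + fragment + host.seq[insert_site:]
    truth = EventTruth(host.id, insert_site, 0, 1, "single", fragment)
    return SequenceRecord(host.id, seq), truth


# ---------------------------------------------------------------------------
# Haplotype mutation and read generation
# ---------------------------------------------------------------------------

def mutate_genome(seq: str, config: SimConfig, rng: np.random.Generator) -> str:
    """Apply substitutions and geometric-length indels at ``mut_rate``.

    The mutated copy stands in for the sequenced individual's haplotype;
    fragments are sampled from it, so reads carry consistent divergence from
    the mapping reference.
    """
    n = len(seq)
    n_mut = rng.poisson(config.mut_rate * n)
    if n_mut == 0:
        return seq
    positions = np.sort(rng.choice(n, size=min(n_mut, n), replace=False))
    is_indel = rng.random(len(positions)) < config.indel_frac
    pieces: list[str] = []
    prev = 0
    for pos, indel in zip(positions.tolist(), is_indel.tolist()):
        pieces.append(seq[prev:pos])
        if not indel:
            orig = seq[pos]
            choices = [b for b in "ACGT" if b != orig]
            pieces.append(choices[int(rng.integers(0, 3))])
            prev = pos + 1
        else:
            length = config.min_indel + int(rng.geometric(1.0 - config.indel_ext_prob)) - 1
            if rng.random() < 0.5:  # insertion
                pieces.append(_decode(rng.integers(0, 4, size=length).astype(np.uint8)))
                prev = pos
            else:  # deletion
                prev = min(pos + length, n)
    pieces.append(seq[prev:])
    return "".join(pieces)


def _error_ramp(config: SimConfig) -> np.ndarray:
    """Per-cycle substitution probability, linear between the two endpoints."""
    if config.read_len == 1:
        return np.array([config.err_start])
    return np.linspace(config.err_start, config.err_end, config.read_len)


def _qual_string(config: SimConfig) -> str:
    p = np.clip(_error_ramp(config), 1e-4, 0.75)
    q = np.clip(np.round(-10.0 * np.log10(p)).astype(int), 2, 40)
    return "".join(chr(33 + int(v)) for v in q)


def simulate_reads(
    genome: SequenceRecord,
    config: SimConfig,
    id_prefix: str = "sim",
) -> list[ReadPair]:
    """Generate paired-end reads at the configured depth.

    The pair count is exactly ``round(depth * len(genome) / (2 * read_len))``.
    Fragment starts are uniform; insert lengths are Normal(insert_mean,
    insert_sd) truncated to ``[2 * read_len, genome length]``.  R1 reads the
    fragment 5' end on the forward strand; R2 is the reverse complement of
    the fragment 3' end.
    """
    L = config.read_len
    if len(genome) <= config.insert_mean + 6 * config.insert_sd:
        raise ValueError("genome too short for the configured insert size distribution")
    rng = np.random.default_rng(config.seed)
    hap = mutate_genome(genome.seq, config, rng)
    arr = _encode(hap)
    g = len(arr)
    npairs = int(round(config.depth * len(genome) / (2 * L)))

    inserts = np.clip(
        np.round(rng.normal(config.insert_mean, config.insert_sd, size=npairs)),
        2 * L,
        g,
    ).astype(np.int64)
    starts = (rng.random(npairs) * (g - inserts + 1)).astype(np.int64)

    r1 = np.empty((npairs, L), dtype=np.uint8)
    r2 = np.empty((npairs, L), dtype=np.uint8)
    for i in range(npairs):
        s, ins = starts[i], inserts[i]
        r1[i] = arr[s : s + L]
        r2[i] = _COMP_CODES[arr[s + ins - L : s + ins]][::-1]

    ramp = _error_ramp(config)
    for mat in (r1, r2):
        # sequencing errors: substitute to one of the three other bases
        err = rng.random((npairs, L)) < ramp[None, :]
        shift = rng.integers(1, 4, size=(npairs, L), dtype=np.uint8)
        mat[err] = (mat[err] + shift[err]) % 4
        # whole-read replacement by random DNA (one end per draw)
        repl = rng.random(npairs) < config.random_read_prob
        k = int(repl.sum())
        if k:
            mat[repl] = rng.integers(0, 4, size=(k, L), dtype=np.uint8)
        # at most max_n_per_read positions become N
        if config.max_n_per_read > 0 and config.n_read_prob > 0:
            has_n = rng.random(npairs) < config.n_read_prob
            npos = rng.integers(0, L, size=npairs)
            rows = np.nonzero(has_n)[0]
            mat[rows, npos[rows]] = 4

    qual = _qual_string(config)
    pairs = [
        ReadPair(f"{id_prefix}:{genome.id}:{i}", _decode(r1[i]), qual, _decode(r2[i]), qual)
        for i in range(npairs)
    ]
    return pairs


def spike_reads(
    background: Sequence[ReadPair],
    spike: Sequence[ReadPair],
    seed: int = 0,
) -> list[ReadPair]:
    """Merge a spike-in read set into a background set, shuffled under seed."""
    ids = [p.pair_id for p in background] + [p.pair_id for p in spike]
    if len(set(ids)) != len(ids):
        raise ValueError("read id collision between background and spike sets")
    if background and spike and len(background[0].seq1) != len(spike[0].seq1):
        raise ValueError("read lengths differ between background and spike sets")
    merged = list(background) + list(spike)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(merged))
    return [merged[i] for i in order]


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def write_fastq_pair(pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_fastq_pair(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    def load(path):
        out = []
        with open(path) as fh:
            while True:
                h = fh.readline().rstrip()
                if not h:
                    break
                seq = fh.readline().rstrip()
                fh.readline()
                qual = fh.readline().rstrip()
                name = h[1:].split()[0]
                if name.endswith("/1") or name.endswith("/2"):
                    name = name[:-2]
                out.append((name, seq.upper(), qual))
        return out

    ends1, ends2 = load(path1), load(path2)
    if len(ends1) != len(ends2):
        raise ValueError("FASTQ mates have different record counts")
    pairs = []
    for (n1, s1, q1), (n2, s2, q2) in zip(ends1, ends2):
        if n1 != n2:
            raise ValueError(f"mate name mismatch: {n1!r} vs {n2!r}")
        pairs.append(ReadPair(n1, s1, q1, s2, q2))
    return pairs


# ---------------------------------------------------------------------------
# Built-in synthetic reference set
# ---------------------------------------------------------------------------

def make_references(
    seed: int = 0,
    host_len: int = 200_000,
    plasmid_len: int = 10_000,
) -> tuple[list[SequenceRecord], PlasmidMap, dict]:
    """Build the synthetic host + plasmid pair used throughout testing.

    The plasmid carries an 8 kb T-DNA (borders RB/LB) holding two
    host-homologous elements — an RNAi trigger copied from one host locus
    right at the T-DNA 5' terminus, and a native promoter copied into the
    cassette interior that also exists at two host loci — mimicking a
    construct whose ends are built from recipient-species DNA.  A 1.5 kb
    single-copy host interval is designated as the depth calibrator gene.

    Returns ``(host_records, plasmid_map, aux)`` where ``aux`` holds the
    calibrator interval, the planted homology intervals on the host, and the
    zone recommended for placing insertion sites.
    """
    from .refmodel import GenomicInterval, PlasmidElement

    if host_len < 40_000:
        raise ValueError("host_len must be at least 40 kb")
    rng = np.random.default_rng(seed)
    host_arr = rng.integers(0, 4, size=host_len, dtype=np.uint8)

    # planted homologies: native promoter at two loci, RNAi trigger at one
    # (positions scale with the host so small test genomes keep the layout)
    prom_len, rnai_len = 400, 300
    prom_loci = [host_len // 10, host_len // 4]
    rnai_locus = int(host_len * 0.4)
    promoter = host_arr[prom_loci[0] : prom_loci[0] + prom_len].copy()
    host_arr[prom_loci[1] : prom_loci[1] + prom_len] = promoter
    rnai = host_arr[rnai_locus : rnai_locus + rnai_len].copy()

    host = SequenceRecord("chr1", _decode(host_arr))

    plas_arr = rng.integers(0, 4, size=plasmid_len, dtype=np.uint8)
    t0, t1 = 1000, 9000
    # gene-scale cassette elements: ADT sampling noise falls as 1/sqrt(len)
    layout = [
        ("RB", t0, t0 + 25, "+"),
        ("CYP81A6-RNAi", t0 + 40, t0 + 40 + rnai_len, "+"),
        ("CaMV35S", t0 + 400, t0 + 1200, "+"),
        ("hLF", t0 + 1300, t0 + 3300, "+"),
        ("G6-EPSPS", t0 + 3400, t0 + 5400, "+"),
        ("ZmUbi", t0 + 5500, t0 + 6700, "+"),
        ("Gt1-promoter", t0 + 6800, t0 + 6800 + prom_len, "+"),
        ("PEPC", t0 + 7300, t0 + 7900, "+"),
        ("LB", t1 - 25, t1, "+"),
        ("Ori", t1 + 200, t1 + 800, "+"),  # backbone replication origin
    ]
    plas_arr[t0 + 40 : t0 + 40 + rnai_len] = rnai
    plas_arr[t0 + 6800 : t0 + 6800 + prom_len] = promoter
    plasmid = SequenceRecord("plasmid", _decode(plas_arr), circular=True)
    pmap = PlasmidMap(
        plasmid=plasmid,
        tdna=(t0, t1),
        elements=[PlasmidElement(*row) for row in layout],
    )

    # gene-scale single-copy calibrator: its ADT noise is common to every
    # element's calibrated value, so it gets the longest interval
    sps_start = int(host_len * 0.8)
    sps = GenomicInterval("chr1", sps_start, sps_start + 4000, "+")
    aux = {
        "sps_interval": sps,
        "homolog_host_intervals": [
            GenomicInterval("chr1", s, s + prom_len) for s in prom_loci
        ] + [GenomicInterval("chr1", rnai_locus, rnai_locus + rnai_len)],
        "site_zone": (int(host_len * 0.475), int(host_len * 0.75)),
    }
    return [host], pmap, aux
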