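"""Chimeric-pair extraction, blacklist filtering, clustering, noise rejection.

The junction stage turns classified read pairs into integration-region
candidates: it keeps the pairs with one host end and one plasmid end, drops
those explained by plasmid-host homology (blacklist), single-links the
remaining host-side positions into clusters at the insert-size scale, and
rejects sporadic clusters whose support is incompatible with the sequencing
depth — real junctions are crossed by a sizeable fraction of the local
fragment population, while noise and alignment jitter produce isolated
pairs.  Every discarded pair and cluster carries a reason code, and
kept + discarded always equals the input count.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .homology import Blacklist, in_blacklist
from .mapping import PairAlignment, ReferenceIndex, map_read
from .refmodel import GenomicInterval

__all__ = [
    "CandidateCluster",
    "cluster_candidates",
    "consistency_check",
    "extract_chimeric",
    "filter_native",
    "filter_sporadic",
]

REASON_HOMOLOGY = "homologous sequence (blacklist)"
REASON_NOISE = "noise sequences/alignment jitter"


@dataclass
class CandidateCluster:
    """Chimeric pairs whose host-side positions co-locate on one chromosome."""

    host_chr: str
    span: GenomicInterval
    support: int
    members: list[PairAlignment] = field(default_factory=list)
    unique_support: int = 0
    verdict: str = "unchecked"

    @property
    def member_ids(self) -> list[str]:
        return [m.pair_id for m in self.members]


def extract_chimeric(pairs: Sequence[PairAlignment]) -> list[PairAlignment]:
    """Pairs with one end on the host and the other on the plasmid."""
    return [p for p in pairs if p.pair_class == "chimeric_host_plasmid"]


def filter_native(
    chimeric: Sequence[PairAlignment],
    blacklist: Blacklist,
    side: str = "host",
) -> tuple[list[PairAlignment], list[tuple[PairAlignment, str]]]:
    """Split chimeric pairs into (kept, discarded-with-reason) by the blacklist.

    ``side`` selects which end's position is tested: ``"host"`` (default)
    discards a pair when its host-side end falls in a blacklisted host
    interval; ``"plasmid"`` tests the plasmid-side end; ``"both"`` discards
    when either end is blacklisted.  Host-side filtering is the default
    because the plasmid terminus element may itself be host-homologous (a
    construct built from recipient DNA), in which case every true junction
    pair has a blacklisted plasmid end but a clean host position.
    """
    if side not in {"host", "plasmid", "both"}:
        raise ValueError(f"invalid side {side!r}")
    kept: list[PairAlignment] = []
    discarded: list[tuple[PairAlignment, str]] = []
    for p in chimeric:
        hit_host = p.host_end is not None and p.host_end.mapped and in_blacklist(
            blacklist, p.host_end.ref_id, p.host_end.pos
        )
        hit_plasmid = p.plasmid_end is not None and p.plasmid_end.mapped and in_blacklist(
            blacklist, p.plasmid_end.ref_id, p.plasmid_end.pos
        )
        drop = {"host": hit_host, "plasmid": hit_plasmid, "both": hit_host or hit_plasmid}[side]
        if drop:
            discarded.append((p, REASON_HOMOLOGY))
        else:
            kept.append(p)
    return kept, discarded


def cluster_candidates(
    kept: Sequence[PairAlignment],
    cluster_window: int = 500,
    read_len: int = 100,
) -> list[CandidateCluster]:
    """Single-linkage clustering of host-side positions per chromosome.

    Two pairs join the same cluster when their host positions are within
    ``cluster_window`` (the physical scale of junction-spanning fragments).
    Clusters are returned sorted by support, descending.
    """
    by_chr: dict[str, list[PairAlignment]] = {}
    for p in kept:
        if p.host_end is None or not p.host_end.mapped:
            continue
        by_chr.setdefault(p.host_end.ref_id, []).append(p)
    clusters: list[CandidateCluster] = []
    for chrom, members in by_chr.items():
        members.sort(key=lambda p: p.host_end.pos)
        group: list[PairAlignment] = []
        for p in members:
            if group and p.host_end.pos - group[-1].host_end.pos > cluster_window:
                clusters.append(_make_cluster(chrom, group, read_len))
                group = []
            group.append(p)
        if group:
            clusters.append(_make_cluster(chrom, group, read_len))
    clusters.sort(key=lambda c: (-c.support, c.host_chr, c.span.start))
    return clusters


def _make_cluster(chrom: str, group: list[PairAlignment], read_len: int) -> CandidateCluster:
    lo = group[0].host_end.pos
    hi = max(p.host_end.pos for p in group) + read_len
    uniq = sum(1 for p in group if p.end1.unique and p.end2.unique)
    return CandidateCluster(chrom, GenomicInterval(chrom, lo, hi), len(group), group, uniq)


def filter_sporadic(
    clusters: Sequence[CandidateCluster],
    depth_d: float,
    min_abs: int = 3,
    min_frac: float = 0.1,
) -> tuple[list[CandidateCluster], list[tuple[CandidateCluster, str]]]:
    """Reject clusters whose support is sporadic relative to sequencing depth.

    A cluster survives when its support reaches both an absolute floor and a
    fraction of the genome depth, and at least ``min_abs`` members are
    uniquely mapped at both ends.
    """
    if depth_d <= 0:
        raise ValueError("depth must be positive")
    threshold = max(min_abs, min_frac * depth_d)
    kept, rejected = [], []
    for c in clusters:
        if c.support >= threshold and c.unique_support >= min_abs:
            kept.append(c)
        else:
            rejected.append((c, REASON_NOISE))
    return kept, rejected


def consistency_check(
    cluster: CandidateCluster,
    index: ReferenceIndex | None = None,
    insert_mean: float = 500.0,
    max_mismatch_frac: float = 0.1,
) -> str:
    """Verdict ``"consistent"`` or ``"contradictory"`` for one cluster.

    Members are re-aligned (all best hits) when an index is supplied.  The
    cluster is contradictory when no member is uniquely mapped at both ends,
    when host-side positions spread beyond 3x the insert size, or when
    within a host-strand group the plasmid-side positions scatter beyond 3x
    the insert size (paired ends at a real junction sample one compact
    plasmid neighbourhood per flank).
    """
    if cluster.unique_support == 0:
        cluster.verdict = "contradictory"
        return cluster.verdict

    host_pos: list[int] = []
    by_strand: dict[str, list[int]] = {}
    for m in cluster.members:
        h, p = m.host_end, m.plasmid_end
        if h is None or p is None:
            continue
        if index is not None and h.seq is not None:
            hits = [a for a in map_read(h.seq, index, max_mismatch_frac)
                    if a.ref_id == cluster.host_chr]
            if not hits:
                continue
            h = min(hits, key=lambda a: abs(a.pos - cluster.span.start))
        host_pos.append(h.pos)
        by_strand.setdefault(h.strand, []).append(p.pos)

    if not host_pos:
        cluster.verdict = "contradictory"
        return cluster.verdict
    if max(host_pos) - min(host_pos) > 3 * insert_mean:
        cluster.verdict = "contradictory"
        return cluster.verdict
    for positions in by_strand.values():
        if max(positions) - min(positions) > 3 * insert_mean:
            cluster.verdict = "contradictory"
            return cluster.verdict
    cluster.verdict = "consistent"
    return cluster.verdict


def export_audit_tsv(
    kept_clusters: Sequence[CandidateCluster],
    rejected: Sequence[tuple[CandidateCluster, str]],
    discarded_pairs: Sequence[tuple[PairAlignment, str]],
    path: str | Path,
) -> None:
    """Per-chromosome audit table: unfiltered vs surviving pair counts + reason."""
    rows: dict[str, dict[str, object]] = {}

    def row(chrom: str) -> dict[str, object]:
        return rows.setdefault(chrom, {"not_filtered": 0, "filtered": 0, "reason": ""})

    for c in kept_clusters:
        r = row(c.host_chr)
        r["not_filtered"] = int(r["not_filtered"]) + c.support
        r["filtered"] = int(r["filtered"]) + c.support
        r["reason"] = "candidate"
    for c, reason in rejected:
        r = row(c.host_chr)
        r["not_filtered"] = int(r["not_filtered"]) + c.support
        r["filtered"] = int(r["filtered"]) + c.support
        if not r["reason"]:
            r["reason"] = reason
    for p, reason in discarded_pairs:
        chrom = p.host_end.ref_id if p.host_end and p.host_end.mapped else "?"
        r = row(chrom)
        r["not_filtered"] = int(r["not_filtered"]) + 1
        if r["reason"] != "candidate":
            r["reason"] = reason
    with open(path, "w") as fh:
        fh.write("chr\tnot_filtered\tfiltered\treason\n")
        for chrom in sorted(rows):
            r = rows[chrom]
            fh.write(f"{chrom}\t{r['not_filtered']}\t{r['filtered']}\t{r['reason']}\n")
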