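"""End-to-end characterization pipeline: one call from reads to report.

Stages run in method order — mapping/classification, homology blacklist,
chimeric-pair filtering and clustering, junction assembly, copy-number
estimation, backbone scan — mirroring the count narrative a reviewer audits:
total pairs, plasmid-mapped, chimeric, blacklist-surviving, clustered,
candidate.  A wild-type control, when provided, is processed identically and
differenced: its surviving candidates measure the false-positive background
and its element depths supply the wild-type terms of the copy-number
formulas.  Every number in the report is recomputed from the inputs; the
pipeline is fully deterministic given reads and configuration.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .assembly import (IntegrationCall, SplitAligner, assemble_contigs,
                       call_integration, call_junction, format_report,
                       polish_contigs)
from .backbone import BackboneReport, scan_backbone
from .copynumber import CopyNumberResult, copy_number_table, round_half_up
from .homology import (Blacklist, build_blacklist, export_blacklist,
                       export_blocks_tsv, find_homology_blocks)
from .junction import (CandidateCluster, cluster_candidates, consistency_check,
                       export_audit_tsv, extract_chimeric, filter_native,
                       filter_sporadic)
from .mapping import (EndAlignment, PairAlignment, ReferenceIndex,
                      average_target_depth, coverage_calibrator, general_depth,
                      map_pair)
from .refmodel import GenomicInterval, PlasmidMap, SequenceRecord, write_fasta
from .simulate import ReadPair

log = logging.getLogger("tdnakit")

__all__ = ["PipelineConfig", "SampleResult", "characterize", "write_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters for every stage, with the documented defaults."""

    read_len: int = 100
    k: int = 31
    max_mismatch_frac: float = 0.1
    word_size: int = 16
    hom_min_identity: float = 0.9
    min_block_len: int = 50
    margin: int = 500
    filter_side: str = "host"
    cluster_window: int = 500
    min_abs: int = 3
    min_frac: float = 0.1
    insert_mean: float = 500.0
    min_overlap: int = 30
    asm_min_identity: float = 0.90   # pairwise overlaps carry both reads' errors
    split_min_identity: float = 0.95
    min_element_len: int = 200
    backbone_min_depth_frac: float = 0.3
    backbone_min_span: int = 200


@dataclass
class SampleResult:
    """Per-sample stage outputs and audit counts."""

    name: str
    alignments: list[PairAlignment]
    counts: dict[str, int]
    depth_d: float
    calibrator_r: float
    adt: dict[str, float]
    clusters: list[CandidateCluster]
    candidates: list[CandidateCluster]
    rejected: list[tuple[CandidateCluster, str]]
    discarded_pairs: list[tuple[PairAlignment, str]]
    plasmid_ends: list[EndAlignment]

    @property
    def depth_stats(self) -> "DepthStats":
        from .mapping import DepthStats
        return DepthStats(self.depth_d, self.calibrator_r, dict(self.adt))


def _plasmid_coverage(ends: Sequence[EndAlignment], plen: int) -> np.ndarray:
    cov = np.zeros(plen, dtype=np.int64)
    for a in ends:
        lo, hi = a.pos, a.pos + a.matched_len
        if hi <= plen:
            cov[lo:hi] += 1
        else:
            cov[lo:plen] += 1
            cov[: hi - plen] += 1
    return cov


def _analyze_sample(
    name: str,
    pairs: Sequence[ReadPair],
    index: ReferenceIndex,
    plasmid_map: PlasmidMap,
    blacklist: Blacklist,
    sps_interval: GenomicInterval | None,
    host_len: int,
    cfg: PipelineConfig,
) -> SampleResult:
    pid = plasmid_map.plasmid.id
    plasmid_ids = {pid}
    alignments = [
        map_pair(p.pair_id, p.seq1, p.seq2, index, plasmid_ids, cfg.max_mismatch_frac)
        for p in pairs
    ]
    by_class: dict[str, int] = {}
    for a in alignments:
        by_class[a.pair_class] = by_class.get(a.pair_class, 0) + 1

    total = len(alignments)
    depth_d = general_depth(total, cfg.read_len, host_len)
    r = coverage_calibrator(by_class.get("both_host", 0), total) if total else 0.0

    plasmid_ends = [
        e for a in alignments for e in (a.end1, a.end2)
        if e.mapped and e.ref_id == pid
    ]
    plen = len(plasmid_map.plasmid)
    cov = _plasmid_coverage(plasmid_ends, plen)
    adt: dict[str, float] = {}
    for el in plasmid_map.elements:
        adt[el.name] = float(cov[el.start : el.end].mean())
    if sps_interval is not None:
        host_ends = [
            e for a in alignments for e in (a.end1, a.end2)
            if e.mapped and e.ref_id == sps_interval.ref_id
        ]
        adt["SPS"] = average_target_depth(host_ends, sps_interval)

    chimeric = extract_chimeric(alignments)
    kept, discarded = filter_native(chimeric, blacklist, side=cfg.filter_side)
    clusters = cluster_candidates(kept, cfg.cluster_window, cfg.read_len)
    survivors, rejected = filter_sporadic(clusters, depth_d, cfg.min_abs, cfg.min_frac)
    candidates = []
    for c in survivors:
        verdict = consistency_check(c, index, cfg.insert_mean, cfg.max_mismatch_frac)
        if verdict == "consistent":
            candidates.append(c)
        else:
            rejected.append((c, "contradictory paired-end geometry"))

    counts = {
        "total_pairs": total,
        **{k: by_class.get(k, 0) for k in
           ("both_host", "both_plasmid", "chimeric_host_plasmid",
            "one_unmapped", "both_unmapped")},
        "chimeric_kept": len(kept),
        "chimeric_discarded": len(discarded),
        "clusters": len(clusters),
        "candidate_clusters": len(candidates),
    }
    log.info(
        "%s: %d pairs -> %d plasmid, %d chimeric, %d kept after blacklist, "
        "%d clusters, %d candidates",
        name, total, by_class.get("both_plasmid", 0),
        by_class.get("chimeric_host_plasmid", 0), len(kept),
        len(clusters), len(candidates),
    )
    return SampleResult(name, alignments, counts, depth_d, r, adt,
                        clusters, candidates, rejected, discarded, plasmid_ends)


def _recruit_unmapped_mates(
    alignments: Sequence[PairAlignment],
    cluster: CandidateCluster,
    plasmid_map: PlasmidMap,
    cfg: PipelineConfig,
) -> list[str]:
    """Unmapped reads whose mapped mate anchors near the candidate junction.

    A read crossing the junction itself maps to neither reference under
    full-length ungapped alignment, so the junction base itself is carried
    only by the unmapped mates of anchored pairs: host anchors within one
    insert size of the cluster span, or plasmid anchors within one insert
    size of a T-DNA terminus.
    """
    pid = plasmid_map.plasmid.id
    plen = len(plasmid_map.plasmid)
    t5, t3 = plasmid_map.tdna[0], plasmid_map.tdna[1] - 1
    reach = int(cfg.insert_mean)
    lo, hi = cluster.span.start - reach, cluster.span.end + reach
    out: list[str] = []
    for pa in alignments:
        if pa.pair_class != "one_unmapped":
            continue
        mapped, unmapped = (pa.end1, pa.end2) if pa.end1.mapped else (pa.end2, pa.end1)
        if unmapped.seq is None:
            continue
        if mapped.ref_id == cluster.host_chr and lo <= mapped.pos <= hi:
            out.append(unmapped.seq)
        elif mapped.ref_id == pid:
            d = min(
                min((mapped.pos - t) % plen, (t - mapped.pos) % plen)
                for t in (t5, t3)
            )
            if d <= reach:
                out.append(unmapped.seq)
    return out


def characterize(
    hosts: Sequence[SequenceRecord],
    plasmid_map: PlasmidMap,
    gm_pairs: Sequence[ReadPair],
    wt_pairs: Sequence[ReadPair] | None = None,
    sps_interval: GenomicInterval | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full characterization and return the report dictionary.

    ``gm_pairs`` are the transgenic sample's read pairs; ``wt_pairs`` is the
    strongly recommended wild-type control (its absence is recorded and the
    wild-type terms of the copy-number formulas become zero).
    ``sps_interval`` locates the single-copy endogenous calibrator gene on
    the host; without it only raw copy numbers are available.
    """
    cfg = config or PipelineConfig()
    plasmid_rec = plasmid_map.plasmid
    refs = list(hosts) + [plasmid_rec]
    index = ReferenceIndex(refs, k=cfg.k)
    host_len = sum(len(h) for h in hosts)
    ref_lengths = {r.id: len(r) for r in refs}

    blocks = find_homology_blocks(
        plasmid_rec, hosts, cfg.word_size, cfg.hom_min_identity, cfg.min_block_len
    )
    blacklist = build_blacklist(blocks, cfg.margin, ref_lengths, plasmid_rec.id)
    log.info("homology: %d blocks, %d blacklisted bases", len(blocks), blacklist.total_bases())

    gm = _analyze_sample("gm", gm_pairs, index, plasmid_map, blacklist,
                         sps_interval, host_len, cfg)
    wt = None
    if wt_pairs is not None:
        wt = _analyze_sample("wt", wt_pairs, index, plasmid_map, blacklist,
                             sps_interval, host_len, cfg)
    else:
        warnings.warn("no wild-type control supplied; copy numbers use zero wt terms")

    # ---- copy number ------------------------------------------------------
    copy_rows: list[CopyNumberResult] = []
    copy_estimate: float | None = None
    tdna_lo, tdna_hi = plasmid_map.tdna
    cassette = {
        el.name: len(el) for el in plasmid_map.elements
        if el.start >= tdna_lo and el.end <= tdna_hi and len(el) >= cfg.min_element_len
    }
    if "SPS" in gm.adt and gm.adt["SPS"] > 0:
        adt_gm = {k: v for k, v in gm.adt.items()}
        adt_wt = {k: v for k, v in (wt.adt if wt else {}).items()}
        copy_rows = copy_number_table(
            adt_gm, adt_wt,
            d_gm=gm.depth_d, r_gm=gm.calibrator_r,
            d_wt=wt.depth_d if wt else None, r_wt=wt.calibrator_r if wt else None,
        )
        # length-weighted: equivalent to one ADT over the cassette union,
        # so short elements do not dominate the sampling noise
        vals = [(r.calibrated, cassette[r.element]) for r in copy_rows
                if r.element in cassette]
        if vals:
            wsum = sum(w for _, w in vals)
            copy_estimate = float(sum(v * w for v, w in vals) / wsum)

    # ---- junction assembly ------------------------------------------------
    integration: IntegrationCall | None = None
    contigs: list[str] = []
    if gm.candidates:
        top = gm.candidates[0]
        reads = [s for m in top.members for s in (m.end1.seq, m.end2.seq) if s]
        reads += _recruit_unmapped_mates(gm.alignments, top, plasmid_map, cfg)
        contigs = assemble_contigs(reads, cfg.min_overlap, cfg.asm_min_identity)
        contigs = polish_contigs(contigs, reads)
        aligner = SplitAligner(hosts, plasmid_map)
        junctions = [
            j for j in (
                call_junction(c, aligner, cfg.min_overlap, cfg.split_min_identity)
                for c in contigs
            )
            if j is not None
        ]
        # only junctions in the candidate cluster's neighbourhood belong to
        # this event; homologous fragments can split-align elsewhere
        reach = int(cfg.insert_mean)
        junctions = [
            j for j in junctions
            if j.host_ref == top.host_chr
            and top.span.start - reach <= j.breakpoint_host <= top.span.end + reach
        ]
        if junctions:
            integration = call_integration(junctions, copy_estimate)

    # ---- backbone ----------------------------------------------------------
    bb: BackboneReport = scan_backbone(
        gm.plasmid_ends, plasmid_map, gm.depth_d,
        cfg.backbone_min_depth_frac, cfg.backbone_min_span,
    )

    report = {
        "params": dataclasses.asdict(cfg),
        "wild_type_control": wt is not None,
        "gm": _sample_section(gm),
        "wt": _sample_section(wt) if wt else None,
        "homology_blocks": len(blocks),
        "blacklist_bases": blacklist.total_bases(),
        "integration": _integration_section(integration),
        "copy_number": [
            {
                "element": r.element,
                "calibrated": round_half_up(r.calibrated),
                "raw": None if r.raw_eq is None else round_half_up(r.raw_eq, 3),
                "rounded": r.rounded,
            }
            for r in copy_rows
        ],
        "copy_number_estimate": None if copy_estimate is None
        else round_half_up(copy_estimate, 3),
        "backbone": bb.to_dict(),
    }
    if outdir is not None:
        write_report(report, outdir, gm=gm, wt=wt, blocks=blocks,
                     blacklist=blacklist, contigs=contigs,
                     integration=integration, plasmid_map=plasmid_map,
                     backbone=bb)
    return report


def _sample_section(s: SampleResult | None) -> dict | None:
    if s is None:
        return None
    return {
        "counts": s.counts,
        "depth_d": round(s.depth_d, 3),
        "calibrator_r": round(s.calibrator_r, 4),
        "adt": {k: round(v, 3) for k, v in sorted(s.adt.items())},
        "candidates": [
            {
                "chr": c.host_chr,
                "span": [c.span.start, c.span.end],
                "support": c.support,
                "unique_support": c.unique_support,
                "verdict": c.verdict,
            }
            for c in s.candidates
        ],
        "rejected_clusters": [
            {"chr": c.host_chr, "support": c.support, "reason": reason}
            for c, reason in s.rejected
        ],
    }


def _integration_section(call: IntegrationCall | None) -> dict | None:
    if call is None:
        return None
    return {
        "chr": call.chrom,
        "locus_1based": call.locus,
        "deletion_len": call.deletion_len,
        "element_5p": call.element_5p,
        "element_3p": call.element_3p,
        "strand_5p": call.strand_5p,
        "strand_3p": call.strand_3p,
        "arrangement": call.arrangement,
        "copy_number": None if call.copy_number is None
        else round(call.copy_number, 3),
        "n_junction_contigs": len(call.contigs),
        "contig_lengths": sorted((len(c.seq) for c in call.contigs), reverse=True),
    }


def write_report(report: dict, outdir: str | Path, **artifacts) -> None:
    """Write report.json + report.md and the per-stage artifact files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    lines = ["# Integration characterization report", ""]
    integ = report.get("integration")
    if integ:
        lines += ["## Integration call", ""]
        call = artifacts.get("integration")
        if call is not None:
            lines += ["```", format_report(call), "```", ""]
    else:
        lines += ["No integration call (no consistent candidate cluster).", ""]
    lines += ["## Copy number", "", "| element | calibrated | raw | rounded |",
              "|---|---|---|---|"]
    for row in report["copy_number"]:
        lines.append(
            f"| {row['element']} | {row['calibrated']} | {row['raw']} | {row['rounded']} |"
        )
    lines += ["", f"Backbone verdict: **{report['backbone']['verdict']}**", ""]
    with open(out / "report.md", "w") as fh:
        fh.write("\n".join(lines))

    pm: PlasmidMap | None = artifacts.get("plasmid_map")
    if artifacts.get("blocks") is not None:
        export_blocks_tsv(artifacts["blocks"], out / "homology_blocks.tsv")
    if artifacts.get("blacklist") is not None and pm is not None:
        export_blacklist(artifacts["blacklist"], out / "blacklist.bed",
                         pm.plasmid.id, out / "blacklist_plasmid.tsv")
    if artifacts.get("contigs"):
        write_fasta(
            [SequenceRecord(f"contig_{i+1}", c)
             for i, c in enumerate(artifacts["contigs"])],
            out / "contigs.fasta",
        )
    for key in ("gm", "wt"):
        s: SampleResult | None = artifacts.get(key)
        if s is not None:
            export_audit_tsv(s.candidates, s.rejected, s.discarded_pairs,
                             out / f"audit_{key}.tsv")
    bb: BackboneReport | None = artifacts.get("backbone")
    if bb is not None and pm is not None and bb.coverage is not None:
        from .backbone import write_bedgraph
        write_bedgraph(bb, pm.plasmid.id, out / "plasmid_coverage.bedgraph")
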