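"""circRNA back-splice junction detection from SAM/BAM alignments.

A back-splice junction (BSJ) is evidenced by a paired chiastic clipping
(PCC) signal: one read aligned as two same-chromosome segments whose
genomic order is inverted relative to their order along the read, as a
primary + SA-tagged supplementary record pair.  Candidates are then
filtered by paired-end mapping (the mate must lie inside the candidate
circle; skipped for single-end data), by the AG/GT splice motif and by
annotated exon boundaries, and quantified as spliced reads per billion
mapped reads (SRPBM).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .reference import ReferenceBundle, splice_motif_at

log = logging.getLogger(__name__)

_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _parse_cigar(cig: str) -> list[tuple[int, int]]:
    ops = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}
    return [(ops[op], int(n)) for n, op in _CIG_RE.findall(cig)]


def _cigar_stats(cigartuples) -> tuple[int, int, int]:
    """(leading clip as written, reference span, aligned query length)."""
    leading = 0
    for op, n in cigartuples:
        if op in (4, 5):
            leading += n
        else:
            break
    ref_span = sum(n for op, n in cigartuples if op in (0, 2, 3, 7, 8))
    q_aln = sum(n for op, n in cigartuples if op in (0, 1, 7, 8))
    return leading, ref_span, q_aln


@dataclass
class LibraryStats:
    """Totals for one sequencing library."""

    n_total: int            # primary mapped records (QC-passing read ends)
    role: str = "INPUT"     # "IP" or "INPUT"

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("N_total must be > 0")


@dataclass
class BsjEvidence:
    """Read support for one candidate back-splice junction."""

    chrom: str
    bsj_start: int   # acceptor, genomic 0-based
    bsj_end: int     # donor, genomic, exclusive
    # supporting read ends: (qname, is_read2)
    reads: set[tuple[str, bool]] = field(default_factory=set)

    @property
    def n_bsj(self) -> int:
        return len(self.reads)


@dataclass
class CircRNACall:
    """An annotated, quantified circRNA call."""

    chrom: str
    bsj_start: int
    bsj_end: int
    strand: str
    n_bsj: dict[str, int]          # per library role
    canonical_motif: bool
    exon_boundary: bool
    genes: list[str]
    gene_feature: str
    srpbm: dict[str, float] = field(default_factory=dict)

    @property
    def junction(self) -> tuple[str, int, int]:
        return (self.chrom, self.bsj_start, self.bsj_end)


def scan_library(
    bam_path: str | Path, min_segment: int = 20
) -> tuple[dict[tuple[str, int, int], BsjEvidence], LibraryStats, dict[str, int]]:
    """One pass over a BAM: PCC candidates plus library totals.

    A primary record with exactly one same-chromosome, same-strand SA
    segment contributes a junction when the segment earlier in the
    as-written query maps strictly downstream of the later one
    (chiastic order) and both aligned segments are at least
    ``min_segment`` bases.  A read end contributes to at most one
    junction.  Records without a stored sequence are skipped (counted).
    """
    candidates: dict[tuple[str, int, int], BsjEvidence] = {}
    counters = {"records": 0, "no_sequence": 0, "multi_segment": 0, "paired": 0}
    n_total = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if not bam.has_index() and bam.is_bam:
            raise ValueError(f"{bam_path}: coordinate-sorted, indexed BAM required")
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            counters["records"] += 1
            n_total += 1
            if rec.is_paired:
                counters["paired"] += 1
            if not rec.has_tag("SA"):
                continue
            if rec.query_sequence is None:
                counters["no_sequence"] += 1
                continue
            sa_entries = [s for s in rec.get_tag("SA").split(";") if s]
            if len(sa_entries) != 1:
                counters["multi_segment"] += 1
                continue
            sa_chrom, sa_pos, sa_strand, sa_cig, _mapq, _nm = sa_entries[0].split(",")
            if sa_chrom != rec.reference_name:
                continue
            if sa_strand != ("-" if rec.is_reverse else "+"):
                continue
            r_lead, r_span, r_qaln = _cigar_stats(rec.cigartuples)
            s_lead, s_span, s_qaln = _cigar_stats(_parse_cigar(sa_cig))
            if min(r_qaln, s_qaln) < min_segment:
                continue
            r_start, r_end = rec.reference_start, rec.reference_start + r_span
            s_start = int(sa_pos) - 1
            s_end = s_start + s_span
            if r_lead < s_lead:
                a = (r_start, r_end)   # earlier in query
                b = (s_start, s_end)   # later in query
            else:
                a = (s_start, s_end)
                b = (r_start, r_end)
            if a[0] < b[1]:            # not chiastic (colinear or overlapping)
                continue
            key = (rec.reference_name, b[0], a[1])
            ev = candidates.get(key)
            if ev is None:
                ev = candidates[key] = BsjEvidence(*key)
            ev.reads.add((rec.query_name, rec.is_read2))
    stats = LibraryStats(max(n_total, 1))
    stats.n_total = n_total  # allow 0 for empty files; SRPBM guards separately
    return candidates, stats, counters


def extract_bsj_candidates(
    bam_path: str | Path, min_segment: int = 20
) -> dict[tuple[str, int, int], BsjEvidence]:
    candidates, _, _ = scan_library(bam_path, min_segment)
    return candidates


def apply_pem_filter(
    candidates: dict[tuple[str, int, int], BsjEvidence],
    bam_path: str | Path,
    paired: bool | None = None,
) -> dict[tuple[str, int, int], BsjEvidence]:
    """Paired-end mapping filter.

    A supporting read end is kept only when its mate aligns entirely
    (all aligned segments) within [bsj_start, bsj_end) on the same
    chromosome.  With single-end data the filter is skipped and the
    input returned unchanged.  Support can only shrink; candidates with
    no remaining support are removed.
    """
    if not candidates:
        return candidates
    wanted: dict[tuple[str, bool], list[tuple[str, int, int]]] = {}
    for key, ev in candidates.items():
        for qname, is_read2 in ev.reads:
            wanted.setdefault((qname, not is_read2), []).append(key)
    mate_spans: dict[tuple[str, bool], list[tuple[str, int, int]]] = {}
    any_paired = False
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.is_paired:
                any_paired = True
            k = (rec.query_name, rec.is_read2)
            if k in wanted:
                mate_spans.setdefault(k, []).append(
                    (rec.reference_name, rec.reference_start, rec.reference_end)
                )
    if paired is None:
        paired = any_paired
    if not paired:
        return candidates
    out: dict[tuple[str, int, int], BsjEvidence] = {}
    for key, ev in candidates.items():
        chrom, s, e = key
        kept = set()
        for qname, is_read2 in ev.reads:
            spans = mate_spans.get((qname, not is_read2))
            if spans and all(c == chrom and s <= a and b <= e for c, a, b in spans):
                kept.add((qname, is_read2))
        if kept:
            out[key] = BsjEvidence(chrom, s, e, kept)
    return out


def annotate_and_filter(
    candidates: dict[tuple[str, int, int], BsjEvidence],
    ref: ReferenceBundle,
    require_canonical: bool = True,
    require_boundary: bool = True,
    library_role: str = "INPUT",
) -> list[CircRNACall]:
    """Attach motif/boundary flags and host genes; drop failing calls."""
    anno = ref.annotation
    calls: list[CircRNACall] = []
    for (chrom, s, e), ev in sorted(candidates.items()):
        if chrom not in ref.genome:
            log.warning("candidate on %s absent from reference; dropped", chrom)
            continue
        try:
            motif = splice_motif_at(ref, chrom, s, e)
        except IndexError:
            log.warning("junction %s:%d-%d at contig edge; dropped", chrom, s, e)
            continue
        boundary = anno.is_exon_start(chrom, s) and anno.is_exon_end(chrom, e)
        if require_canonical and not motif.canonical:
            continue
        if require_boundary and not boundary:
            continue
        calls.append(
            CircRNACall(
                chrom, s, e, motif.strand, {library_role: ev.n_bsj},
                motif.canonical, boundary,
                anno.host_genes(chrom, s, e), anno.gene_feature(chrom, s, e),
            )
        )
    return calls


def quantify_srpbm(n_bsj: int, stats: LibraryStats) -> float:
    """Spliced reads per billion mapped reads: N_BSJ / N_total * 1e9."""
    if stats.n_total <= 0:
        raise ValueError("library has no mapped reads")
    return n_bsj / stats.n_total * 1e9


def multi_sample_filter(
    calls_by_sample: dict[str, dict[tuple[str, int, int], int]],
    min_reads: int = 2,
    min_samples: int = 2,
) -> set[tuple[str, int, int]]:
    """Junctions with read count >= min_reads in >= min_samples samples."""
    if not calls_by_sample:
        raise ValueError("at least one sample required")
    tally: dict[tuple[str, int, int], int] = {}
    for counts in calls_by_sample.values():
        for junction, n in counts.items():
            if n >= min_reads:
                tally[junction] = tally.get(junction, 0) + 1
    return {j for j, k in tally.items() if k >= min_samples}


def circular_ratio(n_bsj: int, n_linear_donor: int, n_linear_acceptor: int) -> float | None:
    """Back-spliced fraction at a junction.

    ratio = N_BSJ / (N_BSJ + N_linear) with N_linear the mean count of
    colinear spliced reads using the same donor or acceptor site.
    Returns None (missing) when there is no evidence at all.
    """
    if min(n_bsj, n_linear_donor, n_linear_acceptor) < 0:
        raise ValueError("counts must be >= 0")
    n_linear = (n_linear_donor + n_linear_acceptor) / 2.0
    if n_bsj + n_linear == 0:
        return None
    return n_bsj / (n_bsj + n_linear)


def count_linear_junction_reads(
    bam_path: str | Path, junctions: list[tuple[str, int, int]]
) -> dict[tuple[str, int, int], tuple[int, int]]:
    """Colinear spliced-read counts at each junction's donor/acceptor.

    For a circle (s, e): acceptor usage = reads with an N gap ending at
    s (a linear intron spliced onto the same acceptor); donor usage =
    reads with an N gap starting at e.
    """
    acc_sites = {(c, s) for c, s, _ in junctions}
    don_sites = {(c, e) for c, _, e in junctions}
    acc_counts: dict[tuple[str, int], int] = {}
    don_counts: dict[tuple[str, int], int] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.cigartuples is None:
                continue
            pos = rec.reference_start
            for op, n in rec.cigartuples:
                if op == 3:  # N
                    gs, ge = pos, pos + n
                    if (rec.reference_name, ge) in acc_sites:
                        acc_counts[(rec.reference_name, ge)] = (
                            acc_counts.get((rec.reference_name, ge), 0) + 1
                        )
                    if (rec.reference_name, gs) in don_sites:
                        don_counts[(rec.reference_name, gs)] = (
                            don_counts.get((rec.reference_name, gs), 0) + 1
                        )
                if op in (0, 2, 3, 7, 8):
                    pos += n
    return {
        (c, s, e): (don_counts.get((c, e), 0), acc_counts.get((c, s), 0))
        for c, s, e in junctions
    }


@dataclass
class DetectionResult:
    calls: list[CircRNACall]
    stats: dict[str, LibraryStats]          # role -> stats
    counters: dict[str, dict[str, int]]


def detect_circrnas(
    input_bam: str | Path,
    ref: ReferenceBundle,
    ip_bam: str | Path | None = None,
    require_canonical: bool = True,
    require_boundary: bool = True,
    min_segment: int = 20,
    paired: bool | None = None,
) -> DetectionResult:
    """Full detection pipeline over an INPUT (and optional IP) library.

    With only RNA-seq (INPUT) data this is plain circRNA detection;
    when an IP library is supplied its junction evidence also seeds
    candidates and per-library BSJ counts are recorded on each call.
    """
    in_cands, in_stats, in_ctr = scan_library(input_bam, min_segment)
    in_stats.role = "INPUT"
    in_cands = apply_pem_filter(in_cands, input_bam, paired)
    stats = {"INPUT": in_stats}
    counters = {"INPUT": in_ctr}
    merged: dict[tuple[str, int, int], BsjEvidence] = dict(in_cands)
    ip_cands: dict[tuple[str, int, int], BsjEvidence] = {}
    if ip_bam is not None:
        ip_cands, ip_stats, ip_ctr = scan_library(ip_bam, min_segment)
        ip_stats.role = "IP"
        ip_cands = apply_pem_filter(ip_cands, ip_bam, paired)
        stats["IP"] = ip_stats
        counters["IP"] = ip_ctr
        for key, ev in ip_cands.items():
            if key not in merged:
                merged[key] = BsjEvidence(key[0], key[1], key[2], set())
    calls = annotate_and_filter(merged, ref, require_canonical, require_boundary)
    for call in calls:
        key = call.junction
        call.n_bsj = {"INPUT": in_cands[key].n_bsj if key in in_cands else 0}
        call.srpbm = {"INPUT": quantify_srpbm(call.n_bsj["INPUT"], in_stats)}
        if ip_bam is not None:
            call.n_bsj["IP"] = ip_cands[key].n_bsj if key in ip_cands else 0
            call.srpbm["IP"] = quantify_srpbm(call.n_bsj["IP"], stats["IP"])
    return DetectionResult(calls, stats, counters)


def write_calls_table(result: DetectionResult, path: str | Path) -> None:
    """Tab-delimited circRNA table (0-based half-open coordinates)."""
    roles = sorted(result.stats)
    with open(path, "w") as fh:
        cols = ["chrom", "start", "end", "strand"]
        cols += [f"n_bsj_{r.lower()}" for r in roles]
        cols += [f"srpbm_{r.lower()}" for r in roles]
        cols += ["canonical_motif", "exon_boundary", "genes", "gene_feature"]
        fh.write("\t".join(cols) + "\n")
        for c in result.calls:
            row = [c.chrom, c.bsj_start, c.bsj_end, c.strand]
            row += [c.n_bsj.get(r, 0) for r in roles]
            row += [f"{c.srpbm.get(r, 0.0):.4f}" for r in roles]
            row += [int(c.canonical_motif), int(c.exon_boundary),
                    ",".join(c.genes) or ".", c.gene_feature]
            fh.write("\t".join(str(x) for x in row) + "\n")
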