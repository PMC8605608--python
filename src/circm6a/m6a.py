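"""IP-vs-INPUT m6A enrichment calling in 25-bp genome bins.

The genome is tiled into fixed-width bins; for each bin of interest a
one-sided (greater-in-IP) Fisher's exact test compares read coverage
between IP and INPUT libraries on the 2x2 table

    [[ip_count,    N_total_IP    - ip_count],
     [input_count, N_total_INPUT - input_count]]

and p-values are Benjamini-Hochberg adjusted (q < 0.05 significant by
default).  Around each circRNA junction the two 100-bp flanks internal
to the circle are tested; significant bins are concatenated in circular
order and the circRNA is an m6A-circRNA candidate when the concatenated
run crosses the back-splice junction.  Confidence classes:

* low:  candidate with at least one junction read in IP
  (N_BSJ_IP >= 1);
* high: candidate with N_BSJ_IP >= 2 and a junction-read fraction at
  least as high in IP as in INPUT,
  (N_BSJ_IP/N_total_IP) / (N_BSJ_INPUT/N_total_INPUT) >= 1.

Linear m6A peaks are called over exonic bins with the same test in a
separate adjustment family, merging significant bins across single-bin
gaps.  Relative m6A level of a span is the ratio of IP to INPUT SRPBM
over that span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .detect import CircRNACall, DetectionResult, LibraryStats
from .reference import GenomeAnnotation, ReferenceBundle

DEFAULT_BIN = 25
DEFAULT_FLANK = 100
DEFAULT_FDR = 0.05


def genome_bin_counts(
    bam_path: str | Path, chrom_lengths: dict[str, int], bin_width: int = DEFAULT_BIN
) -> tuple[dict[str, np.ndarray], int]:
    """Per-bin read counts over the whole genome plus the library total.

    A read increments every bin one of its aligned blocks overlaps by
    at least one base (intron gaps skipped); junction-crossing reads
    contribute through both their primary and supplementary segments,
    i.e. on both sides of the junction.  The returned total counts
    primary mapped records only (the same QC as the detector).
    """
    counts = {
        c: np.zeros(length // bin_width + 1, dtype=np.int64)
        for c, length in chrom_lengths.items()
    }
    n_total = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary:
                continue
            if not rec.is_supplementary:
                n_total += 1
            arr = counts.get(rec.reference_name)
            if arr is None:
                continue
            seen_hi = -1
            for bs, be in rec.get_blocks():
                lo, hi = bs // bin_width, (be - 1) // bin_width
                if lo <= seen_hi:
                    lo = seen_hi + 1
                if lo > hi:
                    continue
                arr[lo : hi + 1] += 1
                seen_hi = hi
    return counts, n_total


def bin_coverage(
    bam_path: str | Path,
    chrom: str,
    start: int,
    end: int,
    chrom_length: int,
    bin_width: int = DEFAULT_BIN,
) -> list[tuple[int, int]]:
    """Read coverage of the bin-grid window containing [start, end).

    Returns (bin_start, count) pairs for the region expanded outward to
    whole bins.  Convenience wrapper over :func:`genome_bin_counts`
    semantics for a single region.
    """
    if start >= end:
        return []
    lo = (start // bin_width) * bin_width
    hi = -(-end // bin_width) * bin_width
    counts: dict[int, int] = {b: 0 for b in range(lo, min(hi, chrom_length), bin_width)}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for rec in bam.fetch(chrom, max(lo, 0), min(hi, chrom_length)):
            if rec.is_unmapped or rec.is_secondary:
                continue
            touched = set()
            for bs, be in rec.get_blocks():
                b0 = max(bs // bin_width, lo // bin_width)
                b1 = min((be - 1) // bin_width, (hi - 1) // bin_width)
                touched.update(range(b0, b1 + 1))
            for b in touched:
                if b * bin_width in counts:
                    counts[b * bin_width] += 1
    return sorted(counts.items())


def fisher_greater(
    ip_counts: np.ndarray, input_counts: np.ndarray, n_ip: int, n_input: int
) -> np.ndarray:
    """One-sided (enrichment in IP) Fisher exact p-values, vectorised.

    The one-sided Fisher p for the table [[a, n_ip - a], [b, n_input - b]]
    is the hypergeometric upper tail P(X >= a) with population
    n_ip + n_input, successes a + b and draws n_ip.
    """
    a = np.asarray(ip_counts, dtype=np.int64)
    b = np.asarray(input_counts, dtype=np.int64)
    if (a > n_ip).any() or (b > n_input).any():
        raise ValueError("bin count exceeds library total")
    return hypergeom.sf(a - 1, n_ip + n_input, a + b, n_ip)


def bin_enrichment_test(
    ip_count: int, input_count: int, ip_stats: LibraryStats, input_stats: LibraryStats
) -> float:
    """Fisher p for a single bin (see :func:`fisher_greater`)."""
    return float(
        fisher_greater(
            np.array([ip_count]), np.array([input_count]),
            ip_stats.n_total, input_stats.n_total,
        )[0]
    )


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def relative_m6a_level(
    ip_count: int, input_count: int, n_ip: int, n_input: int, pseudo_count: bool = True
) -> tuple[float | None, bool]:
    """IP SRPBM / INPUT SRPBM over a span; (level, pseudo_count_used).

    With zero INPUT coverage and pseudo-counting enabled, one read is
    added to both libraries' span counts (flagged); otherwise the level
    is reported missing.
    """
    used = False
    if input_count == 0:
        if not pseudo_count:
            return None, False
        ip_count, input_count, used = ip_count + 1, 1, True
    return (ip_count / n_ip) / (input_count / n_input), used


@dataclass
class M6aCircCall:
    """Enrichment-test result around one circRNA junction."""

    call: CircRNACall
    bins: list[tuple[str, int]]        # (chrom, bin_start) donor-side then acceptor-side
    q_values: list[float]
    significant: list[bool]
    spans_bsj: bool
    span_bins: list[tuple[str, int]]   # concatenated significant run through the BSJ
    confidence: str                    # none | low | high
    n_bsj_ip: int
    n_bsj_input: int
    fraction_ratio: float
    relative_level: float | None = None
    pseudo_count_used: bool = False

    @property
    def q_value(self) -> float:
        sig_q = [q for q, s in zip(self.q_values, self.significant) if s]
        return min(sig_q) if sig_q else (min(self.q_values) if self.q_values else 1.0)


@dataclass
class LinearPeak:
    """Merged run of significant exonic bins on the linear transcriptome."""

    chrom: str
    start: int
    end: int
    q_value: float
    relative_level: float | None = None
    pseudo_count_used: bool = False


def _flank_bins(call: CircRNACall, flank: int, bin_width: int) -> tuple[list[int], list[int]]:
    """Bin indices of the two junction flanks internal to the circle.

    Returns (donor_side, acceptor_side) ascending bin indices; flanks
    are truncated for circles shorter than two flank widths so the two
    sides never overlap.
    """
    span = call.bsj_end - call.bsj_start
    eff = min(flank, span // 2)
    eff = max(eff, 1)
    acc_lo = call.bsj_start // bin_width
    acc_hi = (call.bsj_start + eff - 1) // bin_width
    don_lo = (call.bsj_end - eff) // bin_width
    don_hi = (call.bsj_end - 1) // bin_width
    acceptor = list(range(acc_lo, acc_hi + 1))
    donor = [b for b in range(don_lo, don_hi + 1) if b > acc_hi]
    return donor, acceptor


def classify_confidence(
    spans_bsj: bool, n_bsj_ip: int, fraction_ratio: float
) -> str:
    if not spans_bsj:
        return "none"
    if n_bsj_ip >= 2 and fraction_ratio >= 1.0:
        return "high"
    if n_bsj_ip >= 1:
        return "low"
    return "none"


def call_m6a_circrnas(
    calls: list[CircRNACall],
    ip_bins: dict[str, np.ndarray],
    input_bins: dict[str, np.ndarray],
    n_ip: int,
    n_input: int,
    flank: int = DEFAULT_FLANK,
    bin_width: int = DEFAULT_BIN,
    fdr: float = DEFAULT_FDR,
    pseudo_count: bool = True,
) -> list[M6aCircCall]:
    """Test junction flanks of every circRNA and classify m6A-circRNAs.

    All flank bins of all candidate circRNAs form one BH adjustment
    family.  The two flanks are contiguous in circular order through
    the junction, so the concatenated significant run crosses the BSJ
    exactly when the donor-side bin adjacent to the junction and the
    acceptor-side bin adjacent to the junction are both significant.
    """
    per_call_bins: list[tuple[list[int], list[int]]] = []
    family: dict[tuple[str, int], int] = {}
    for call in calls:
        donor, acceptor = _flank_bins(call, flank, bin_width)
        per_call_bins.append((donor, acceptor))
        for b in donor + acceptor:
            family.setdefault((call.chrom, b), -1)
    keys = sorted(family)
    for i, k in enumerate(keys):
        family[k] = i
    ip_arr = np.array([ip_bins[c][b] for c, b in keys], dtype=np.int64)
    in_arr = np.array([input_bins[c][b] for c, b in keys], dtype=np.int64)
    if len(keys):
        p = fisher_greater(ip_arr, in_arr, n_ip, n_input)
        q = adjust_fdr(p)
    else:
        q = np.array([])
    sig = q < fdr

    results: list[M6aCircCall] = []
    for call, (donor, acceptor) in zip(calls, per_call_bins):
        ordered = donor + acceptor           # circular order through the BSJ
        idx = [family[(call.chrom, b)] for b in ordered]
        qs = [float(q[i]) for i in idx]
        ss = [bool(sig[i]) for i in idx]
        n_donor = len(donor)
        spans = bool(
            n_donor > 0
            and len(acceptor) > 0
            and ss[n_donor - 1]              # donor bin touching the junction
            and ss[n_donor]                  # acceptor bin touching the junction
        )
        span_bins: list[tuple[str, int]] = []
        if spans:
            i0 = n_donor - 1
            while i0 > 0 and ss[i0 - 1]:
                i0 -= 1
            i1 = n_donor
            while i1 + 1 < len(ordered) and ss[i1 + 1]:
                i1 += 1
            span_bins = [(call.chrom, b) for b in ordered[i0 : i1 + 1]]
        n_ip_bsj = call.n_bsj.get("IP", 0)
        n_in_bsj = call.n_bsj.get("INPUT", 0)
        if n_in_bsj == 0:
            ratio = math.inf if n_ip_bsj > 0 else 0.0
        else:
            ratio = (n_ip_bsj / n_ip) / (n_in_bsj / n_input)
        conf = classify_confidence(spans, n_ip_bsj, ratio)
        level, used = (None, False)
        if span_bins:
            ipc = int(sum(ip_bins[c][b] for c, b in span_bins))
            inc = int(sum(input_bins[c][b] for c, b in span_bins))
            level, used = relative_m6a_level(ipc, inc, n_ip, n_input, pseudo_count)
        results.append(
            M6aCircCall(
                call, [(call.chrom, b) for b in ordered], qs, ss, spans,
                span_bins, conf, n_ip_bsj, n_in_bsj, ratio, level, used,
            )
        )
    return results


def call_linear_peaks(
    annotation: GenomeAnnotation,
    ip_bins: dict[str, np.ndarray],
    input_bins: dict[str, np.ndarray],
    n_ip: int,
    n_input: int,
    bin_width: int = DEFAULT_BIN,
    fdr: float = DEFAULT_FDR,
    max_gap_bins: int = 1,
    pseudo_count: bool = True,
) -> list[LinearPeak]:
    """m6A peaks on the linear transcriptome.

    Exonic bins are tested as one BH family (separate from the circRNA
    family); adjacent significant bins are merged into peaks, tolerating
    gaps of up to ``max_gap_bins`` non-significant bins.
    """
    exonic: dict[str, set[int]] = {}
    for t in annotation.transcripts:
        bins = exonic.setdefault(t.chrom, set())
        for s, e in t.exons:
            bins.update(range(s // bin_width, (e - 1) // bin_width + 1))
    keys = [(c, b) for c in sorted(exonic) for b in sorted(exonic[c]) if c in ip_bins]
    if not keys:
        return []
    ip_arr = np.array([ip_bins[c][b] for c, b in keys], dtype=np.int64)
    in_arr = np.array([input_bins[c][b] for c, b in keys], dtype=np.int64)
    q = adjust_fdr(fisher_greater(ip_arr, in_arr, n_ip, n_input))
    sig = q < fdr

    peaks: list[LinearPeak] = []
    run: list[int] = []          # indices into keys of the current peak

    def close_run() -> None:
        if not run:
            return
        chrom = keys[run[0]][0]
        member = [i for i in run if sig[i]]
        b0, b1 = keys[member[0]][1], keys[member[-1]][1]
        ipc = int(sum(ip_bins[chrom][keys[i][1]] for i in member))
        inc = int(sum(input_bins[chrom][keys[i][1]] for i in member))
        level, used = relative_m6a_level(ipc, inc, n_ip, n_input, pseudo_count)
        peaks.append(
            LinearPeak(
                chrom, b0 * bin_width, (b1 + 1) * bin_width,
                float(min(q[i] for i in member)), level, used,
            )
        )

    last_sig: int | None = None
    for i, (c, b) in enumerate(keys):
        if not sig[i]:
            continue
        if (
            last_sig is not None
            and keys[last_sig][0] == c
            and b - keys[last_sig][1] <= max_gap_bins + 1
        ):
            run.append(i)
        else:
            close_run()
            run = [i]
        last_sig = i
    close_run()
    return peaks


def write_m6a_table(results: list[M6aCircCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tstrand\tn_bsj_ip\tn_bsj_input\tfraction_ratio\t"
            "spans_bsj\tconfidence\tq_value\trelative_m6a_level\tpseudo_count\n"
        )
        for r in results:
            c = r.call
            level = f"{r.relative_level:.4f}" if r.relative_level is not None else "NA"
            ratio = "inf" if math.isinf(r.fraction_ratio) else f"{r.fraction_ratio:.4f}"
            fh.write(
                f"{c.chrom}\t{c.bsj_start}\t{c.bsj_end}\t{c.strand}\t{r.n_bsj_ip}\t"
                f"{r.n_bsj_input}\t{ratio}\t{int(r.spans_bsj)}\t{r.confidence}\t"
                f"{r.q_value:.3e}\t{level}\t{int(r.pseudo_count_used)}\n"
            )


def write_peaks_bed(peaks: list[LinearPeak], path: str | Path) -> None:
    """Linear peaks as BED6 with score = -10*log10(q), capped at 1000."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = 1000 if p.q_value <= 0 else min(1000, int(-10 * math.log10(p.q_value)))
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{score}\t.\n")
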