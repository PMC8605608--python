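"""End-to-end benchmark pipeline: simulate -> detect -> call m6A -> score.

Wires the simulator's truth alignments straight into the detector so
the whole benchmark runs without an external aligner.  One master seed
deterministically derives all per-stage seeds; every run writes a
machine-readable copy of its resolved configuration next to its
outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pysam

from . import detect as _detect
from . import evaluate as _evaluate
from . import m6a as _m6a
from .reference import ReferenceBundle
from .simulate import SimConfig, build_sim_transcriptome, simulate_merip

log = logging.getLogger(__name__)


def sort_and_index(sam_path: str | Path, bam_path: str | Path) -> Path:
    """Coordinate-sort a SAM/BAM and index the result."""
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return Path(bam_path)


def run_benchmark(
    ref_fasta: str | Path,
    ref_gtf: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    depth: float = 10.0,
    n_circ: int = 50,
    n_linear: int = 20,
    frac_m6a: float = 0.5,
    frac_m6a_linear: float | None = None,
    proximal_frac: float = 0.5,
    strategy: str = "frag_after",
    with_ip: bool = True,
    read_len: int = 150,
    insert_len: int = 300,
    enrichment: float = 20.0,
    background: float = 0.01,
    paired: bool = True,
    fdr: float = _m6a.DEFAULT_FDR,
    flank: int = _m6a.DEFAULT_FLANK,
    bin_width: int = _m6a.DEFAULT_BIN,
    min_segment: int = 20,
    write_fastq: bool = False,
    truth_reads: str = "crossing",
    match_tolerance: int = 0,
) -> dict:
    """Run the full chain and return (and write) a summary report."""
    ref_fasta, ref_gtf = Path(ref_fasta), Path(ref_gtf)
    for p in (ref_fasta, ref_gtf):
        if not p.exists():
            raise FileNotFoundError(f"reference file missing: {p}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = {k: v for k, v in locals().items() if isinstance(v, (int, float, str, bool))}
    config.update(ref_fasta=str(ref_fasta), ref_gtf=str(ref_gtf), out_dir=str(out_dir))
    with open(out_dir / "run_config.json", "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)

    ss = np.random.SeedSequence(seed)
    tset_seed, sim_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    log.info("loading reference %s", ref_fasta)
    ref = ReferenceBundle.load(ref_fasta, ref_gtf)
    cfg = SimConfig(
        depth=depth, read_len=read_len, insert_len=insert_len,
        enrichment=enrichment, background=background, strategy=strategy,
        paired=paired,
    )
    log.info("building simulated transcriptome (%d circ, %d linear)", n_circ, n_linear)
    tset = build_sim_transcriptome(
        ref, n_circ=n_circ, n_linear=n_linear, frac_m6a=frac_m6a,
        frac_m6a_linear=frac_m6a_linear, proximal_frac=proximal_frac,
        frag_len=insert_len, max_frag_len=cfg.max_fragment,
        seed=np.random.default_rng(tset_seed),
    )
    log.info("simulating libraries (strategy=%s, depth=%g)", strategy, depth)
    sim = simulate_merip(
        tset, ref, cfg, out_dir, seed=sim_seed, with_ip=with_ip,
        write_fastq=write_fastq, truth_reads=truth_reads,
    )
    input_bam = sort_and_index(sim.input_sam, out_dir / "input.bam")
    ip_bam = sort_and_index(sim.ip_sam, out_dir / "ip.bam") if with_ip else None

    log.info("detecting circRNAs")
    det = _detect.detect_circrnas(
        input_bam, ref, ip_bam=ip_bam, min_segment=min_segment
    )
    _detect.write_calls_table(det, out_dir / "circrna_calls.tsv")

    truth_junc = sim.truth_junctions
    circ_report = _evaluate.score_detection(
        [c.junction for c in det.calls], truth_junc, match_tolerance
    )
    summary: dict = {
        "seed": seed,
        "depth": depth,
        "strategy": strategy,
        "input_reads": det.stats["INPUT"].n_total,
        "n_truth_circ": len(truth_junc),
        "n_calls": len(det.calls),
        "f1_circ": circ_report.f1,
        "precision_circ": circ_report.precision,
        "recall_circ": circ_report.recall,
    }

    if with_ip:
        log.info("binning coverage and testing enrichment")
        chrom_lengths = ref.chrom_lengths
        ip_bins, _ = _m6a.genome_bin_counts(ip_bam, chrom_lengths, bin_width)
        in_bins, _ = _m6a.genome_bin_counts(input_bam, chrom_lengths, bin_width)
        n_ip = det.stats["IP"].n_total
        n_in = det.stats["INPUT"].n_total
        m6a_calls = _m6a.call_m6a_circrnas(
            det.calls, ip_bins, in_bins, n_ip, n_in,
            flank=flank, bin_width=bin_width, fdr=fdr,
        )
        _m6a.write_m6a_table(m6a_calls, out_dir / "m6a_circrna_calls.tsv")
        peaks = _m6a.call_linear_peaks(
            ref.annotation, ip_bins, in_bins, n_ip, n_in, bin_width=bin_width, fdr=fdr
        )
        _m6a.write_peaks_bed(peaks, out_dir / "linear_peaks.bed")

        circ_truth = sim.transcripts[
            (sim.transcripts["shape"] == "circular") & sim.transcripts["methylated"]
        ]
        truth_m6a = {
            (r.chrom, int(r.bsj_start), int(r.bsj_end)): r.site_class.split(",")[0]
            for r in circ_truth.itertuples()
        }
        call_conf = {
            r.call.junction: r.confidence
            for r in m6a_calls
            if r.confidence in ("high", "low")
        }
        high = _evaluate.score_m6a_detection(
            call_conf, truth_m6a, include_low_confidence=False,
            stratify_by_site_class=True, match_tolerance=match_tolerance,
        )
        with_low = _evaluate.score_m6a_detection(
            call_conf, truth_m6a, include_low_confidence=True,
            match_tolerance=match_tolerance,
        )
        summary.update(
            ip_reads=n_ip,
            n_truth_m6a=len(truth_m6a),
            n_m6a_high=sum(1 for r in m6a_calls if r.confidence == "high"),
            n_m6a_low=sum(1 for r in m6a_calls if r.confidence == "low"),
            n_linear_peaks=len(peaks),
            f1_m6a_high=high["m6A-circRNA"].f1,
            f1_m6a_with_low=with_low["m6A-circRNA"].f1,
        )
        for klass in ("bsj_proximal", "bsj_distal"):
            if klass in high:
                summary[f"f1_m6a_{klass}"] = high[klass].f1
                summary[f"recall_m6a_{klass}"] = high[klass].recall

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
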