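"""MeRIP-seq read simulator with ground-truth output.

Generates paired IP/INPUT sequencing libraries over a reference carrying
both linear and circular (back-spliced) transcripts, under the
generative model:

* per-transcript read count ``C = round(F * d * l/1000)`` with
  expression factor ``F = e**lam``, ``lam ~ Poisson(1.0)``, sequencing
  depth ``d`` (reads per kb per unit expression) and spliced length
  ``l``;
* per-read length ``R ~ Binomial(ceil(L_r/0.95), 0.95)`` and
  per-fragment insert ``S ~ Binomial(2*L_s, 0.5)``;
* IP enrichment: with fragmentation AFTER immunoprecipitation, every
  methylated transcript is sequenced at ``enrichment``-fold its INPUT
  count over the whole molecule; with fragmentation BEFORE, only
  fragments overlapping a 200-bp m6A region are pulled down
  (rejection sampling of ``enrichment * C`` candidates);
* nonspecific antibody background: every transcript contributes
  ``Binomial(C, background)`` reads to the IP library.

Fragments on circular transcripts wrap around the back-splice junction;
wrapped reads are emitted as chiastic primary + supplementary alignment
pairs (SA-tagged) in the optional truth SAM, so the detector can run
without an external aligner.  All outputs are byte-deterministic for a
fixed (config, seed).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import ReferenceBundle, Transcript, revcomp

READ_P = 0.95    # per-base success prob of the read-length binomial
INSERT_P = 0.5   # success prob of the insert-size binomial


@dataclass
class SimConfig:
    """Parameters of the generative model.

    depth
        Sequencing depth ``d``: expected fragments per kb of spliced
        sequence per unit expression factor.
    read_len / insert_len
        Expected read length ``L_r`` (default 150 bp) and insert size
        ``L_s`` (default 300 bp); the binomial parameters are derived
        from these, their success probabilities are constants of the
        model.
    enrichment
        Fold-enrichment of methylated material in the IP library
        (default 20).
    background
        Nonspecific IP pulldown rate relative to INPUT (default 0.01).
    m6a_region
        Width of a methylated region in spliced coordinates (200 bp).
    strategy
        ``frag_after`` (fragmentation after IP: whole methylated
        molecules enriched) or ``frag_before`` (only region-overlapping
        fragments enriched).
    """

    depth: float = 10.0
    read_len: int = 150
    insert_len: int = 300
    enrichment: float = 20.0
    background: float = 0.01
    m6a_region: int = 200
    strategy: str = "frag_after"
    paired: bool = True
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 < self.background < 1:
            raise ValueError("background factor must be in (0, 1)")
        if self.enrichment <= 1:
            raise ValueError("enrichment fold must be > 1")
        if self.paired and self.read_len > self.insert_len:
            raise ValueError("read_len must be <= insert_len in paired mode")
        if self.strategy not in ("frag_after", "frag_before"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @property
    def read_n(self) -> int:
        return math.ceil(self.read_len / READ_P)

    @property
    def max_fragment(self) -> int:
        """Largest insert the model can draw (binomial upper bound)."""
        return 2 * self.insert_len


@dataclass(frozen=True)
class M6aSite:
    """A methylation site in spliced transcript coordinates."""

    pos: int                 # spliced coordinate of the site
    klass: str               # linear | bsj_proximal | bsj_distal
    genomic_pos: int         # genomic anchor of the site


@dataclass
class SimTranscript:
    """A simulated (linear or circular) transcript."""

    tid: str
    gene_id: str
    chrom: str
    strand: str
    shape: str               # "linear" | "circular"
    exons: list[tuple[int, int]]  # ascending genomic order
    seq: str                 # spliced sequence, transcript orientation
    lam: int = 0
    sites: list[M6aSite] = field(default_factory=list)

    @property
    def F(self) -> float:
        return math.exp(self.lam)

    @property
    def spliced_length(self) -> int:
        return len(self.seq)

    @property
    def methylated(self) -> bool:
        return bool(self.sites)

    @property
    def junction(self) -> tuple[int, int] | None:
        """Genomic (bsj_start, bsj_end) for circular transcripts."""
        if self.shape != "circular":
            return None
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exons_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def spliced_to_blocks(self, s: int, e: int) -> list[tuple[int, int]]:
        """Map spliced interval [s, e) to ascending genomic blocks."""
        if not 0 <= s < e <= self.spliced_length:
            raise ValueError(f"spliced interval [{s},{e}) outside transcript")
        blocks = []
        off = 0
        for gs, ge in self.exons_transcript_order:
            elen = ge - gs
            lo, hi = max(s, off), min(e, off + elen)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((gs + lo - off, gs + hi - off))
                else:
                    blocks.append((ge - (hi - off), ge - (lo - off)))
            off += elen
        return sorted(blocks)

    def genomic_to_spliced(self, gpos: int) -> int | None:
        off = 0
        for gs, ge in self.exons_transcript_order:
            if gs <= gpos < ge:
                return off + (gpos - gs if self.strand == "+" else ge - 1 - gpos)
            off += ge - gs
        return None

    def region_for(self, site: M6aSite, width: int) -> tuple[int, int]:
        """Site region as spliced (start, length); wraps on circles."""
        half = width // 2
        l = self.spliced_length
        if self.shape == "circular":
            return (site.pos - half) % l, min(width, l)
        start = max(0, site.pos - half)
        return start, min(site.pos + half, l) - start


def expected_read_count(F: float, depth: float, spliced_len: int) -> int:
    """C = F * d * l with l in kilobases, rounded to nearest integer."""
    return int(round(F * depth * spliced_len / 1000.0))


def sample_read_count(spliced_len: int, cfg: SimConfig, rng: np.random.Generator) -> int:
    """Draw lam ~ Poisson(1.0) and return C = round(e**lam * d * l/1000)."""
    return expected_read_count(math.exp(rng.poisson(1.0)), cfg.depth, spliced_len)


def sample_fragment_geometry(
    cfg: SimConfig, rng: np.random.Generator, n: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (read length R, insert size S) pairs from the binomial models."""
    R = rng.binomial(cfg.read_n, READ_P, n)
    S = rng.binomial(2 * cfg.insert_len, INSERT_P, n)
    if cfg.paired:
        S = np.maximum(S, R)
    return R, S


def site_class(pos: int, spliced_len: int, shape: str, frag_len: int) -> str:
    """Classify a site by circular distance to the back-splice junction."""
    if shape != "circular":
        return "linear"
    dist = min(pos % spliced_len, spliced_len - pos % spliced_len)
    return "bsj_proximal" if dist <= frag_len else "bsj_distal"


def build_sim_transcriptome(
    ref: ReferenceBundle,
    n_circ: int,
    n_linear: int,
    frac_m6a: float = 0.5,
    proximal_frac: float = 0.5,
    frac_m6a_linear: float | None = None,
    frag_len: int = 300,
    max_frag_len: int | None = None,
    region_len: int = 200,
    seed: int | np.random.Generator = 0,
) -> list[SimTranscript]:
    """Build the simulated transcriptome from an annotated reference.

    Circular transcripts are contiguous exon sub-chains of annotated
    transcripts (distinct back-splice junctions).  Methylation is
    assigned at the host-gene level: an m6A site is a genomic position,
    so a circle and the linear isoform sharing its exons are methylated
    together.  Sites on circles are placed at the junction
    (``bsj_proximal``) or at the circle midpoint (``bsj_distal``); a
    distal placement is only used when the circle is long enough that
    no fragment (at most ``max_frag_len`` bases) can span both the
    200-bp site region and the junction, making the distal geometric
    guarantee exact.  Expression factors ``F = e**lam`` are drawn once
    per transcript.  Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if max_frag_len is None:
        max_frag_len = 2 * frag_len
    if frac_m6a_linear is None:
        frac_m6a_linear = frac_m6a
    anno = ref.annotation
    hosts = anno.transcripts

    def spliced_seq(t: Transcript | SimTranscript, exons) -> str:
        s = "".join(ref.fetch(t.chrom, a, b) for a, b in exons)
        return revcomp(s) if t.strand == "-" else s

    # --- linear transcripts -------------------------------------------------
    if n_linear > len(hosts):
        raise ValueError(f"requested {n_linear} linear transcripts, {len(hosts)} available")
    lin_idx = sorted(rng.choice(len(hosts), size=n_linear, replace=False))
    linears: dict[str, SimTranscript] = {}
    for i in lin_idx:
        h = hosts[i]
        linears[h.gene_id] = SimTranscript(
            f"lin_{h.transcript_id}", h.gene_id, h.chrom, h.strand,
            "linear", list(h.exons), spliced_seq(h, h.exons),
        )

    # --- circular transcripts: contiguous exon sub-chains -------------------
    candidates = []
    for hi, h in enumerate(hosts):
        k = len(h.exons)
        for i in range(k):
            for j in range(i, k):
                candidates.append((hi, i, j))
    order = rng.permutation(len(candidates))
    circles: list[SimTranscript] = []
    seen_junctions: set[tuple[str, int, int]] = set()
    for oi in order:
        hi, i, j = candidates[oi]
        h = hosts[hi]
        exons = h.exons[i : j + 1]
        junc = (h.chrom, exons[0][0], exons[-1][1])
        if junc in seen_junctions:
            continue
        seen_junctions.add(junc)
        circles.append(
            SimTranscript(
                f"circ_{h.transcript_id}_{i}_{j}", h.gene_id, h.chrom, h.strand,
                "circular", list(exons), spliced_seq(h, exons),
            )
        )
        if len(circles) == n_circ:
            break
    if len(circles) < n_circ:
        raise ValueError(
            f"only {len(circles)} distinct exon sub-chains available, {n_circ} requested"
        )

    # --- gene-level methylation assignment ----------------------------------
    by_gene: dict[str, list[SimTranscript]] = {}
    for c in circles:
        by_gene.setdefault(c.gene_id, []).append(c)
    gene_order = list(rng.permutation(sorted(by_gene)))
    target = int(round(frac_m6a * n_circ))
    meth_circles: list[SimTranscript] = []
    meth_genes: set[str] = set()
    for g in gene_order:
        if len(meth_circles) >= target:
            break
        meth_genes.add(g)
        meth_circles.extend(by_gene[g])

    # distal placements go to the longest circles that admit them exactly
    min_distal_len = 2 * (max_frag_len + region_len // 2) + 2
    n_distal = int(round((1.0 - proximal_frac) * len(meth_circles)))
    for c in sorted(meth_circles, key=lambda c: -c.spliced_length):
        l = c.spliced_length
        if n_distal > 0 and l >= min_distal_len:
            pos = l // 2
            n_distal -= 1
        else:
            pos = 0
        gpos = c.spliced_to_blocks(pos, pos + 1)[0][0]
        c.sites.append(M6aSite(pos, site_class(pos, l, "circular", frag_len), gpos))
        host_lin = linears.get(c.gene_id)
        if host_lin is not None:
            sp = host_lin.genomic_to_spliced(gpos)
            if sp is not None:
                host_lin.sites.append(M6aSite(sp, "linear", gpos))

    # linear-only genes are methylated independently at frac_m6a_linear
    circle_genes = set(by_gene)
    lin_only = sorted(g for g in linears if g not in circle_genes)
    n_meth_lin = int(round(frac_m6a_linear * len(lin_only)))
    for g in list(rng.permutation(lin_only))[:n_meth_lin]:
        t = linears[g]
        pos = t.spliced_length // 2
        gpos = t.spliced_to_blocks(pos, pos + 1)[0][0]
        t.sites.append(M6aSite(pos, "linear", gpos))

    tset = sorted(linears.values(), key=lambda t: t.tid) + sorted(
        circles, key=lambda t: t.tid
    )
    for t in tset:
        t.lam = int(rng.poisson(1.0))
    return tset


# ---------------------------------------------------------------------------
# library emission
# ---------------------------------------------------------------------------

def _circular_overlap(a: int, alen: int, b: int, blen: int, l: int) -> bool:
    """Do intervals [a,a+alen) and [b,b+blen) overlap on a circle of size l?"""
    if alen >= l or blen >= l:
        return True
    return ((b - a) % l) < alen or ((a - b) % l) < blen


@dataclass
class _ReadPlan:
    """Planned alignment of one read end before rendering to SAM."""

    seq: str                  # read in sequencing orientation (as in FASTQ)
    strand: str               # genome strand of the alignment
    crosses_bsj: bool
    min_seg: int              # shortest aligned segment (= read len if unsplit)
    # per alignment record: (pos, cigar, is_primary)
    records: list[tuple[int, str, bool]]
    primary_pos: int


def _plan_read(t: SimTranscript, sp_start: int, rlen: int, read2: bool) -> _ReadPlan:
    l = t.spliced_length
    s = sp_start % l
    rlen = min(rlen, l)
    e = s + rlen
    if t.shape == "linear" and e > l:  # defensive: fragments are clamped upstream
        e, rlen = l, l - s
    crosses = t.shape == "circular" and e > l
    readseq = (t.seq + t.seq)[s:e] if crosses else t.seq[s:e]
    strand = t.strand if not read2 else ("-" if t.strand == "+" else "+")
    # the sequenced read: R1 in transcript orientation, R2 reverse-complemented
    seq_out = readseq if not read2 else revcomp(readseq)
    parts = [(0, s, l), (l - s, 0, e - l)] if crosses else [(0, s, e)]
    recs = []
    qlens = []
    for qstart, ps, pe in parts:
        blocks = t.spliced_to_blocks(ps, pe)
        qlen = pe - ps
        qlens.append(qlen)
        # CIGAR is written in reference orientation; query offsets measured
        # on the genome-forward read flip when the transcript is on "-"
        leading = qstart if t.strand == "+" else rlen - qstart - qlen
        cig = []
        if leading:
            cig.append(f"{leading}S")
        prev_end = None
        for bs, be in blocks:
            if prev_end is not None:
                cig.append(f"{bs - prev_end}N")
            cig.append(f"{be - bs}M")
            prev_end = be
        trailing = rlen - leading - qlen
        if trailing:
            cig.append(f"{trailing}S")
        recs.append((blocks[0][0], "".join(cig)))
    primary_i = int(np.argmax(qlens))
    records = [(pos, cig, i == primary_i) for i, (pos, cig) in enumerate(recs)]
    return _ReadPlan(
        seq_out, strand, crosses, min(qlens), records, recs[primary_i][0]
    )


def _render_sam(
    name: str,
    t: SimTranscript,
    plan: _ReadPlan,
    mate: _ReadPlan | None,
    read2: bool,
    paired: bool,
    out: list[str],
) -> None:
    base = 0
    if paired:
        base |= 0x1 | 0x2 | (0x80 if read2 else 0x40)
        if mate is not None and mate.strand == "-":
            base |= 0x20
    if plan.strand == "-":
        base |= 0x10
    sam_seq = plan.seq if plan.strand == "+" else revcomp(plan.seq)
    qual = "I" * len(sam_seq)
    rnext = "=" if paired else "*"
    pnext = (mate.primary_pos + 1) if (paired and mate is not None) else 0
    split = len(plan.records) > 1
    for pos, cig, is_primary in plan.records:
        flag = base | (0 if is_primary else 0x800)
        tags = []
        if split:
            others = [
                f"{t.chrom},{p + 1},{plan.strand},{c},60,0;"
                for p, c, prim in plan.records
                if (p, c) != (pos, cig)
            ]
            tags.append("SA:Z:" + "".join(others))
        out.append(
            f"{name}\t{flag}\t{t.chrom}\t{pos + 1}\t60\t{cig}\t{rnext}\t{pnext}\t0\t"
            f"{sam_seq}\t{qual}" + ("\t" + "\t".join(tags) if tags else "")
        )


@dataclass
class SimOutput:
    """File paths and truth tables produced by one simulation."""

    out_dir: Path
    input_sam: Path | None
    ip_sam: Path | None
    input_fastq: tuple[Path, ...] | None
    ip_fastq: tuple[Path, ...] | None
    transcripts: pd.DataFrame
    reads: pd.DataFrame
    config: SimConfig

    @property
    def truth_junctions(self) -> set[tuple[str, int, int]]:
        circ = self.transcripts[self.transcripts["shape"] == "circular"]
        return {
            (r.chrom, int(r.bsj_start), int(r.bsj_end)) for r in circ.itertuples()
        }

    def truth_bsj_read_counts(
        self, library: str, min_seg: int = 0
    ) -> dict[tuple[str, int, int], int]:
        """Truth count of junction-crossing read ends per BSJ in a library."""
        juncs = {
            r.tid: (r.chrom, int(r.bsj_start), int(r.bsj_end))
            for r in self.transcripts[self.transcripts["shape"] == "circular"].itertuples()
        }
        rows = self.reads
        rows = rows[
            (rows["library"] == library)
            & rows["crosses_bsj"]
            & (rows["min_seg"] >= min_seg)
        ]
        counts: dict[tuple[str, int, int], int] = {}
        for tid, n in rows.groupby("tid").size().items():
            counts[juncs[tid]] = int(n)
        return counts


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = list(seq)
    for i in rng.choice(len(seq), size=n_err, replace=False):
        arr[i] = "ACGT"[(("ACGT".index(arr[i]) if arr[i] in "ACGT" else 0) + rng.integers(1, 4)) % 4]
    return "".join(arr)


def simulate_merip(
    tset: Sequence[SimTranscript],
    ref: ReferenceBundle,
    cfg: SimConfig,
    out_dir: str | Path,
    seed: int,
    with_ip: bool = True,
    write_sam: bool = True,
    write_fastq: bool = True,
    gzip_fastq: bool = False,
    truth_reads: str = "all",
) -> SimOutput:
    """Emit INPUT (and optionally IP) libraries plus truth tables.

    ``truth_reads`` controls the per-read truth table: ``all`` records
    every read end, ``crossing`` only junction-crossing read ends (the
    rows needed for junction-level scoring), ``none`` skips it.
    """
    if truth_reads not in ("all", "crossing", "none"):
        raise ValueError("truth_reads must be all|crossing|none")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    header = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, length in ref.chrom_lengths.items():
        header.append(f"@SQ\tSN:{chrom}\tLN:{length}")

    read_rows: list[tuple] = []
    tx_counts = {t.tid: [0, 0, 0] for t in tset}  # input, ip_enriched, ip_background

    def emit_library(lib: str) -> tuple[Path | None, tuple[Path, ...] | None, int]:
        sam_path = out_dir / f"{lib}.sam" if write_sam else None
        sam_fh = open(sam_path, "w") if sam_path else None
        if sam_fh:
            sam_fh.write("\n".join(header) + "\n")
        fq_paths: tuple[Path, ...] | None = None
        fq_fhs = None
        if write_fastq:
            opener = (lambda p: gzip.open(p, "wt")) if gzip_fastq else (lambda p: open(p, "w"))
            ext = ".fastq.gz" if gzip_fastq else ".fastq"
            if cfg.paired:
                fq_paths = (out_dir / f"{lib}_R1{ext}", out_dir / f"{lib}_R2{ext}")
            else:
                fq_paths = (out_dir / f"{lib}{ext}",)
            fq_fhs = [opener(p) for p in fq_paths]
        n_reads = 0

        def emit_fragments(t: SimTranscript, n: int, enriched: bool, counter_idx: int) -> None:
            nonlocal n_reads
            if n <= 0:
                return
            l = t.spliced_length
            R1, S = sample_fragment_geometry(cfg, rng, n)
            if cfg.paired:
                R2 = rng.binomial(cfg.read_n, READ_P, n)
                S = np.maximum(S, R2)
            else:
                R2 = None
                R1 = np.minimum(R1, S)
            if t.shape == "circular":
                a = rng.integers(0, l, n)
            else:
                S = np.minimum(S, l)
                R1 = np.minimum(R1, S)
                if R2 is not None:
                    R2 = np.minimum(R2, S)
                a = rng.integers(0, l - S + 1)
            if enriched and cfg.strategy == "frag_before":
                keep = np.zeros(n, dtype=bool)
                regions = [t.region_for(site, cfg.m6a_region) for site in t.sites]
                for i in range(n):
                    for r0, rlen in regions:
                        ok = (
                            _circular_overlap(int(a[i]), int(S[i]), r0, rlen, l)
                            if t.shape == "circular"
                            else (a[i] < r0 + rlen and r0 < a[i] + S[i])
                        )
                        if ok:
                            keep[i] = True
                            break
                a, S, R1 = a[keep], S[keep], R1[keep]
                if R2 is not None:
                    R2 = R2[keep]
            m = len(a)
            tx_counts[t.tid][counter_idx] += m
            sam_buf: list[str] = []
            for i in range(m):
                name = f"{lib}:{t.tid}:{tx_counts[t.tid][counter_idx] - m + i}" + (
                    ":e" if enriched else (":b" if lib == "ip" else "")
                )
                p1 = _plan_read(t, int(a[i]), int(R1[i]), read2=False)
                p2 = (
                    _plan_read(t, int(a[i] + S[i] - R2[i]), int(R2[i]), read2=True)
                    if cfg.paired
                    else None
                )
                if cfg.error_rate > 0:
                    p1.seq = _mutate(p1.seq, cfg.error_rate, rng)
                    if p2 is not None:
                        p2.seq = _mutate(p2.seq, cfg.error_rate, rng)
                if sam_fh:
                    _render_sam(name, t, p1, p2, False, cfg.paired, sam_buf)
                    if p2 is not None:
                        _render_sam(name, t, p2, p1, True, cfg.paired, sam_buf)
                if fq_fhs:
                    fq_fhs[0].write(f"@{name}\n{p1.seq}\n+\n{'I' * len(p1.seq)}\n")
                    if p2 is not None:
                        fq_fhs[1].write(f"@{name}\n{p2.seq}\n+\n{'I' * len(p2.seq)}\n")
                for ri, plan in enumerate((p1, p2)):
                    if plan is None:
                        continue
                    n_reads += 1
                    if truth_reads == "all" or (
                        truth_reads == "crossing" and plan.crosses_bsj
                    ):
                        read_rows.append(
                            (name, ri + 1, t.tid, lib, enriched,
                             int(a[i]) % l if ri == 0 else int(a[i] + S[i] - R2[i]) % l,
                             len(plan.seq), plan.crosses_bsj, plan.min_seg)
                        )
            if sam_fh and sam_buf:
                sam_fh.write("\n".join(sam_buf) + "\n")

        for t in tset:
            c_input = expected_read_count(t.F, cfg.depth, t.spliced_length)
            if lib == "input":
                emit_fragments(t, c_input, enriched=False, counter_idx=0)
            else:
                if t.methylated:
                    emit_fragments(
                        t, int(round(cfg.enrichment * c_input)), enriched=True, counter_idx=1
                    )
                emit_fragments(
                    t, int(rng.binomial(c_input, cfg.background)), enriched=False,
                    counter_idx=2,
                )
        if sam_fh:
            sam_fh.close()
        if fq_fhs:
            for fh in fq_fhs:
                fh.close()
        return sam_path, fq_paths, n_reads

    input_sam, input_fq, _ = emit_library("input")
    ip_sam = ip_fq = None
    if with_ip:
        ip_sam, ip_fq, _ = emit_library("ip")

    tx_rows = []
    for t in tset:
        junc = t.junction
        tx_rows.append(
            {
                "tid": t.tid,
                "gene_id": t.gene_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "shape": t.shape,
                "start": t.exons[0][0],
                "end": t.exons[-1][1],
                "bsj_start": junc[0] if junc else -1,
                "bsj_end": junc[1] if junc else -1,
                "spliced_len": t.spliced_length,
                "F": t.F,
                "methylated": t.methylated,
                "site_class": ",".join(s.klass for s in t.sites),
                "site_pos": ",".join(str(s.pos) for s in t.sites),
                "site_genomic": ",".join(str(s.genomic_pos) for s in t.sites),
                "c_input": tx_counts[t.tid][0],
                "c_ip_enriched": tx_counts[t.tid][1],
                "c_ip_background": tx_counts[t.tid][2],
            }
        )
    transcripts = pd.DataFrame(tx_rows)
    reads = pd.DataFrame(
        read_rows,
        columns=[
            "name", "read", "tid", "library", "enriched",
            "spliced_start", "read_len", "crosses_bsj", "min_seg",
        ],
    )
    transcripts.to_csv(out_dir / "truth_transcripts.tsv", sep="\t", index=False)
    if truth_reads != "none":
        reads.to_csv(out_dir / "truth_reads.tsv", sep="\t", index=False)
    circ = transcripts[transcripts["shape"] == "circular"]
    with open(out_dir / "truth_junctions.bed", "w") as fh:
        for r in circ.itertuples():
            fh.write(
                f"{r.chrom}\t{r.bsj_start}\t{r.bsj_end}\t{r.tid}\t0\t{r.strand}\n"
            )
    return SimOutput(
        out_dir, input_sam, ip_sam, input_fq, ip_fq, transcripts, reads, cfg
    )
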