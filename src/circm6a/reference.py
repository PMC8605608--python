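"""Reference genome and annotation handling.

Loads an indexed FASTA plus a GENCODE-dialect GTF into light-weight
transcript models with a fast exon-boundary / splice-site index, and
provides a deterministic toy-reference generator used throughout the
test and benchmark machinery.

Coordinate conventions
----------------------
All coordinates are stored internally as 0-based half-open intervals.
GTF input is 1-based closed and converted on load; GTF output converts
back.  Emitted BED-like tables are 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from pyfaidx import Fasta

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_0_based_half_open(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based closed interval (GTF) to 0-based half-open."""
    return start_1based - 1, end_1based


def to_1_based_closed(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval back to 1-based closed (GTF)."""
    return start + 1, end


@dataclass(frozen=True)
class MotifCall:
    """Splice dinucleotides flanking a back-splice junction."""

    acceptor: str  # two bases immediately upstream of bsj_start
    donor: str     # two bases immediately downstream of bsj_end
    canonical: bool
    strand: str    # "+", "-" or "." when non-canonical


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # ascending genomic order, 0-based half-open

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}: "
                    f"({s0},{e0}) and ({s1},{e1})"
                )
        if any(s >= e for s, e in self.exons):
            raise ValueError(f"empty exon in transcript {self.transcript_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exons_transcript_order(self) -> list[tuple[int, int]]:
        """Exons ordered 5'->3' along the transcript."""
        return self.exons if self.strand == "+" else self.exons[::-1]


class GenomeAnnotation:
    """Transcript/exon models with an exon-boundary and splice-site index."""

    def __init__(self, transcripts: Sequence[Transcript]):
        self.transcripts: list[Transcript] = list(transcripts)
        self.exon_boundary_index: set[tuple[str, int, str]] = set()
        for t in self.transcripts:
            for s, e in t.exons:
                self.exon_boundary_index.add((t.chrom, s, "start"))
                self.exon_boundary_index.add((t.chrom, e, "end"))
        self._exon_trees: dict[str, IntervalTree] | None = None
        self._gene_trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def chroms(self) -> set[str]:
        return {t.chrom for t in self.transcripts}

    def is_exon_start(self, chrom: str, pos: int) -> bool:
        return (chrom, pos, "start") in self.exon_boundary_index

    def is_exon_end(self, chrom: str, pos: int) -> bool:
        return (chrom, pos, "end") in self.exon_boundary_index

    def _build_trees(self) -> None:
        exon_trees: dict[str, IntervalTree] = {}
        gene_trees: dict[str, IntervalTree] = {}
        spans: dict[tuple[str, str], tuple[int, int]] = {}
        for t in self.transcripts:
            tree = exon_trees.setdefault(t.chrom, IntervalTree())
            for s, e in t.exons:
                tree.addi(s, e, t.gene_id)
            key = (t.chrom, t.gene_id)
            s0, e0 = spans.get(key, (t.start, t.end))
            spans[key] = (min(s0, t.start), max(e0, t.end))
        for (chrom, gene), (s, e) in spans.items():
            gene_trees.setdefault(chrom, IntervalTree()).addi(s, e, gene)
        self._exon_trees, self._gene_trees = exon_trees, gene_trees

    def host_genes(self, chrom: str, start: int, end: int) -> list[str]:
        """Gene ids whose exons overlap [start, end)."""
        if self._exon_trees is None:
            self._build_trees()
        tree = self._exon_trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})

    def gene_feature(self, chrom: str, start: int, end: int) -> str:
        """Host-gene feature class of a locus: exonic / intronic / intergenic."""
        if self._exon_trees is None:
            self._build_trees()
        if self.host_genes(chrom, start, end):
            return "exonic"
        gtree = self._gene_trees.get(chrom)
        if gtree is not None and gtree.overlap(start, end):
            return "intronic"
        return "intergenic"

    def write_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.transcripts:
                for i, (s, e) in enumerate(t.exons, 1):
                    s1, e1 = to_1_based_closed(s, e)
                    attrs = (
                        f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'exon_number "{i}";'
                    )
                    fh.write(
                        f"{t.chrom}\tcircm6a\texon\t{s1}\t{e1}\t.\t{t.strand}\t.\t{attrs}\n"
                    )


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def load_annotation(gtf_path: str | Path) -> GenomeAnnotation:
    """Parse a GENCODE-dialect GTF into a :class:`GenomeAnnotation`.

    Only ``exon`` features are consulted; exon records are grouped by
    ``transcript_id``.  Transcript features without any exon records are
    dropped with a warning.  Coordinates are converted from GTF 1-based
    closed to internal 0-based half-open.
    """
    exons: dict[str, dict] = {}
    seen_transcripts: set[str] = set()
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gtf_path}: malformed GTF record at line {lineno}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("exon", "transcript"):
                continue
            ad = dict(_ATTR_RE.findall(attrs))
            if "transcript_id" not in ad or "gene_id" not in ad:
                raise ValueError(
                    f"{gtf_path}: missing transcript_id/gene_id attribute at line {lineno}"
                )
            tid = ad["transcript_id"]
            if feature == "transcript":
                seen_transcripts.add(tid)
                continue
            s0, e0 = to_0_based_half_open(int(start), int(end))
            rec = exons.setdefault(
                tid, {"gene_id": ad["gene_id"], "chrom": chrom, "strand": strand, "exons": []}
            )
            rec["exons"].append((s0, e0))
    for tid in seen_transcripts - exons.keys():
        log.warning("transcript %s has no exon features; dropped", tid)
    transcripts = [
        Transcript(tid, rec["gene_id"], rec["chrom"], rec["strand"], rec["exons"])
        for tid, rec in exons.items()
    ]
    return GenomeAnnotation(transcripts)


class ReferenceBundle:
    """Indexed genome FASTA plus its annotation.

    Sequence lookups are upper-cased; chromosome names are matched by
    exact string comparison (no "chr" aliasing).
    """

    def __init__(self, fasta_path: str | Path, annotation: GenomeAnnotation):
        self.genome = Fasta(str(fasta_path), sequence_always_upper=True)
        self.annotation = annotation
        missing = annotation.chroms - set(self.genome.keys())
        if missing:
            raise ValueError(f"annotation chromosomes absent from FASTA: {sorted(missing)}")

    @classmethod
    def load(cls, fasta_path: str | Path, gtf_path: str | Path) -> "ReferenceBundle":
        return cls(fasta_path, load_annotation(gtf_path))

    def chrom_length(self, chrom: str) -> int:
        return len(self.genome[chrom])

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self.genome.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > self.chrom_length(chrom):
            raise IndexError(f"{chrom}:{start}-{end} out of sequence range")
        return str(self.genome[chrom][start:end])


def splice_motif_at(
    ref: ReferenceBundle, chrom: str, bsj_start: int, bsj_end: int
) -> MotifCall:
    """Splice dinucleotides flanking a candidate back-splice junction.

    The acceptor dinucleotide is the two bases immediately upstream of
    ``bsj_start``; the donor dinucleotide the two bases immediately
    downstream of ``bsj_end``.  The junction is canonical when the
    intronic context reads AG]...[GT on the plus strand or its reverse
    complement (AC]...[CT as read on the plus strand) on the minus
    strand; strand is inferred from the motif alone.
    """
    if bsj_start >= bsj_end:
        raise ValueError("bsj_start must be < bsj_end")
    if bsj_start < 2 or bsj_end + 2 > ref.chrom_length(chrom):
        raise IndexError(f"junction {chrom}:{bsj_start}-{bsj_end} too close to contig edge")
    acceptor = ref.fetch(chrom, bsj_start - 2, bsj_start)
    donor = ref.fetch(chrom, bsj_end, bsj_end + 2)
    if acceptor == "AG" and donor == "GT":
        return MotifCall(acceptor, donor, True, "+")
    if acceptor == "AC" and donor == "CT":
        return MotifCall(acceptor, donor, True, "-")
    return MotifCall(acceptor, donor, False, ".")


def make_toy_reference(
    out_dir: str | Path,
    n_genes: int = 10,
    exons_per_gene: int = 4,
    exon_len: int = 300,
    intron_len: int = 200,
    spacing: int = 500,
    seed: int = 0,
    chrom: str = "chrT",
    minus_fraction: float = 0.5,
) -> tuple[Path, Path]:
    """Write a deterministic synthetic genome FASTA + GTF.

    Genes are tiled along one contig with ``spacing`` bases between
    them; every exon boundary carries canonical splice dinucleotides
    (AG upstream of each exon start, GT downstream of each exon end on
    plus-strand genes; AC/CT for minus-strand genes), so circles built
    from annotated exon chains pass the motif filter.  Deterministic
    for a fixed seed: the same call yields byte-identical files.
    """
    if min(n_genes, exons_per_gene, exon_len) < 1 or intron_len < 4 or spacing < 4:
        raise ValueError("sizes must be >= 1 (intron_len and spacing >= 4)")
    rng = np.random.default_rng(seed)
    gene_span = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    total = n_genes * (gene_span + spacing) + spacing
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=total)

    transcripts = []
    n_minus = int(round(n_genes * minus_fraction))
    for g in range(n_genes):
        gstart = spacing + g * (gene_span + spacing)
        strand = "-" if g < n_minus else "+"
        acc, don = ("AC", "CT") if strand == "-" else ("AG", "GT")
        exons = []
        for j in range(exons_per_gene):
            es = gstart + j * (exon_len + intron_len)
            ee = es + exon_len
            exons.append((es, ee))
            seq[es - 2 : es] = np.frombuffer(acc.encode(), dtype="S1")
            seq[ee : ee + 2] = np.frombuffer(don.encode(), dtype="S1")
        transcripts.append(Transcript(f"tx{g:04d}", f"gene{g:04d}", chrom, strand, exons))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "toy.fa"
    gtf_path = out_dir / "toy.gtf"
    seq_str = seq.tobytes().decode()
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, total, 60):
            fh.write(seq_str[i : i + 60] + "\n")
    GenomeAnnotation(transcripts).write_gtf(gtf_path)
    return fasta_path, gtf_path
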