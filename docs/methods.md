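# Methods

This note documents the models implemented in `circm6a`, the parameter
choices that matter, what the simulator does and does not emulate, and
the numerical conventions used throughout.

## Coordinates and references

All internal coordinates are 0-based half-open; GTF input (1-based
closed, GENCODE attribute dialect) is converted on load and on write.
Only `exon` features are consulted; transcripts are groups of exon
records sharing a `transcript_id`.  Chromosome names are matched
exactly (no "chr" aliasing).  Strand of a candidate circle is inferred
from the splice motif (AG…GT on plus, AC…CT as read on plus for minus),
never from read orientation, because MeRIP libraries are typically
unstranded.

## circRNA detection

A back-splice junction (BSJ) candidate requires a read aligned as a
primary record plus exactly one same-chromosome, same-strand SA
segment, with the segment earlier in the as-written query mapping
strictly downstream of the later segment (chiastic order).  Reads with
more than two segments are ignored, and soft-clipped reads without a
supplementary record are not re-aligned — the detector assumes a
chimera-reporting aligner (BWA-MEM-style) or the simulator's truth
alignments.  Parameters:

| parameter | default | meaning |
|---|---|---|
| `min_segment` | 20 bp | minimum aligned length of each junction segment |
| `require_canonical` | on | AG/GT (or reverse-complement) at the junction |
| `require_boundary` | on | both junction ends on annotated exon boundaries |

Motif and boundary checks are pure filters with 0-bp tolerance: no
rescue or shifting of junction ends toward annotated boundaries is
attempted.  The paired-end mapping (PEM) filter keeps a supporting read
only when every aligned segment of its mate lies inside
`[bsj_start, bsj_end)`; it is skipped automatically when the library is
single-end.  Duplicate reads are not collapsed, and a primary record
with mapping quality 0 still counts.

Quantification is SRPBM = N_BSJ / N_total × 10⁹, where N_total counts
primary mapped records passing the same QC as the detector
(supplementary and secondary records excluded).  The multi-sample
filter retains junctions with N_BSJ ≥ 2 in ≥ 2 samples.  The circular
ratio at a junction is N_BSJ / (N_BSJ + N_linear), where N_linear is
the mean of the colinear spliced-read counts using the same donor or
acceptor site; this numerical definition is this package's own
(the quantity has no standard formula).

## m⁶A-circRNA calling

The genome is tiled into fixed 25-bp bins.  For each circle the two
100-bp flanks **internal** to the circle on either side of the junction
are tested (flanks truncated to half the circle span for short
circles).  Because only internal sequence is part of the circle, the
donor-side flank is logically contiguous with the acceptor-side flank
through the BSJ — "crossing the junction" is meaningful only in
circular coordinates.  Per bin, a one-sided (greater-in-IP) Fisher's
exact test is computed on

```
[[ip_count,    N_IP    − ip_count],
 [input_count, N_INPUT − input_count]]
```

implemented as the hypergeometric upper tail (vectorised
`hypergeom.sf`), which is exactly the one-sided Fisher p.  A read
increments every bin one of its aligned blocks overlaps by at least one
base; a junction-crossing read therefore contributes on both sides of
the BSJ through its two alignment records.

All flank bins of all candidate circles in a sample form one
Benjamini–Hochberg adjustment family; linear peaks form a separate
family.  Significance is q < 0.05.  The concatenated significant run
crosses the BSJ exactly when the two bins touching the junction (last
donor-side, first acceptor-side) are both significant — strict
contiguity, no gaps.  Linear peaks instead merge significant exonic
bins across single-bin gaps, the usual practice for bin-based peak
merging.

Confidence classes for a junction-spanning candidate:

* **low** — N_BSJ,IP ≥ 1;
* **high** — N_BSJ,IP ≥ 2 and
  (N_BSJ,IP / N_IP) / (N_BSJ,INPUT / N_INPUT) ≥ 1.

Relative m⁶A level over a span is IP SRPBM / INPUT SRPBM computed from
summed bin counts; when the INPUT span count is zero a pseudo-count of
one read is added to both libraries and the value flagged.  One-sided
testing, the single adjustment family and the strict junction-crossing
rule are design choices of this package where the published procedure
leaves latitude.

Note one property of the exact test worth remembering when reading
q-value columns: for identical non-zero proportions the one-sided p is
about 0.5–0.6, not 1 (the observed table belongs to the upper tail);
only empty bins give p = 1 exactly.

## Simulator

The generative model:

| parameter | default | meaning |
|---|---|---|
| `depth` d | — | fragments per kb of spliced sequence per unit expression factor |
| `read_len` L_r | 150 bp | expected read length; R ~ B(⌈L_r/0.95⌉, 0.95) per read |
| `insert_len` L_s | 300 bp | expected insert; S ~ B(2·L_s, 0.5) per fragment, clamped ≥ R |
| `enrichment` | 20 | IP fold-enrichment of methylated material |
| `background` | 0.01 | nonspecific IP pulldown per transcript, Binomial(C, 0.01) |
| `m6a_region` | 200 bp | width of a methylated region in spliced coordinates |
| `error_rate` | 0 | uniform substitution rate (off by default) |

Per-transcript counts are C = round(F · d · l/1000) with F = e^λ and
λ ~ Poisson(1.0) drawn once per transcript per library pair; l is taken
in kilobases so that d is "fragments per kb per unit expression".  The
Poisson is integer-valued, so F ∈ {1, e, e², …} — taken literally from
the model definition; the heavy tail it produces is a feature (a few
transcripts dominate, as in real libraries).

Fragment starts are uniform on the spliced sequence; on circles the
position wraps, producing junction-crossing reads with probability
(R−1)/l per read (verified against exhaustive enumeration in the test
suite).  Orientation is FR; R2 is the reverse complement of the
fragment end.  With fragmentation **after** MeRIP, methylated
transcripts are emitted at `enrichment` × their INPUT count over the
whole molecule.  With fragmentation **before**, `enrichment` × C
candidate fragments are drawn and kept only if they overlap a 200-bp
m⁶A region (rejection sampling), so region coverage reaches the
enrichment target while the rest of the molecule stays at background.

Simulated circles are contiguous exon sub-chains of annotated
transcripts with distinct junctions.  Methylation is assigned at the
host-gene level: an m⁶A site is anchored at a genomic position, and a
circle and the linear isoform sharing its exons are methylated
together — mirroring how real genomic m⁶A peaks project onto every
overlapping isoform, and avoiding the biologically incoherent case of
an unmethylated circle nested inside a heavily methylated locus.
BSJ-proximal sites are placed at the junction; BSJ-distal sites at the
circle midpoint, and only on circles long enough that no fragment (at
most 2·L_s bases) can span both the site region and the junction.
This makes the distal guarantee *exact*: under fragmentation-before,
no enriched read from a distal-only circle can ever contain the BSJ,
which is audited read-by-read from the truth table in the tests.  A
site is classified proximal when its circular distance to the junction
is at most one expected fragment length (L_s), distal otherwise.

The simulator writes FASTQ, truth alignments (SAM with correct CIGARs;
junction-crossing reads as chiastic primary + SA-tagged supplementary
pairs), and truth tables (per-transcript counts and sites; per-read
origin, spliced start and junction-crossing flag).  All outputs are
byte-deterministic for a fixed (config, seed).

What the simulator does **not** emulate: sequencing errors and quality
variation (qualities are constant, errors default to 0), PCR
duplication, GC or positional coverage bias, strand-specific protocols,
partial methylation stoichiometry, overlapping genes and alternative
isoform structure beyond exon sub-chains, intron-lariat circles, and
RNase-R treatment.  Passing benchmarks on these simulations therefore
demonstrates correctness of the detection geometry and statistics under
the stated generative model — not robustness to alignment artifacts or
library pathologies of real data.

## Scoring

Junction matching is exact-position by default (simulator and detector
share coordinates); a tolerance exists for scoring third-party tools.
F1 = 2PR/(P+R) with the 0/0 conventions fixed to 0.  For stratified
m⁶A scoring, TP and FN are partitioned by the truth site class (they
sum to the unstratified counts); a call matching no methylated truth at
all counts as a false positive in *every* stratum, so stratum F1 still
reflects global precision.  RNase-R response categories: fold ≥ 5
resistant, 1 ≤ fold < 5 unaffected, fold < 1 depleted.

## Benchmark problem sizes

The bundled acceptance run uses a 600-gene toy reference (6 exons of
400 bp per gene), 250 circles and 600 linear transcripts, with half of
the circles methylated and 20% of linear-only genes methylated — a
methylated mass fraction around one third, comparable to the fraction
of peak-bearing expressed transcripts in real MeRIP data.  (Pushing the
methylated fraction toward 100% is not just unrealistic; it makes the
IP library almost entirely enriched material, which flattens per-bin
relative enrichment toward 1 and degrades the test for everyone — a
property of MeRIP normalisation, not of this implementation.)  The
detection benchmark uses an ~1.3M-read INPUT library; the MeRIP
benchmarks use ~0.3–0.5M INPUT reads, whose 20-fold-enriched IP
companions reach ~2M reads.  The pytest suite runs the same chains at
roughly one-tenth that size.

## Known limitations

* No built-in aligner: real data must be aligned with a
  chimera-reporting aligner first; soft-clip-only junction evidence is
  not rescued.
* Junctions are never merged across small positional offsets; a real
  aligner's wobble at repetitive junction contexts will fragment
  support.
* The linear peak caller is a plain bin-Fisher-merge procedure; it does
  not model local coverage trends or fragment-length smoothing.
* Differential methylation across cohorts, coding-potential scoring and
  network analyses are out of scope.
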