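"""Bin enrichment testing: Fisher exact, BH-FDR, span/confidence rules."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circm6a import (
    LibraryStats,
    adjust_fdr,
    bin_enrichment_test,
    call_linear_peaks,
    call_m6a_circrnas,
    fisher_greater,
    relative_m6a_level,
)
from circm6a.detect import CircRNACall
from circm6a.m6a import bin_coverage, classify_confidence, genome_bin_counts
from circm6a.simulate import SimConfig, SimTranscript, M6aSite, simulate_merip
from circm6a.pipeline import sort_and_index


def hypergeom_tail(a, b, n_ip, n_input):
    """Independent brute-force oracle: P(X >= a) for X hypergeometric with
    population n_ip+n_input, a+b successes, n_ip draws, via exact binomial
    coefficients (no scipy)."""
    K, N, n = a + b, n_ip + n_input, n_ip
    denom = math.comb(N, K)
    total = Fraction(0)
    for x in range(a, min(K, n) + 1):
        if K - x > N - n:
            continue
        total += Fraction(math.comb(n, x) * math.comb(N - n, K - x), denom)
    return float(total)


class TestFisher:
    def test_matches_brute_force_oracle_small_margins(self):
        """p-values agree with the exact tail sum to 1e-9 across a sweep of
        2x2 tables with margins up to 500."""
        cases = []
        for n_ip, n_input in [(50, 50), (123, 77), (500, 400), (500, 500)]:
            for a in [0, 1, 5, 17, 50]:
                for b in [0, 1, 4, 20, 50]:
                    if a <= n_ip and b <= n_input:
                        cases.append((a, b, n_ip, n_input))
        for a, b, n_ip, n_input in cases:
            got = float(fisher_greater(np.array([a]), np.array([b]), n_ip, n_input)[0])
            assert abs(got - hypergeom_tail(a, b, n_ip, n_input)) < 1e-9

    def test_identical_proportions_never_significant(self):
        # empty bins give p exactly 1; equal non-zero proportions sit at or
        # above 0.5 (the observed table is included in the upper tail)
        stats = LibraryStats(1000)
        assert bin_enrichment_test(0, 0, stats, stats) == pytest.approx(1.0)
        p = bin_enrichment_test(10, 10, stats, stats)
        assert p >= 0.5
        assert abs(p - hypergeom_tail(10, 10, 1000, 1000)) < 1e-9

    def test_enriched_bin_matches_oracle(self):
        got = bin_enrichment_test(12, 1, LibraryStats(1000), LibraryStats(1000))
        assert abs(got - hypergeom_tail(12, 1, 1000, 1000)) < 1e-9

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            fisher_greater(np.array([11]), np.array([0]), 10, 100)

    def test_agrees_with_scipy_fisher_exact(self):
        from scipy.stats import fisher_exact

        for a, b, ni, nj in [(12, 1, 1000, 900), (3, 7, 200, 400), (0, 5, 50, 60)]:
            ours = float(fisher_greater(np.array([a]), np.array([b]), ni, nj)[0])
            table = [[a, ni - a], [b, nj - b]]
            assert ours == pytest.approx(fisher_exact(table, "greater")[1], abs=1e-12)


class TestBH:
    def test_hand_computed_triple(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(adjust_fdr([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_q_nondecreasing_in_sorted_p_order(self, ps):
        q = adjust_fdr(ps)
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestBinCoverage:
    def _one_read_bam(self, tmp_path, n_copies=1):
        recs = "".join(
            f"r{i}\t0\tg\t111\t60\t100M\t*\t0\t0\t{'A' * 100}\t{'I' * 100}\n"
            for i in range(n_copies)
        )
        sam = tmp_path / "c.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:g\tLN:1000\n" + recs)
        return sort_and_index(sam, tmp_path / "c.bam")

    def test_read_increments_every_overlapped_bin(self, tmp_path):
        # read [110,210) over a bin grid: bins 100,125,150,175 and 200 each +1
        bam = self._one_read_bam(tmp_path)
        cov = bin_coverage(bam, "g", 100, 225, chrom_length=1000)
        assert cov == [(100, 1), (125, 1), (150, 1), (175, 1), (200, 1)]

    def test_no_reads_all_zero(self, tmp_path):
        bam = self._one_read_bam(tmp_path)
        cov = bin_coverage(bam, "g", 500, 600, chrom_length=1000)
        assert all(c == 0 for _, c in cov)

    def test_two_identical_reads_double_counts(self, tmp_path):
        bam = self._one_read_bam(tmp_path, n_copies=2)
        cov = bin_coverage(bam, "g", 100, 225, chrom_length=1000)
        assert all(c == 2 for _, c in cov)

    def test_genome_bin_counts_split_read_covers_both_sides(self, tmp_path):
        sam = tmp_path / "s.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:g\tLN:1000\n"
            f"r\t0\tg\t801\t60\t60M40S\t*\t0\t0\t{'A' * 100}\t{'I' * 100}\tSA:Z:g,101,+,60S40M,60,0;\n"
            f"r\t2048\tg\t101\t60\t60S40M\t*\t0\t0\t{'A' * 100}\t{'I' * 100}\tSA:Z:g,801,+,60M40S,60,0;\n"
        )
        bam = sort_and_index(sam, tmp_path / "s.bam")
        bins, n_total = genome_bin_counts(bam, {"g": 1000})
        assert n_total == 1  # supplementary not counted in the library total
        assert bins["g"][800 // 25] == 1 and bins["g"][100 // 25] == 1


def _mk_call(chrom, s, e, n_ip, n_input):
    return CircRNACall(chrom, s, e, "+", {"IP": n_ip, "INPUT": n_input},
                       True, True, ["g"], "exonic")


class TestCircCalling:
    N = 10_000

    def _bins(self, enriched_bins, chrom_len=10_000):
        ip = {"g": np.full(chrom_len // 25 + 1, 5, dtype=np.int64)}
        inp = {"g": np.full(chrom_len // 25 + 1, 5, dtype=np.int64)}
        for b in enriched_bins:
            ip["g"][b] = 120
        return ip, inp

    def test_all_flank_bins_enriched_high_confidence(self):
        call = _mk_call("g", 1000, 3000, n_ip=3, n_input=1)
        ip, inp = self._bins(range(0, 400))
        (res,) = call_m6a_circrnas([call], ip, inp, self.N, self.N)
        assert res.spans_bsj and res.confidence == "high"
        assert res.fraction_ratio == pytest.approx(3.0)

    def test_spans_with_single_ip_read_low_confidence(self):
        call = _mk_call("g", 1000, 3000, n_ip=1, n_input=4)
        ip, inp = self._bins(range(0, 400))
        (res,) = call_m6a_circrnas([call], ip, inp, self.N, self.N)
        assert res.spans_bsj and res.confidence == "low"

    def test_donor_side_only_cannot_span_junction(self):
        call = _mk_call("g", 1000, 3000, n_ip=5, n_input=1)
        donor_bins = range((3000 - 100) // 25, 3000 // 25)
        ip, inp = self._bins(donor_bins)
        (res,) = call_m6a_circrnas([call], ip, inp, self.N, self.N)
        assert not res.spans_bsj and res.confidence == "none"

    def test_fdr_one_everything_significant_fdr_zero_nothing(self):
        call = _mk_call("g", 1000, 3000, n_ip=5, n_input=1)
        ip, inp = self._bins([])
        (res1,) = call_m6a_circrnas([call], ip, inp, self.N, self.N, fdr=1.0)
        assert all(res1.significant)
        ip, inp = self._bins(range(0, 400))
        (res0,) = call_m6a_circrnas([call], ip, inp, self.N, self.N, fdr=0.0)
        assert not any(res0.significant)

    def test_short_circle_flanks_truncated_without_overlap(self):
        call = _mk_call("g", 1000, 1150, n_ip=2, n_input=1)  # 150-bp circle
        ip, inp = self._bins(range(0, 400))
        (res,) = call_m6a_circrnas([call], ip, inp, self.N, self.N)
        assert len(res.bins) == len(set(res.bins))
        assert res.spans_bsj  # everything enriched: the short run still crosses

    @settings(derandomize=True, max_examples=60)
    @given(
        st.integers(0, 10), st.integers(0, 10),
        st.floats(0, 5), st.floats(0, 5),
    )
    def test_confidence_monotone_in_support_and_ratio(self, n1, n2, r1, r2):
        rank = {"none": 0, "low": 1, "high": 2}
        lo = classify_confidence(True, min(n1, n2), min(r1, r2))
        hi = classify_confidence(True, max(n1, n2), max(r1, r2))
        assert rank[hi] >= rank[lo]


class TestRelativeLevel:
    def test_equal_normalised_coverage_is_one(self):
        level, used = relative_m6a_level(50, 50, 1000, 1000)
        assert level == pytest.approx(1.0) and not used

    def test_srpbm_ratio(self):
        # IP SRPBM 200, INPUT SRPBM 100 at equal totals -> 2.0
        level, _ = relative_m6a_level(200, 100, 10**9, 10**9)
        assert level == pytest.approx(2.0)

    def test_zero_input_with_pseudo_count(self):
        level, used = relative_m6a_level(10, 0, 1000, 2000)
        assert used and level == pytest.approx((11 / 1000) / (1 / 2000))

    def test_zero_input_without_pseudo_count_missing(self):
        level, used = relative_m6a_level(10, 0, 1000, 2000, pseudo_count=False)
        assert level is None and not used


@pytest.fixture(scope="module")
def peak_sim(toy_ref, tmp_path_factory):
    """One linear transcript with two 200-bp m6A regions ~1.7 kb apart,
    fragmentation before IP."""
    host = [t for t in toy_ref.annotation.transcripts if t.strand == "+"][0]
    seq = "".join(toy_ref.fetch(host.chrom, s, e) for s, e in host.exons)
    t = SimTranscript("lin_test", host.gene_id, host.chrom, "+",
                      "linear", list(host.exons), seq, lam=2)
    # sites centred inside exon 2 and exon 5 (spliced 400-bp exons)
    for pos in (600, 1800):
        gpos = t.spliced_to_blocks(pos, pos + 1)[0][0]
        t.sites.append(M6aSite(pos, "linear", gpos))
    cfg = SimConfig(depth=40.0, strategy="frag_before")
    d = tmp_path_factory.mktemp("peaks")
    sim = simulate_merip([t], toy_ref, cfg, d, seed=31, write_fastq=False,
                         truth_reads="none")
    input_bam = sort_and_index(sim.input_sam, d / "input.bam")
    ip_bam = sort_and_index(sim.ip_sam, d / "ip.bam")
    n_in = int(sim.transcripts["c_input"].sum()) * 2
    n_ip = int(
        (sim.transcripts["c_ip_enriched"] + sim.transcripts["c_ip_background"]).sum()
    ) * 2
    return toy_ref, t, input_bam, ip_bam, n_in, n_ip


class TestLinearPeaks:
    def test_two_separated_regions_give_distinct_peaks(self, peak_sim):
        """Two true regions far apart on the transcript must not merge into
        one peak (enrichment bleeds at most one fragment length beyond a
        region, far less than the separation here)."""
        ref, t, input_bam, ip_bam, n_in, n_ip = peak_sim
        ip_bins, _ = genome_bin_counts(ip_bam, ref.chrom_lengths)
        in_bins, _ = genome_bin_counts(input_bam, ref.chrom_lengths)
        peaks = call_linear_peaks(ref.annotation, ip_bins, in_bins, n_ip, n_in)
        hits = []
        for site in t.sites:
            hits.append(
                {i for i, p in enumerate(peaks)
                 if p.start <= site.genomic_pos < p.end}
            )
        assert all(hits), "each true region must be covered by a peak"
        assert not (hits[0] & hits[1]), "distant regions must give distinct peaks"

    def test_peaks_cover_true_regions(self, peak_sim):
        ref, t, input_bam, ip_bam, n_in, n_ip = peak_sim
        ip_bins, _ = genome_bin_counts(ip_bam, ref.chrom_lengths)
        in_bins, _ = genome_bin_counts(input_bam, ref.chrom_lengths)
        peaks = call_linear_peaks(ref.annotation, ip_bins, in_bins, n_ip, n_in)
        for site in t.sites:
            r0, rlen = t.region_for(site, 200)
            blocks = t.spliced_to_blocks(r0, r0 + rlen)
            truth = {p for s, e in blocks for p in range(s, e)}
            covered = set()
            for p in peaks:
                covered |= {x for x in range(p.start, p.end) if x in truth}
            assert len(covered) / len(truth) >= 0.8
            level = [
                p.relative_level for p in peaks
                if p.start <= site.genomic_pos < p.end
            ]
            assert level and level[0] > 1.5  # enriched region clearly above input

    def test_uniform_coverage_zero_peaks_on_unmethylated_genes(self, peak_sim):
        ref, t, input_bam, ip_bam, n_in, n_ip = peak_sim
        ip_bins, _ = genome_bin_counts(ip_bam, ref.chrom_lengths)
        in_bins, _ = genome_bin_counts(input_bam, ref.chrom_lengths)
        peaks = call_linear_peaks(ref.annotation, ip_bins, in_bins, n_ip, n_in)
        outside = [p for p in peaks
                   if not (t.exons[0][0] - 500 <= p.start <= t.exons[-1][1])]
        assert outside == []
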