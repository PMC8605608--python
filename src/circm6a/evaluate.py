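"""Benchmark scoring of detector output against simulator truth.

Junction-level precision/recall/F1 with configurable positional
tolerance (0 bp by default: simulator truth and detector share
coordinates exactly), stratified scoring of m6A-circRNA calls by the
truth site class (BSJ-proximal vs BSJ-distal), RNase-R response
categories, and a sequencing-depth saturation ladder.

Stratification convention: true-positive and false-negative counts are
partitioned by the truth class of each methylated circRNA (they sum to
the unstratified counts); a call matching no methylated truth at all is
a false positive in every stratum, so stratum F1 still reflects global
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

Junction = tuple[str, int, int]


@dataclass
class EvalReport:
    """Precision/recall/F1 for one comparison stratum."""

    tp: int
    fp: int
    fn: int
    stratum: str = "circRNA"
    depth: float | None = None

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "stratum": self.stratum, "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


def _match(
    calls: set[Junction], truth: set[Junction], tolerance: int
) -> tuple[set[Junction], set[Junction]]:
    """Greedy junction matching; returns (matched_calls, matched_truth)."""
    if tolerance == 0:
        common = calls & truth
        return set(common), set(common)
    matched_calls: set[Junction] = set()
    matched_truth: set[Junction] = set()
    by_chrom: dict[str, list[Junction]] = {}
    for t in truth:
        by_chrom.setdefault(t[0], []).append(t)
    for c in sorted(calls):
        best = None
        for t in by_chrom.get(c[0], []):
            if t in matched_truth:
                continue
            if abs(t[1] - c[1]) <= tolerance and abs(t[2] - c[2]) <= tolerance:
                d = abs(t[1] - c[1]) + abs(t[2] - c[2])
                if best is None or d < best[0]:
                    best = (d, t)
        if best is not None:
            matched_calls.add(c)
            matched_truth.add(best[1])
    return matched_calls, matched_truth


def score_detection(
    calls: Iterable[Junction], truth: Iterable[Junction], match_tolerance: int = 0
) -> EvalReport:
    """Exact-position (or tolerant) junction-set comparison."""
    calls, truth = set(calls), set(truth)
    mc, mt = _match(calls, truth, match_tolerance)
    return EvalReport(tp=len(mt), fp=len(calls - mc), fn=len(truth - mt))


def score_m6a_detection(
    calls: Mapping[Junction, str],
    truth: Mapping[Junction, str],
    include_low_confidence: bool = False,
    stratify_by_site_class: bool = False,
    match_tolerance: int = 0,
) -> dict[str, EvalReport]:
    """Score m6A-circRNA calls against methylated truth.

    ``calls`` maps junction -> confidence class ("high"/"low");
    ``truth`` maps junction -> site class ("bsj_proximal"/"bsj_distal"/
    other).  Low-confidence calls count only when included.
    """
    allowed = {"high", "low"} if include_low_confidence else {"high"}
    called = {j for j, conf in calls.items() if conf in allowed}
    truth_set = set(truth)
    mc, mt = _match(called, truth_set, match_tolerance)
    global_fp = len(called - mc)
    reports = {
        "m6A-circRNA": EvalReport(
            tp=len(mt), fp=global_fp, fn=len(truth_set - mt), stratum="m6A-circRNA"
        )
    }
    if stratify_by_site_class:
        for klass in sorted({k for k in truth.values()}):
            t_k = {j for j, k in truth.items() if k == klass}
            reports[klass] = EvalReport(
                tp=len(mt & t_k), fp=global_fp, fn=len(t_k - mt), stratum=klass
            )
    return reports


def classify_rnase_r(fold_change: float) -> str:
    """RNase-R response category from treated/untreated abundance fold.

    >= 5-fold enrichment: resistant (supports circularity); < 1: depleted
    (likely linear false positive); 1 to 5: unaffected.
    """
    if fold_change < 0:
        raise ValueError("fold change must be >= 0")
    if fold_change >= 5:
        return "resistant"
    if fold_change >= 1:
        return "unaffected"
    return "depleted"


def saturation_curve(
    ref_fasta,
    ref_gtf,
    out_dir,
    depths: Iterable[float],
    seeds: Iterable[int],
    **benchmark_kwargs,
) -> pd.DataFrame:
    """Simulate-detect-score at each depth; one row per (depth, seed).

    Depth on the ladder is the simulator depth factor; the emitted
    INPUT read count is reported alongside.  Medians across seeds give
    the saturation curve.
    """
    from .pipeline import run_benchmark  # deferred: avoids an import cycle

    depths = list(depths)
    if len(depths) < 2:
        raise ValueError("at least two depths required for a saturation curve")
    rows = []
    out_dir = __import__("pathlib").Path(out_dir)
    for depth in depths:
        for seed in seeds:
            summary = run_benchmark(
                ref_fasta, ref_gtf, out_dir / f"d{depth}_s{seed}",
                seed=seed, depth=depth, **benchmark_kwargs,
            )
            rows.append(
                {
                    "depth": depth,
                    "seed": seed,
                    "input_reads": summary["input_reads"],
                    "f1_circ": summary["f1_circ"],
                    "f1_m6a": summary.get("f1_m6a_high"),
                }
            )
    return pd.DataFrame(rows)
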