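"""End-to-end differential-methylation pipeline and recovery evaluation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deps import DEP, assign_promoter, filter_deps
from .peaks import find_peaks, merge_peaks, window_score
from .simulate import GroundTruth
from .tiling import IntensityMatrix, ProbeDesign, log_ratio


def run_differential_pipeline(m: IntensityMatrix, design: ProbeDesign,
                              window_bp: int = 750, cutoff: float = 2.0,
                              min_probes: int = 2, merge_gap: int = 500,
                              median_min: float = 0.3, cv_max: float = 0.8,
                              cv_frac: float = 0.5,
                              group1: str = "HF-CON", group2: str = "CON-CON",
                              median_center: bool = False,
                              promoter_classes: dict[str, str] | None = None) -> list[DEP]:
    """Enrichment -> per-group peak calling -> merging -> DEP filtering.

    Candidate regions are the union of peaks called on either group-mean
    track: regions enriched in the treatment track yield hypermethylated
    DEPs, regions enriched in the control track hypomethylated ones.
    """
    enrich = log_ratio(m, median_center=median_center)
    candidates = []
    for g in (group1, group2):
        track = enrich.group_mean(g)
        scores = window_score(track, design, window_bp=window_bp)
        raw = find_peaks(scores, design, cutoff=cutoff, min_probes=min_probes, group=g)
        candidates.extend(merge_peaks(raw, gap_bp=merge_gap))
    deps = filter_deps(candidates, enrich, m, median_min=median_min,
                       cv_max=cv_max, cv_frac=cv_frac, group1=group1, group2=group2)
    return [assign_promoter(d, design, promoter_classes) for d in deps]


@dataclass
class RecoveryStats:
    """How well called DEPs recover the planted truth of one experiment."""

    n_truth: int
    n_called: int
    n_truth_recovered: int
    n_called_true: int
    n_direction_correct: int
    mprime_errors: list[float]  # called M' minus signed planted effect, matched DEPs

    @property
    def recall(self) -> float:
        return self.n_truth_recovered / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_called_true / self.n_called if self.n_called else float("nan")

    @property
    def direction_accuracy(self) -> float:
        return (self.n_direction_correct / self.n_called_true
                if self.n_called_true else float("nan"))


def evaluate_recovery(deps: list[DEP], truth: GroundTruth) -> RecoveryStats:
    """Match called DEPs to planted regions by genomic overlap.

    A planted region counts as recovered if any DEP overlaps it; a DEP is
    true if it overlaps any planted region (matched to the region with the
    largest overlap).  The M' error compares the called M' with the signed
    planted effect (+effect for hyper, -effect for hypo)."""
    recovered = set()
    n_called_true = 0
    n_direction = 0
    errors: list[float] = []
    for dep in deps:
        best, best_ov = None, 0
        for region in truth.regions:
            if region.chrom != dep.chrom:
                continue
            ov = min(dep.end, region.end) - max(dep.start, region.start)
            if ov > 0 and ov > best_ov:
                best, best_ov = region, ov
        if best is None:
            continue
        n_called_true += 1
        recovered.add((best.chrom, best.start, best.end))
        if dep.direction == best.direction:
            n_direction += 1
        signed = best.effect if best.direction == "hyper" else -best.effect
        errors.append(dep.mprime - signed)
    return RecoveryStats(
        n_truth=len(truth.regions), n_called=len(deps),
        n_truth_recovered=len(recovered), n_called_true=n_called_true,
        n_direction_correct=n_direction, mprime_errors=errors)


def pooled_recovery(stats_list: list[RecoveryStats]) -> RecoveryStats:
    """Pool per-seed recovery statistics over a Monte-Carlo run."""
    return RecoveryStats(
        n_truth=sum(s.n_truth for s in stats_list),
        n_called=sum(s.n_called for s in stats_list),
        n_truth_recovered=sum(s.n_truth_recovered for s in stats_list),
        n_called_true=sum(s.n_called_true for s in stats_list),
        n_direction_correct=sum(s.n_direction_correct for s in stats_list),
        mprime_errors=[e for s in stats_list for e in s.mprime_errors])
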