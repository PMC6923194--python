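"""Differential enrichment peak (DEP) statistics, filtering and tallies.

A candidate peak becomes a DEP when it survives two criteria:

1. at least one of the two groups has a median member-probe
   log2(MeDIP/Input) >= 0.3 and the differential statistic M' is non-zero
   (M' > 0 marks hypermethylation in the treatment group, M' < 0
   hypomethylation);
2. in each group separately, at least half of the member probes have a
   replicate coefficient of variability (CV) <= 0.8 on the linear-scale
   MeDIP/Input ratio.

M' is the unweighted arithmetic mean of r = log2(MeDIP/Input) over the
peak's member probes and the treatment group's samples, minus the same
mean for the control group.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import Peak
from .tiling import EnrichmentMatrix, IntensityMatrix, ProbeDesign

CPG_CLASSES = ("HCP", "ICP", "LCP")


@dataclass(frozen=True)
class DEP:
    """A peak that passed both filter criteria, with its region statistics."""

    peak: Peak
    mprime: float
    direction: str  # "hyper" | "hypo"
    medians: dict = field(default_factory=dict)       # group -> median member-probe r
    cv_pass_frac: dict = field(default_factory=dict)  # group -> fraction of probes with CV <= cv_max
    gene_ids: tuple[str, ...] = ()
    cpg_class: str | None = None

    @property
    def chrom(self) -> str:
        return self.peak.chrom

    @property
    def start(self) -> int:
        return self.peak.start

    @property
    def end(self) -> int:
        return self.peak.end

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return self.peak.probe_ids


def region_mprime(peak: Peak, enrich: EnrichmentMatrix,
                  group1: str = "HF-CON", group2: str = "CON-CON") -> float:
    """M' = mean r over (member probes x group1 samples) minus the same for group2."""
    if not peak.probe_ids:
        raise ValueError("peak has no member probes")
    s1 = enrich.samples_of_group(group1)
    s2 = enrich.samples_of_group(group2)
    block = enrich.values.loc[list(peak.probe_ids)]
    return float(block[s1].to_numpy().mean() - block[s2].to_numpy().mean())


def group_cv(m: IntensityMatrix, group: str) -> pd.Series:
    """Per-probe CV (sample sd / mean, ddof=1) of the linear MeDIP/Input
    ratio across the group's replicates."""
    cols = m.samples_of_group(group)
    if len(cols) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 replicates; CV undefined")
    ratios = (m.medip[cols] / m.input_[cols])
    return ratios.std(axis=1, ddof=1) / ratios.mean(axis=1)


def probe_cv(m: IntensityMatrix, probe_id: str, group: str) -> float:
    return float(group_cv(m, group).loc[probe_id])


def filter_deps(peaks: list[Peak], enrich: EnrichmentMatrix, m: IntensityMatrix,
                median_min: float = 0.3, cv_max: float = 0.8, cv_frac: float = 0.5,
                group1: str = "HF-CON", group2: str = "CON-CON") -> list[DEP]:
    """Apply both DEP criteria to candidate peaks.

    The per-group median is taken over the member probes' group-mean
    enrichment values.  Output is sorted by |M'| descending (ties broken by
    genomic position for determinism).
    """
    if not peaks:
        return []
    mean1 = enrich.group_mean(group1)
    mean2 = enrich.group_mean(group2)
    cv1 = group_cv(m, group1)
    cv2 = group_cv(m, group2)
    deps: list[DEP] = []
    for peak in peaks:
        ids = list(peak.probe_ids)
        med = {group1: float(mean1.loc[ids].median()),
               group2: float(mean2.loc[ids].median())}
        if max(med.values()) < median_min:
            continue
        mprime = region_mprime(peak, enrich, group1, group2)
        if mprime == 0.0:
            continue
        frac = {group1: float((cv1.loc[ids] <= cv_max).mean()),
                group2: float((cv2.loc[ids] <= cv_max).mean())}
        if frac[group1] < cv_frac or frac[group2] < cv_frac:
            continue
        deps.append(DEP(peak=peak, mprime=mprime,
                        direction="hyper" if mprime > 0 else "hypo",
                        medians=med, cv_pass_frac=frac))
    deps.sort(key=lambda d: (-abs(d.mprime), d.chrom, d.start))
    return deps


def assign_promoter(dep: DEP, design: ProbeDesign,
                    promoter_classes: dict[str, str] | None = None) -> DEP:
    """Attach the promoter/gene ids of the member probes.

    A DEP spanning probes from k promoters carries all k gene ids.  Its CpG
    class is that of the promoter contributing the most member probes
    (first-seen promoter wins ties).
    """
    prom_of = design.promoter_of_probe()
    proms = [prom_of.loc[p] for p in dep.probe_ids]
    gene_ids = tuple(dict.fromkeys(proms))
    cls = None
    if promoter_classes is not None:
        counts = {g: proms.count(g) for g in gene_ids}
        top = max(gene_ids, key=lambda g: counts[g])
        cls = promoter_classes.get(top)
    return dataclasses.replace(dep, gene_ids=gene_ids, cpg_class=cls)


@dataclass
class DEPTally:
    """Counts of DEPs by direction, direction x CpG class, and chromosome."""

    by_class: dict       # direction -> {class: count}
    by_chrom: dict       # direction -> {chrom: count}

    DIRECTIONS = ("hyper", "hypo")

    def __post_init__(self) -> None:
        for d in self.DIRECTIONS:
            self.by_class.setdefault(d, {})
            self.by_chrom.setdefault(d, {})

    @classmethod
    def from_deps(cls, deps: list[DEP]) -> "DEPTally":
        by_class: dict = {d: {} for d in cls.DIRECTIONS}
        by_chrom: dict = {d: {} for d in cls.DIRECTIONS}
        for dep in deps:
            key = dep.cpg_class if dep.cpg_class is not None else "unclassified"
            by_class[dep.direction][key] = by_class[dep.direction].get(key, 0) + 1
            by_chrom[dep.direction][dep.chrom] = by_chrom[dep.direction].get(dep.chrom, 0) + 1
        return cls(by_class=by_class, by_chrom=by_chrom)

    @classmethod
    def from_counts(cls, hyper: dict[str, int], hypo: dict[str, int]) -> "DEPTally":
        """Build a tally directly from direction x class counts (e.g. a
        published table), leaving the chromosome breakdown empty."""
        return cls(by_class={"hyper": dict(hyper), "hypo": dict(hypo)},
                   by_chrom={"hyper": {}, "hypo": {}})

    def direction_total(self, direction: str) -> int:
        return sum(self.by_class[direction].values())

    @property
    def total(self) -> int:
        return sum(self.direction_total(d) for d in self.DIRECTIONS)

    def percentages(self, direction: str) -> dict[str, float]:
        """Class percentages within a direction, count/direction-total x 100,
        rounded to 2 decimals.  An empty direction yields an empty dict."""
        total = self.direction_total(direction)
        if total == 0:
            return {}
        return {k: round(100.0 * v / total, 2) for k, v in self.by_class[direction].items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.DIRECTIONS:
            pct = self.percentages(d)
            for k, v in sorted(self.by_class[d].items()):
                rows.append({"direction": d, "cpg_class": k, "count": v,
                             "percent_of_direction": pct.get(k, float("nan"))})
            rows.append({"direction": d, "cpg_class": "total",
                         "count": self.direction_total(d), "percent_of_direction": 100.0
                         if self.direction_total(d) else float("nan")})
        rows.append({"direction": "all", "cpg_class": "total", "count": self.total,
                     "percent_of_direction": float("nan")})
        return pd.DataFrame(rows)

    def report(self) -> str:
        lines = [f"Total DEPs: {self.total}"]
        for d in self.DIRECTIONS:
            total = self.direction_total(d)
            lines.append(f"  {d}methylated: {total}")
            pct = self.percentages(d)
            for k in sorted(self.by_class[d]):
                lines.append(f"    {k}: {self.by_class[d][k]} ({pct[k]:.2f}%)")
            if self.by_chrom[d]:
                chrom_str = ", ".join(f"{c}:{n}" for c, n in sorted(self.by_chrom[d].items()))
                lines.append(f"    by chromosome: {chrom_str}")
        return "\n".join(lines)


def tally(deps: list[DEP]) -> DEPTally:
    t = DEPTally.from_deps(deps)
    # conservation invariants, asserted on every run
    assert t.total == sum(t.direction_total(d) for d in DEPTally.DIRECTIONS)
    for d in DEPTally.DIRECTIONS:
        assert t.direction_total(d) == sum(t.by_class[d].values())
        if t.by_chrom[d]:
            assert t.direction_total(d) == sum(t.by_chrom[d].values())
    return t


def write_deps(deps: list[DEP], path) -> None:
    """DEPs as BED6+ (extra columns: M', direction, gene ids, CpG class)."""
    rows = []
    for i, d in enumerate(deps):
        rows.append({
            "chrom": d.chrom, "start": d.start, "end": d.end,
            "name": f"dep{i:05d}",
            "score": int(np.clip(round(10 * d.peak.score), 0, 1000)),
            "strand": ".",
            "mprime": d.mprime,
            "direction": d.direction,
            "gene_ids": ",".join(d.gene_ids) if d.gene_ids else ".",
            "cpg_class": d.cpg_class if d.cpg_class else ".",
            "probe_ids": ",".join(d.probe_ids),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
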