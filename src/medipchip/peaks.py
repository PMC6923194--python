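"""Sliding-window peak detection over per-probe enrichment tracks.

The scorer follows the NimbleScan/ACME family of tiling-array peak finders:
for every probe, the enrichment values of all probes whose midpoints fall
within a fixed genomic window around it are compared against the array-wide
enrichment distribution with a one-sided two-sample Kolmogorov–Smirnov
test (alternative: window stochastically greater), and the probe is scored
as -log10 of the Smirnov one-sided tail bound

    p = exp(-2 * m * n * D^2 / (m + n)),

where D = sup_t [F_array(t) - F_window(t)], m is the window size and n the
array size.  Peaks are maximal runs of at least ``min_probes`` consecutive
probes scoring at or above the cutoff, and nearby peaks are merged on
genomic distance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tiling import ProbeDesign

_LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class Peak:
    """A contiguous run of qualifying probes.

    ``start``/``end`` span the member probes (0-based half-open); ``score``
    is the maximum member window score; ``group`` records which group-mean
    track the peak was called on.
    """

    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    score: float
    group: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("degenerate peak interval")
        if not self.probe_ids:
            raise ValueError("peak without member probes")


def ks_greater_statistic(window: np.ndarray, sorted_global: np.ndarray) -> float:
    """One-sided two-sample KS statistic D = sup_t [F_global(t) - F_window(t)].

    Large D means the window values sit in the upper tail of the global
    distribution.  ``sorted_global`` must be sorted ascending.
    """
    xs = np.sort(np.asarray(window, dtype=float))
    m = xs.size
    n = sorted_global.size
    if m == 0 or n == 0:
        raise ValueError("empty sample in KS statistic")
    f_global = np.searchsorted(sorted_global, xs, side="left") / n
    f_window = np.arange(m) / m
    return float(max(0.0, np.max(f_global - f_window)))


def _score_from_d(d: float, m: int, n: int) -> float:
    # -log10 of the Smirnov one-sided bound exp(-2 m n D^2 / (m+n))
    return 2.0 * m * n * d * d / ((m + n) * _LN10)


def window_score(track: pd.Series, design: ProbeDesign, window_bp: int = 750) -> pd.Series:
    """Score every probe of a group-mean enrichment track.

    For each probe, member probes are those on the same chromosome whose
    midpoints lie within +/- window_bp/2 of its midpoint.  Windows with
    fewer than two probes score 0.
    """
    if len(track) == 0:
        raise ValueError("empty enrichment track")
    values = track.reindex(design.probe_ids).to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("non-finite values in enrichment track")
    n = values.size
    sorted_global = np.sort(values)
    mids = design.midpoints()
    chroms = design.probes["chrom"].to_numpy()
    half = window_bp / 2.0
    scores = np.zeros(n)
    # design is sorted by (chrom, start): scan each chromosome block
    boundaries = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1], True])
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        cmids = mids[b0:b1]
        lo = np.searchsorted(cmids, cmids - half, side="left")
        hi = np.searchsorted(cmids, cmids + half, side="right")
        for i in range(b1 - b0):
            m = hi[i] - lo[i]
            if m < 2:
                continue
            window = values[b0 + lo[i]:b0 + hi[i]]
            d = ks_greater_statistic(window, sorted_global)
            scores[b0 + i] = _score_from_d(d, m, n)
    return pd.Series(scores, index=design.probe_ids)


def find_peaks(scores: pd.Series, design: ProbeDesign, cutoff: float = 2.0,
               min_probes: int = 2, group: str | None = None) -> list[Peak]:
    """Maximal same-chromosome runs of consecutive design-order probes with
    score >= cutoff and at least ``min_probes`` members.  Ties at exactly
    the cutoff are included."""
    s = scores.reindex(design.probe_ids).to_numpy(dtype=float)
    df = design.probes
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    ids = df["probe_id"].to_numpy()
    peaks: list[Peak] = []
    run_start = None
    for i in range(len(df) + 1):
        in_run = i < len(df) and s[i] >= cutoff
        if in_run and run_start is not None and chroms[i] != chroms[run_start]:
            in_run_continues = False
        else:
            in_run_continues = in_run
        if run_start is None:
            if in_run:
                run_start = i
            continue
        if in_run_continues:
            continue
        # close run [run_start, i)
        if i - run_start >= min_probes:
            peaks.append(Peak(
                chrom=str(chroms[run_start]),
                start=int(starts[run_start:i].min()),
                end=int(ends[run_start:i].max()),
                probe_ids=tuple(ids[run_start:i]),
                score=float(s[run_start:i].max()),
                group=group,
            ))
        run_start = i if in_run else None
    return peaks


def merge_peaks(peaks: list[Peak], gap_bp: int = 500) -> list[Peak]:
    """Merge same-chromosome peaks whose genomic gap (next.start - prev.end)
    is at most ``gap_bp``, repeated to a fixed point.

    Member probes are concatenated (duplicates dropped, order preserved) and
    the merged score is the maximum.  The result is independent of the
    input order and the operation is idempotent.
    """
    out: list[Peak] = []
    for p in sorted(peaks, key=lambda q: (q.chrom, q.start, q.end)):
        if out and out[-1].chrom == p.chrom and p.start - out[-1].end <= gap_bp:
            prev = out[-1]
            group = prev.group if prev.group == p.group else None
            out[-1] = Peak(
                chrom=prev.chrom,
                start=min(prev.start, p.start),
                end=max(prev.end, p.end),
                probe_ids=tuple(dict.fromkeys(prev.probe_ids + p.probe_ids)),
                score=max(prev.score, p.score),
                group=group,
            )
        else:
            out.append(p)
    return out


def write_peaks(peaks: list[Peak], path) -> None:
    """Peaks as a TSV that round-trips probe membership (BED-like columns
    first; the BED score is 10 x max -log10 p clamped to [0, 1000])."""
    rows = []
    for i, p in enumerate(peaks):
        rows.append({
            "chrom": p.chrom, "start": p.start, "end": p.end,
            "name": f"peak{i:05d}",
            "score": int(np.clip(round(10 * p.score), 0, 1000)),
            "strand": ".",
            "group": p.group if p.group is not None else ".",
            "max_neglog10_p": p.score,
            "probe_ids": ",".join(p.probe_ids),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_peaks(path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "group": str})
    peaks = []
    for _, row in df.iterrows():
        peaks.append(Peak(
            chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
            probe_ids=tuple(str(row["probe_ids"]).split(",")),
            score=float(row["max_neglog10_p"]),
            group=None if row["group"] == "." else row["group"],
        ))
    return peaks
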