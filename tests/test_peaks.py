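"""Sliding-window KS scoring, run detection and peak merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import medipchip as mc
from medipchip.peaks import (Peak, find_peaks, ks_greater_statistic, merge_peaks,
                             window_score, _score_from_d)

from conftest import toy_design

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_window_score(track, design, window_bp=750):
    """Per-window one-sided KS coded from the definition: D as an explicit
    maximum of F_global - F_window over every observed value, p from the
    Smirnov one-sided bound."""
    values = np.asarray(track, float)
    mids = design.midpoints()
    chroms = design.probes["chrom"].to_numpy()
    n = len(values)
    scores = np.zeros(n)
    for i in range(n):
        member = [j for j in range(n)
                  if chroms[j] == chroms[i] and abs(mids[j] - mids[i]) <= window_bp / 2]
        if len(member) < 2:
            continue
        window = values[member]
        m = len(window)
        d = 0.0
        for t in np.concatenate([values, window]):
            f_glob = np.mean(values <= t)
            f_win = np.mean(window <= t)
            d = max(d, f_glob - f_win)
            # also the left limit, just below each jump
            f_glob_l = np.mean(values < t)
            f_win_l = np.mean(window < t)
            d = max(d, f_glob_l - f_win_l)
        p = np.exp(-2 * m * n * d * d / (m + n))
        scores[i] = -np.log10(p) if p > 0 else np.inf
    return scores


def brute_force_peaks(scores, chroms, cutoff=2.0, min_probes=2):
    """Exhaustive enumeration of maximal qualifying runs."""
    n = len(scores)
    runs = []
    for i in range(n):
        for j in range(i + min_probes, n + 1):
            if all(scores[k] >= cutoff and chroms[k] == chroms[i] for k in range(i, j)):
                left_ok = i == 0 or scores[i - 1] < cutoff or chroms[i - 1] != chroms[i]
                right_ok = j == n or scores[j] < cutoff or chroms[j] != chroms[i]
                if left_ok and right_ok:
                    runs.append((i, j))
    return runs


def brute_force_merge(intervals, gap_bp=500):
    """Fixed point of repeated pairwise merging, any order."""
    items = [list(x) for x in intervals]
    changed = True
    while changed:
        changed = False
        for a in range(len(items)):
            for b in range(len(items)):
                if a == b:
                    continue
                ca, sa, ea = items[a]
                cb, sb, eb = items[b]
                gap = max(sa, sb) - min(ea, eb)
                if ca == cb and gap <= gap_bp:
                    items[a] = [ca, min(sa, sb), max(ea, eb)]
                    items.pop(b)
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(x) for x in items)


# ---------------------------------------------------------------------------
# window scoring


def test_flat_track_scores_zero():
    design = toy_design(range(0, 1000, 100))
    track = pd.Series(1.0, index=design.probe_ids)
    assert (window_score(track, design) == 0).all()


def test_isolated_probe_scores_zero():
    rows = pd.DataFrame({"probe_id": ["a", "b", "c"],
                         "chrom": ["chr1", "chr1", "chr2"],
                         "start": [0, 100, 0], "end": [50, 150, 50],
                         "promoter_id": ["g", "g", "h"]})
    design = mc.ProbeDesign(rows)
    track = pd.Series([0.0, 0.0, 5.0], index=design.probe_ids)
    scores = window_score(track, design)
    assert scores.loc["c"] == 0.0  # alone on its chromosome


def test_window_score_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    design = toy_design(range(0, 2500, 250))
    track = pd.Series(rng.normal(0, 1, 10), index=design.probe_ids)
    track.iloc[3:7] += 3.0
    got = window_score(track, design).to_numpy()
    expected = brute_force_window_score(track.to_numpy(), design)
    np.testing.assert_allclose(got, expected, atol=1e-10)


def test_ks_statistic_matches_scipy():
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = int(rng.integers(5, 80))
        m = int(rng.integers(2, min(7, n)))
        glob = np.round(rng.normal(size=n), 1)  # ties on purpose
        window = glob[rng.choice(n, m, replace=False)]
        d = ks_greater_statistic(window, np.sort(glob))
        ref = stats.ks_2samp(window, glob, alternative="less").statistic
        assert d == pytest.approx(ref, abs=1e-12)


def test_empty_track_fails():
    design = toy_design([0, 100])
    with pytest.raises(ValueError):
        window_score(pd.Series(dtype=float), design)


# ---------------------------------------------------------------------------
# run detection


def test_two_qualifying_probes_form_peak():
    design = toy_design([0, 100, 200, 300])
    scores = pd.Series([0.0, 3.0, 3.0, 0.0], index=design.probe_ids)
    peaks = find_peaks(scores, design)
    assert len(peaks) == 1
    assert peaks[0].probe_ids == ("t001", "t002")
    assert (peaks[0].start, peaks[0].end) == (100, 250)


def test_isolated_high_scores_do_not_peak():
    design = toy_design([0, 100, 200])
    scores = pd.Series([3.0, 0.0, 3.0], index=design.probe_ids)
    assert find_peaks(scores, design) == []


def test_cutoff_tie_is_included():
    design = toy_design([0, 100])
    scores = pd.Series([2.0, 2.0], index=design.probe_ids)
    assert len(find_peaks(scores, design, cutoff=2.0)) == 1


def test_runs_break_at_chromosome_boundary():
    rows = pd.DataFrame({"probe_id": ["a", "b", "c", "d"],
                         "chrom": ["chr1", "chr1", "chr2", "chr2"],
                         "start": [0, 100, 0, 100], "end": [50, 150, 50, 150],
                         "promoter_id": ["g"] * 4})
    design = mc.ProbeDesign(rows)
    scores = pd.Series([3.0, 3.0, 3.0, 3.0], index=design.probe_ids)
    peaks = find_peaks(scores, design)
    assert len(peaks) == 2
    assert {p.chrom for p in peaks} == {"chr1", "chr2"}


def test_find_peaks_matches_exhaustive_enumeration():
    rng = np.random.default_rng(23)
    for _ in range(300):
        n = int(rng.integers(2, 50))
        scores = np.where(rng.random(n) < 0.45, rng.uniform(2, 5, n), rng.uniform(0, 2, n))
        scores[rng.random(n) < 0.1] = 2.0  # exact-cutoff ties
        chroms = np.sort(rng.choice(["chr1", "chr2"], n))
        rows = pd.DataFrame({"probe_id": [f"p{i}" for i in range(n)],
                             "chrom": chroms,
                             "start": np.arange(n) * 100,
                             "end": np.arange(n) * 100 + 50,
                             "promoter_id": ["g"] * n})
        design = mc.ProbeDesign(rows)
        got = find_peaks(pd.Series(scores, index=design.probe_ids), design)
        expected = brute_force_peaks(scores, list(design.probes["chrom"]))
        assert [(design.probes["probe_id"].iloc[i], design.probes["probe_id"].iloc[j - 1])
                for i, j in expected] == [(p.probe_ids[0], p.probe_ids[-1]) for p in got]


# ---------------------------------------------------------------------------
# merging


def make_peak(chrom, start, end, ids=("x",), score=3.0):
    return Peak(chrom=chrom, start=start, end=end, probe_ids=tuple(ids), score=score)


def test_merge_within_gap():
    a = make_peak("chr1", 0, 100, ("a",))
    b = make_peak("chr1", 500, 600, ("b",))
    merged = merge_peaks([a, b], gap_bp=500)
    assert len(merged) == 1
    assert (merged[0].start, merged[0].end) == (0, 600)
    assert merged[0].probe_ids == ("a", "b")


def test_no_merge_beyond_gap():
    a = make_peak("chr1", 0, 100)
    b = make_peak("chr1", 601, 700, ("y",))
    assert len(merge_peaks([a, b], gap_bp=500)) == 2


def test_chain_merging_collapses_and_is_order_independent():
    chain = [make_peak("chr1", i * 400, i * 400 + 100, (f"p{i}",)) for i in range(6)]
    merged = merge_peaks(chain)
    assert len(merged) == 1
    rng = np.random.default_rng(1)
    for _ in range(5):
        perm = [chain[i] for i in rng.permutation(6)]
        again = merge_peaks(perm)
        assert [(p.chrom, p.start, p.end) for p in again] == \
               [(p.chrom, p.start, p.end) for p in merged]


def test_merge_is_idempotent_and_matches_fixed_point_oracle():
    rng = np.random.default_rng(9)
    for _ in range(100):
        k = int(rng.integers(1, 10))
        peaks = []
        for i in range(k):
            chrom = rng.choice(["chr1", "chr2"])
            start = int(rng.integers(0, 5000))
            peaks.append(make_peak(chrom, start, start + int(rng.integers(50, 400)),
                                   (f"q{i}",)))
        merged = merge_peaks(peaks)
        twice = merge_peaks(merged)
        assert [(p.chrom, p.start, p.end) for p in merged] == \
               [(p.chrom, p.start, p.end) for p in twice]
        oracle = brute_force_merge([(p.chrom, p.start, p.end) for p in peaks])
        assert sorted((p.chrom, p.start, p.end) for p in merged) == oracle


def test_peaks_round_trip(tmp_path):
    peaks = [make_peak("chr1", 0, 100, ("a", "b"), 3.5),
             make_peak("chr2", 50, 500, ("c", "d", "e"), 12.0)]
    from medipchip.peaks import read_peaks, write_peaks
    path = tmp_path / "peaks.tsv"
    write_peaks(peaks, path)
    back = read_peaks(path)
    assert [(p.chrom, p.start, p.end, p.probe_ids) for p in back] == \
           [(p.chrom, p.start, p.end, p.probe_ids) for p in peaks]
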