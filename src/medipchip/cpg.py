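"""CpG-density classification of promoter sequences (HCP / ICP / LCP).

Promoters are scanned with a sliding 500-bp window stepping 5 bp.  A
promoter is a high-CpG promoter (HCP) if any window has CpG
observed/expected ratio > 0.75 and GC fraction > 0.55; a low-CpG promoter
(LCP) if no window reaches ratio >= 0.48; intermediate (ICP) otherwise.
These are the Weber-style thresholds standard for mouse promoters; all
four numbers are parameters.

The observed/expected ratio of a window of L counted bases is
(#CG dinucleotides x L) / (#C x #G), with ratio 0 when #C or #G is 0.
N bases are excluded from all counts and windows with more than 10% N are
skipped.  CpG is its own reverse complement, so one strand suffices.
"""

from __future__ import annotations

import warnings

import numpy as np

HCP_RATIO = 0.75
HCP_GC = 0.55
LCP_RATIO = 0.48
WINDOW_BP = 500
STEP_BP = 5


def cpg_obs_exp(seq: str) -> tuple[float, float]:
    """Return (CpG observed/expected ratio, GC fraction) of one window.

    Counts every position i with seq[i:i+2] == "CG" (the dinucleotide
    cannot overlap itself, so plain substring counting is exact).
    """
    if len(seq) == 0:
        raise ValueError("empty window")
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected character(s) in sequence: {sorted(bad)}")
    length = len(s) - s.count("N")
    if length < 2:
        raise ValueError("window has fewer than 2 counted bases")
    c = s.count("C")
    g = s.count("G")
    cg = s.count("CG")
    ratio = cg * length / (c * g) if c * g > 0 else 0.0
    gc = (c + g) / length
    return ratio, gc


def window_scan(seq: str, window_bp: int = WINDOW_BP, step_bp: int = STEP_BP,
                max_n_frac: float = 0.10):
    """Vectorized sliding-window CpG statistics.

    Returns (starts, ratio, gc, keep) arrays; ``keep`` is False for windows
    exceeding the N-fraction limit.  A final window flush with the sequence
    end is always included.
    """
    if len(seq) < window_bp:
        raise ValueError("sequence shorter than window")
    if step_bp < 1:
        raise ValueError("step must be >= 1")
    s = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    is_c = s == b"C"
    is_g = s == b"G"
    is_n = s == b"N"
    is_cg = is_c[:-1] & is_g[1:]

    def cum(a):
        out = np.zeros(len(a) + 1, dtype=np.int64)
        np.cumsum(a, out=out[1:])
        return out

    c_c, c_g, c_n, c_cg = cum(is_c), cum(is_g), cum(is_n), cum(is_cg)
    starts = list(range(0, len(seq) - window_bp + 1, step_bp))
    if starts[-1] != len(seq) - window_bp:
        starts.append(len(seq) - window_bp)
    starts = np.asarray(starts, dtype=np.int64)
    ends = starts + window_bp
    n_c = c_c[ends] - c_c[starts]
    n_g = c_g[ends] - c_g[starts]
    n_n = c_n[ends] - c_n[starts]
    # a CG pair starting at i lies inside [start, end) iff start <= i <= end-2
    n_cg = c_cg[ends - 1] - c_cg[starts]
    length = window_bp - n_n
    denom = (n_c * n_g).astype(float)
    ratio = np.divide(n_cg * length.astype(float), denom,
                      out=np.zeros(len(starts)), where=denom > 0)
    gc = (n_c + n_g) / np.maximum(length, 1)
    keep = n_n <= max_n_frac * window_bp
    return starts, ratio, gc, keep


def classify_promoter(seq: str, window_bp: int = WINDOW_BP, step_bp: int = STEP_BP,
                      hcp_ratio: float = HCP_RATIO, hcp_gc: float = HCP_GC,
                      lcp_ratio: float = LCP_RATIO, max_n_frac: float = 0.10) -> str:
    """Classify one promoter sequence as "HCP", "ICP" or "LCP"."""
    if len(seq) < window_bp:
        warnings.warn("sequence shorter than the scan window; classifying on the whole sequence",
                      stacklevel=2)
        ratio, gc = cpg_obs_exp(seq)
        ratios = np.array([ratio])
        gcs = np.array([gc])
    else:
        _, ratios, gcs, keep = window_scan(seq, window_bp, step_bp, max_n_frac)
        if not keep.any():
            raise ValueError("every window exceeds the N-fraction limit")
        ratios, gcs = ratios[keep], gcs[keep]
    if np.any((ratios > hcp_ratio) & (gcs > hcp_gc)):
        return "HCP"
    if not np.any(ratios >= lcp_ratio):
        return "LCP"
    return "ICP"


def classify_fasta(path, **kwargs) -> dict[str, str]:
    """Classify every record of a FASTA file; returns id -> class."""
    from Bio import SeqIO

    return {rec.id: classify_promoter(str(rec.seq), **kwargs)
            for rec in SeqIO.parse(str(path), "fasta")}
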