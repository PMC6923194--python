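"""Bisulfite-sequencing-PCR (BSP) clone analysis.

Bisulfite treatment converts unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine resists conversion.  Each sequenced
clone of an amplicon therefore reads C at a CpG site if that site was
methylated and T if not; cytosines outside CpG context should all read T,
and the fraction that do is the clone's conversion efficiency — a QC
metric for incomplete bisulfite treatment.

Calls are encoded as floats: 1.0 methylated, 0.0 unmethylated, NaN
ambiguous (any base other than C/T at the site).  Ambiguous calls are
excluded from every denominator.  The mouse (subject) is the statistical
unit for group comparisons: clones within a subject are pooled.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METHYLATED = 1.0
UNMETHYLATED = 0.0


def find_cpg_positions(reference: str) -> tuple[int, ...]:
    """0-based positions of the C of every CpG dinucleotide."""
    ref = reference.upper()
    return tuple(i for i in range(len(ref) - 1) if ref[i:i + 2] == "CG")


@dataclass
class CloneSet:
    """Reference amplicon + per-subject bisulfite clone sequences."""

    reference: str
    clones: dict[str, list[str]]                     # subject -> clone sequences
    groups: dict[str, tuple[str, str]] = field(default_factory=dict)
    cpg_positions: tuple[int, ...] = ()
    primer_regions: tuple[tuple[int, int], ...] = ()  # [start, end) intervals to exclude

    def __post_init__(self) -> None:
        if not self.cpg_positions:
            self.cpg_positions = find_cpg_positions(self.reference)
        if not self.cpg_positions:
            raise ValueError("reference amplicon contains no CpG site")
        if self.primer_regions:
            kept = tuple(p for p in self.cpg_positions
                         if not any(s <= p < e for s, e in self.primer_regions))
            if not kept:
                raise ValueError("primer exclusion removes every CpG site")
            self.cpg_positions = kept
        for subject, seqs in self.clones.items():
            for clone in seqs:
                if len(clone) != len(self.reference):
                    raise ValueError(
                        f"clone of subject {subject!r} has length {len(clone)}, "
                        f"reference is {len(self.reference)}")


@dataclass
class MethylationCallMatrix:
    """calls: rows (subject, clone index), columns CpG positions; values
    1.0 / 0.0 / NaN.  ``conversion`` holds per-clone conversion efficiency
    (NaN when the reference has no non-CpG cytosine)."""

    calls: pd.DataFrame
    conversion: pd.Series
    groups: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def n_clones(self) -> int:
        return len(self.calls)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.calls.index.get_level_values(0)))


def call_clone(reference: str, cpg_positions: tuple[int, ...],
               clone: str) -> tuple[np.ndarray, float]:
    """Call one clone: per-CpG-site methylation plus conversion efficiency.

    At each CpG position, C -> methylated, T -> unmethylated, anything else
    -> ambiguous (NaN).  Conversion efficiency is the fraction of non-CpG
    reference cytosines read as T.
    """
    if len(clone) != len(reference):
        raise ValueError(f"clone length {len(clone)} != reference length {len(reference)}")
    ref = reference.upper()
    cl = clone.upper()
    cpg_set = set(cpg_positions)
    calls = np.full(len(cpg_positions), np.nan)
    for k, pos in enumerate(cpg_positions):
        base = cl[pos]
        if base == "C":
            calls[k] = METHYLATED
        elif base == "T":
            calls[k] = UNMETHYLATED
    non_cpg_c = [i for i, b in enumerate(ref) if b == "C" and i not in cpg_set]
    if non_cpg_c:
        converted = sum(1 for i in non_cpg_c if cl[i] == "T")
        efficiency = converted / len(non_cpg_c)
    else:
        efficiency = float("nan")
    return calls, efficiency


def call_clones(cs: CloneSet) -> MethylationCallMatrix:
    rows, effs, index = [], [], []
    for subject in sorted(cs.clones):
        for j, clone in enumerate(cs.clones[subject]):
            calls, eff = call_clone(cs.reference, cs.cpg_positions, clone)
            rows.append(calls)
            effs.append(eff)
            index.append((subject, j))
    idx = pd.MultiIndex.from_tuples(index, names=["subject", "clone"])
    calls = pd.DataFrame(rows, index=idx, columns=list(cs.cpg_positions))
    conversion = pd.Series(effs, index=idx, name="conversion_efficiency")
    return MethylationCallMatrix(calls=calls, conversion=conversion, groups=dict(cs.groups))


def methylation_ratio(matrix: MethylationCallMatrix, level: str = "region"):
    """Methylated / (methylated + unmethylated) at the requested stratum.

    level="site": per-CpG-position ratio pooled over all clones (Series);
    level="region": one pooled ratio over all clones and sites (float);
    level="subject": per-subject pooled ratio (Series).  Strata with no
    unambiguous call are reported as NaN (missing), never as zero.
    """
    calls = matrix.calls
    if level == "site":
        return calls.mean(axis=0, skipna=True)
    if level == "region":
        vals = calls.to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")
    if level == "subject":
        return calls.groupby(level="subject", sort=True).apply(
            lambda df: float(np.nanmean(df.to_numpy()))
            if np.isfinite(df.to_numpy()).any() else float("nan"))
    raise ValueError(f"unknown level {level!r}")


def qc_filter(matrix: MethylationCallMatrix,
              min_conversion: float = 0.95) -> MethylationCallMatrix:
    """Drop clones with conversion efficiency below the threshold.

    Clones with undefined efficiency (no non-CpG cytosine in the
    reference) are kept: there is no evidence against them.  Subjects left
    with no clone are dropped from the matrix with a warning.  Idempotent.
    """
    eff = matrix.conversion
    keep = eff.isna() | (eff >= min_conversion)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("conversion QC removed %d of %d clones", n_removed, len(keep))
    calls = matrix.calls[keep.to_numpy()]
    conversion = matrix.conversion[keep.to_numpy()]
    before = set(matrix.calls.index.get_level_values(0))
    after = set(calls.index.get_level_values(0))
    lost = sorted(before - after)
    if lost:
        warnings.warn(f"all clones removed for subject(s) {lost}; "
                      "dropped from group statistics", stacklevel=2)
    groups = {s: g for s, g in matrix.groups.items() if s in after}
    return MethylationCallMatrix(calls=calls, conversion=conversion, groups=groups)


def lollipop_report(matrix: MethylationCallMatrix,
                    filled: str = "●", open_: str = "○", ambiguous: str = "?") -> str:
    """Text lollipop grid: one row per clone, one column per CpG site,
    rows ordered by (subject, clone id)."""
    lines = [" " * 14 + " ".join(f"{p}" for p in matrix.calls.columns)]
    for (subject, clone), row in matrix.calls.sort_index().iterrows():
        symbols = []
        for v in row:
            if np.isnan(v):
                symbols.append(ambiguous)
            elif v == METHYLATED:
                symbols.append(filled)
            else:
                symbols.append(open_)
        lines.append(f"{subject:>8} #{clone:<3} " + " ".join(symbols))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# FASTA I/O: reference in one file; clones named "<subject>.<n>" or mapped
# through a sidecar CSV with columns clone_id, subject[, maternal, offspring].


def write_cloneset(cs: CloneSet, reference_path: str | Path, clones_path: str | Path,
                   sidecar_path: str | Path | None = None) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(cs.reference), id="reference", description="")],
                str(reference_path), "fasta")
    records, rows = [], []
    for subject in sorted(cs.clones):
        for j, clone in enumerate(cs.clones[subject]):
            cid = f"{subject}.{j}"
            records.append(SeqRecord(Seq(clone), id=cid, description=""))
            row = {"clone_id": cid, "subject": subject}
            if subject in cs.groups:
                row["maternal"], row["offspring"] = cs.groups[subject]
            rows.append(row)
    seqio_write(records, str(clones_path), "fasta")
    if sidecar_path is not None:
        pd.DataFrame(rows).to_csv(sidecar_path, index=False)


def read_cloneset(reference_path: str | Path, clones_path: str | Path,
                  sidecar_path: str | Path | None = None,
                  primer_regions: tuple[tuple[int, int], ...] = ()) -> CloneSet:
    from Bio import SeqIO

    refs = list(SeqIO.parse(str(reference_path), "fasta"))
    if len(refs) != 1:
        raise ValueError(f"expected exactly one reference record, found {len(refs)}")
    reference = str(refs[0].seq)
    subject_of: dict[str, str] = {}
    groups: dict[str, tuple[str, str]] = {}
    if sidecar_path is not None:
        side = pd.read_csv(sidecar_path, dtype=str)
        subject_of = dict(zip(side["clone_id"], side["subject"]))
        if {"maternal", "offspring"} <= set(side.columns):
            for _, row in side.iterrows():
                groups[row["subject"]] = (row["maternal"], row["offspring"])
    clones: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(clones_path), "fasta"):
        subject = subject_of.get(rec.id, rec.id.rsplit(".", 1)[0])
        clones.setdefault(subject, []).append(str(rec.seq))
    return CloneSet(reference=reference, clones=clones, groups=groups,
                    primer_regions=primer_regions)
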