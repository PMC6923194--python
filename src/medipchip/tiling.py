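"""Data model and I/O for promoter tiling-array designs and two-channel intensities.

The array interrogates promoter windows around transcription start sites
(TSSs) with short oligonucleotide probes.  Each sample contributes two
linear-scale channels — a MeDIP (methylated-DNA immunoprecipitation)
channel and a total-input channel — and the working quantity downstream is
the per-probe, per-sample log2(MeDIP/Input) enrichment.

Coordinates are 0-based half-open throughout; BED is the on-disk
interchange format for intervals, TSV for tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

DESIGN_COLUMNS = ["probe_id", "chrom", "start", "end", "promoter_id"]
INTENSITY_COLUMNS = ["probe_id", "sample_id", "channel", "value"]
CHANNELS = ("MeDIP", "Input")


@dataclass(frozen=True)
class Promoter:
    """A strand-aware promoter window around a TSS."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"degenerate window for {self.gene_id}: [{self.start}, {self.end})")

    @classmethod
    def from_tss(cls, gene_id: str, chrom: str, tss: int, strand: str,
                 upstream_bp: int = 1300, downstream_bp: int = 500) -> "Promoter":
        """Build the window from the TSS: upstream_bp before to downstream_bp
        after the TSS in the direction of transcription."""
        if strand == "+":
            start, end = tss - upstream_bp, tss + downstream_bp
        elif strand == "-":
            start, end = tss - downstream_bp, tss + upstream_bp
        else:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return cls(gene_id, chrom, tss, strand, start, end)


@dataclass
class PromoterSet:
    """An ordered collection of promoters plus (optionally) their sequences."""

    promoters: list[Promoter]
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.gene_id for p in self.promoters]
        if len(set(ids)) != len(ids):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicated gene_id(s): {dup}")
        for gid, seq in self.sequences.items():
            if gid not in set(ids):
                raise ValueError(f"sequence for unknown promoter {gid!r}")

    def __len__(self) -> int:
        return len(self.promoters)

    def __iter__(self):
        return iter(self.promoters)

    def by_id(self, gene_id: str) -> Promoter:
        for p in self.promoters:
            if p.gene_id == gene_id:
                return p
        raise KeyError(gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.gene_id, p.chrom, p.tss, p.strand, p.start, p.end) for p in self.promoters],
            columns=["gene_id", "chrom", "tss", "strand", "start", "end"],
        )

    def write_fasta(self, path: str | Path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(self.sequences[p.gene_id]), id=p.gene_id, description="")
                   for p in self.promoters if p.gene_id in self.sequences]
        seqio_write(records, str(path), "fasta")


class ProbeDesign:
    """Probes tiling promoter windows, sorted by (chrom, start).

    Backed by a DataFrame with columns probe_id, chrom, start, end,
    promoter_id.  Each probe belongs to exactly one promoter.
    """

    def __init__(self, probes: pd.DataFrame):
        df = probes.loc[:, DESIGN_COLUMNS].copy()
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicated probe_id: {dup!r}")
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "probe_id"].iloc[0]
            raise ValueError(f"degenerate probe interval: {bad!r}")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.probes = df

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.probes["probe_id"])

    def midpoints(self) -> np.ndarray:
        return (self.probes["start"].to_numpy() + self.probes["end"].to_numpy()) / 2.0

    def probes_of_promoter(self, promoter_id: str) -> pd.DataFrame:
        return self.probes[self.probes["promoter_id"] == promoter_id]

    def promoter_of_probe(self) -> pd.Series:
        return self.probes.set_index("probe_id")["promoter_id"]


@dataclass
class IntensityMatrix:
    """Two-channel linear-scale intensities: probe x sample for MeDIP and Input.

    ``samples`` is indexed by sample_id with columns group and replicate.
    All intensities are strictly positive (enforced), which guarantees the
    log-ratio is finite everywhere.
    """

    medip: pd.DataFrame
    input_: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.medip.index.equals(self.input_.index):
            raise ValueError("MeDIP and Input probe indices differ")
        if not self.medip.columns.equals(self.input_.columns):
            raise ValueError("MeDIP and Input sample columns differ")
        missing = [s for s in self.medip.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples table lacks metadata for: {missing}")
        for name, df in (("MeDIP", self.medip), ("Input", self.input_)):
            vals = df.to_numpy()
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                raise ValueError(f"{name} channel contains non-positive or non-finite values")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.samples["group"]))

    def samples_of_group(self, group: str) -> list[str]:
        ids = [s for s in self.medip.columns if self.samples.loc[s, "group"] == group]
        if not ids:
            raise ValueError(f"no samples in group {group!r}")
        return ids

    def ratio(self) -> pd.DataFrame:
        """Linear-scale MeDIP/Input ratio, probe x sample."""
        return self.medip / self.input_


@dataclass
class EnrichmentMatrix:
    """Per-probe, per-sample log2(MeDIP/Input) in log2 units."""

    values: pd.DataFrame
    samples: pd.DataFrame

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.samples["group"]))

    def samples_of_group(self, group: str) -> list[str]:
        ids = [s for s in self.values.columns if self.samples.loc[s, "group"] == group]
        if not ids:
            raise ValueError(f"no samples in group {group!r}")
        return ids

    def group_mean(self, group: str) -> pd.Series:
        """The group-mean enrichment track used by the peak caller."""
        return self.values[self.samples_of_group(group)].mean(axis=1)


def log_ratio(m: IntensityMatrix, median_center: bool = False) -> EnrichmentMatrix:
    """Elementwise r = log2(MeDIP) - log2(Input).

    ``median_center`` optionally subtracts each sample's median r
    (a light between-array normalization; off by default).
    """
    r = np.log2(m.medip) - np.log2(m.input_)
    if median_center:
        r = r - r.median(axis=0)
    return EnrichmentMatrix(values=r, samples=m.samples.copy())


# ---------------------------------------------------------------------------
# I/O


def write_design(design: ProbeDesign, path: str | Path) -> None:
    design.probes.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> ProbeDesign:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "promoter_id": str})
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design table missing column(s): {missing}")
    return ProbeDesign(df)


def write_design_bed(design: ProbeDesign, path: str | Path) -> None:
    """BED6 view of the design (name = probe_id, score 0, strand '.')."""
    bed = design.probes[["chrom", "start", "end", "probe_id"]].copy()
    bed["score"] = 0
    bed["strand"] = "."
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    mapping = {sid: {"group": str(row["group"]), "replicate": int(row["replicate"])}
               for sid, row in samples.iterrows()}
    Path(path).write_text(yaml.safe_dump(mapping, sort_keys=True))


def read_samples(path: str | Path) -> pd.DataFrame:
    mapping = yaml.safe_load(Path(path).read_text())
    df = pd.DataFrame.from_dict(mapping, orient="index")
    df.index.name = "sample_id"
    return df.sort_index()


def write_intensities(m: IntensityMatrix, path: str | Path) -> None:
    """Long-format TSV: probe_id, sample_id, channel, value."""
    frames = []
    for channel, df in (("MeDIP", m.medip), ("Input", m.input_)):
        long = df.stack().rename("value").reset_index()
        long.columns = ["probe_id", "sample_id", "value"]
        long["channel"] = channel
        frames.append(long[INTENSITY_COLUMNS])
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_intensities(path: str | Path, design: ProbeDesign,
                     samples: pd.DataFrame | str | Path) -> IntensityMatrix:
    """Read a long-format intensity TSV against a known design.

    Rejects unknown probe ids, duplicated (probe, sample, channel) rows and
    samples missing either channel.  ``samples`` may be a metadata frame or
    a path to the YAML sample map.
    """
    if not isinstance(samples, pd.DataFrame):
        samples = read_samples(samples)
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "sample_id": str, "channel": str})
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table missing column(s): {missing}")
    known = set(design.probe_ids)
    unknown = sorted(set(df["probe_id"]) - known)
    if unknown:
        raise ValueError(f"intensity rows reference unknown probe id(s): {unknown[:5]}")
    if df.duplicated(["probe_id", "sample_id", "channel"]).any():
        row = df[df.duplicated(["probe_id", "sample_id", "channel"])].iloc[0]
        raise ValueError(
            f"duplicated intensity row: probe {row['probe_id']!r} sample {row['sample_id']!r} "
            f"channel {row['channel']!r}")
    channels = {}
    for channel in CHANNELS:
        sub = df[df["channel"] == channel]
        wide = sub.pivot(index="probe_id", columns="sample_id", values="value")
        channels[channel] = wide
    all_samples = sorted(set(df["sample_id"]))
    for channel, wide in channels.items():
        lacking = [s for s in all_samples if s not in wide.columns]
        if lacking:
            raise ValueError(f"sample(s) missing {channel} channel: {lacking}")
    order = [p for p in design.probe_ids if p in channels["MeDIP"].index]
    if len(order) != len(channels["MeDIP"]):
        raise ValueError("internal: probe bookkeeping mismatch")
    medip = channels["MeDIP"].loc[order, all_samples]
    input_ = channels["Input"].loc[order, all_samples]
    if medip.isna().any().any() or input_.isna().any().any():
        incomplete = sorted(set(medip.columns[medip.isna().any()])
                            | set(input_.columns[input_.isna().any()]))
        raise ValueError(f"incomplete channel data for sample(s): {incomplete}")
    return IntensityMatrix(medip=medip, input_=input_, samples=samples)
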