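"""Synthetic data generator for the two-group, three-replicate MeDIP
promoter-array design, plus ground-truth records for recovery testing.

What it emulates
----------------
* Promoters spanning ~-1,300 to +500 bp around TSSs on two synthetic
  chromosomes, tiled left-to-right with fixed-length probes.
* Promoter sequences constructed to a requested CpG class (HCP/ICP/LCP):
  the sequence background is CpG-free and a deterministic CpG-dense block
  is inserted for HCP/ICP promoters, so the emitted class is guaranteed by
  construction and verified against the classifier.
* A two-group (HF-CON vs CON-CON) x N-replicate experiment with planted
  hyper-/hypomethylated regions.  The per-probe baseline log2 enrichment is
  N(mu_base, noise_sd^2) shared by both groups; a planted region raises the
  methylated group's track by the effect size (the HF-CON group for
  "hyper", the CON-CON group for "hypo", so M' = +effect or -effect
  respectively and the region is detectable as a peak in the enriched
  group).  Replicate noise is lognormal, scaled so the across-replicate CV
  of the linear MeDIP/Input ratio equals ``replicate_cv`` in expectation.
* Bisulfite clone sets with per-site methylation probabilities and an
  independent Bernoulli conversion-failure model per non-CpG cytosine.
* Balanced 2x2 factorial phenotype tables with OGTT series at
  0/30/60/120 min.

Every generator is bit-for-bit deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cpg
from .bsp import CloneSet, find_cpg_positions
from .tiling import IntensityMatrix, ProbeDesign, Promoter, PromoterSet

GROUPS = ("HF-CON", "CON-CON")
DIRECTIONS = ("hyper", "hypo")
PHENO_GROUPS = ("CON-CON", "CON-HF", "HF-CON", "HF-HF")
OGTT_TIMES = (0, 30, 60, 120)

# Deterministic CpG-block motifs.  Backgrounds are CpG-free, so a window
# covering a block alone decides the class:
#   HCP block: obs/exp 0.889, GC 0.60 in a 500-bp window (10 x 50-bp motif)
#   ICP block: obs/exp 0.620, GC 0.44 in a 500-bp window (5 x 100-bp motif)
_HCP_MOTIF = "CGCGCGCG" + "G" * 11 + "C" * 11 + "ATTATTATTATTATTATTAT"
_ICP_MOTIF = "CGCGCG" + "G" * 19 + "C" * 19 + ("ATTATTAT" * 7)
assert len(_HCP_MOTIF) == 50 and len(_ICP_MOTIF) == 100
_BLOCK_BP = 500
_BLOCK_OFFSET = 600  # multiple of the classifier step so one scan window covers the block


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic array experiment.

    Defaults are the desk-scale version of the study conditions: 500
    promoters (~4,000 probes) instead of the full 22,327/~180,000, three
    replicates per group, and a -1,300/+500 bp promoter window.
    """

    n_promoters: int = 500
    probe_length: int = 50
    probe_spacing: int = 250
    upstream_bp: int = 1300
    downstream_bp: int = 500
    n_replicates_per_group: int = 3
    planted_dmrs: tuple = ()          # (promoter index, "hyper"|"hypo", effect in log2 units)
    noise_sd: float = 0.3             # probe-to-probe baseline spread, log2 units
    replicate_cv: float = 0.3         # target CV of the linear MeDIP/Input ratio
    mu_base: float = 0.5              # baseline log2 enrichment
    class_fractions: tuple = (0.60, 0.25, 0.15)   # HCP, ICP, LCP
    n_chromosomes: int = 2
    groups: tuple = GROUPS
    input_brightness: float = 1000.0
    input_log2_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_length <= 0:
            raise ValueError("probe_length must be > 0")
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")
        if self.n_promoters < 1:
            raise ValueError("n_promoters must be >= 1")
        if self.noise_sd < 0 or self.replicate_cv < 0:
            raise ValueError("noise_sd and replicate_cv must be >= 0")
        if self.n_replicates_per_group < 1:
            raise ValueError("need at least one replicate per group")
        if len(self.groups) != 2:
            raise ValueError("exactly two groups are supported")
        if not math.isclose(sum(self.class_fractions), 1.0, abs_tol=1e-9):
            raise ValueError("class_fractions must sum to 1")
        for idx, direction, effect in self.planted_dmrs:
            if direction not in DIRECTIONS:
                raise ValueError(f"unknown DMR direction {direction!r}")
            if not (0 <= idx < self.n_promoters):
                raise ValueError(f"planted promoter index {idx} out of range")
            if not math.isfinite(effect):
                raise ValueError("effect sizes must be finite")

    @property
    def window_bp(self) -> int:
        return self.upstream_bp + self.downstream_bp


@dataclass(frozen=True)
class TruthRegion:
    chrom: str
    start: int
    end: int
    direction: str
    effect: float
    promoter_id: str


@dataclass
class GroundTruth:
    """Planted regions and true per-promoter CpG classes."""

    regions: tuple[TruthRegion, ...]
    promoter_classes: dict[str, str] = field(default_factory=dict)

    def write_bed(self, path: str | Path) -> None:
        rows = [(r.chrom, r.start, r.end, r.promoter_id, r.direction, r.effect)
                for r in self.regions]
        pd.DataFrame(rows, columns=["chrom", "start", "end", "promoter_id",
                                    "direction", "effect"]).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequences


def _cpg_free_background(rng: np.random.Generator, length: int) -> str:
    """Random sequence at ~40% GC with every CpG dinucleotide removed (the G
    of any C-G pair is rewritten to A/T), so background windows have
    obs/exp exactly 0."""
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=[0.3, 0.2, 0.2, 0.3])
    # rewriting the G of each C-G pair cannot create a new CpG, so one
    # simultaneous pass is enough
    mask = (seq[:-1] == "C") & (seq[1:] == "G")
    replacements = np.array(list("AT"))[rng.integers(2, size=int(mask.sum()))]
    seq[1:][mask] = replacements
    return "".join(seq)


def _class_sequence(rng: np.random.Generator, requested: str, length: int) -> str:
    bg = _cpg_free_background(rng, length)
    if requested == "LCP":
        return bg
    if requested == "HCP":
        block = _HCP_MOTIF * (_BLOCK_BP // len(_HCP_MOTIF))
    elif requested == "ICP":
        block = _ICP_MOTIF * (_BLOCK_BP // len(_ICP_MOTIF))
    else:
        raise ValueError(f"unreachable promoter class requested: {requested!r} "
                         f"(must be one of HCP, ICP, LCP)")
    if length < _BLOCK_OFFSET + _BLOCK_BP:
        raise ValueError(f"promoter window of {length} bp too short to host a "
                         f"{requested} block")
    return bg[:_BLOCK_OFFSET] + block + bg[_BLOCK_OFFSET + _BLOCK_BP:]


def gen_promoter_set(cfg: SimConfig, classes: list[str] | None = None) -> PromoterSet:
    """Promoters on ``cfg.n_chromosomes`` synthetic chromosomes, alternating
    strand, each with a sequence built to its requested CpG class.

    ``classes`` overrides the per-promoter class assignment; by default
    classes are drawn to match ``cfg.class_fractions``.  Every emitted
    sequence is re-classified and must round-trip exactly.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    n = cfg.n_promoters
    if classes is None:
        counts = [int(round(f * n)) for f in cfg.class_fractions]
        while sum(counts) > n:
            counts[counts.index(max(counts))] -= 1
        while sum(counts) < n:
            counts[counts.index(min(counts))] += 1
        pool = (["HCP"] * counts[0] + ["ICP"] * counts[1] + ["LCP"] * counts[2])
        classes = [pool[i] for i in rng.permutation(n)]
    elif len(classes) != n:
        raise ValueError("classes must have one entry per promoter")

    window = cfg.window_bp
    pitch = window + 3200  # leaves > merge-gap spacing between adjacent promoters
    promoters, sequences = [], {}
    for i in range(n):
        chrom = f"chr{i % cfg.n_chromosomes + 1}"
        slot = i // cfg.n_chromosomes
        start = 2000 + slot * pitch
        strand = "+" if i % 2 == 0 else "-"
        tss = start + (cfg.upstream_bp if strand == "+" else cfg.downstream_bp)
        gid = f"g{i:05d}"
        prom = Promoter(gene_id=gid, chrom=chrom, tss=tss, strand=strand,
                        start=start, end=start + window)
        seq = _class_sequence(rng, classes[i], window)
        got = cpg.classify_promoter(seq)
        if got != classes[i]:
            raise RuntimeError(f"generator/classifier mismatch for {gid}: "
                               f"requested {classes[i]}, classified {got}")
        promoters.append(prom)
        sequences[gid] = seq
    return PromoterSet(promoters=promoters, sequences=sequences)


def gen_array_design(promoters: PromoterSet, cfg: SimConfig) -> ProbeDesign:
    """Tile every promoter window left-to-right at ``probe_spacing``.

    The number of probes per window is floor((W - probe_length)/spacing)+1;
    a spacing wider than the window leaves a single probe (with a warning).
    """
    rows = []
    warned = False
    for prom in promoters:
        window = prom.end - prom.start
        if window < cfg.probe_length:
            raise ValueError(f"promoter {prom.gene_id} narrower than a probe")
        n_probes = (window - cfg.probe_length) // cfg.probe_spacing + 1
        if cfg.probe_spacing > window and not warned:
            warnings.warn("probe spacing exceeds the promoter window; "
                          "one probe per promoter", stacklevel=2)
            warned = True
        for k in range(n_probes):
            start = prom.start + k * cfg.probe_spacing
            rows.append((prom.chrom, start, start + cfg.probe_length, prom.gene_id))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "promoter_id"])
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "probe_id", [f"p{i:06d}" for i in range(len(df))])
    return ProbeDesign(df)


def plant_random_dmrs(cfg: SimConfig, n_dmrs: int, effect: float,
                      seed: int | None = None) -> SimConfig:
    """Return a config with ``n_dmrs`` planted regions on distinct random
    promoters, alternating hyper/hypo, all at the same |effect|."""
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 17])
    idx = rng.choice(cfg.n_promoters, size=n_dmrs, replace=False)
    dmrs = tuple((int(i), DIRECTIONS[k % 2], float(effect)) for k, i in enumerate(idx))
    return dataclasses.replace(cfg, planted_dmrs=dmrs)


def gen_medip_experiment(design: ProbeDesign, cfg: SimConfig,
                         promoters: PromoterSet | None = None,
                         promoter_classes: dict[str, str] | None = None
                         ) -> tuple[IntensityMatrix, GroundTruth]:
    """Simulate the two-channel experiment and return intensities + truth.

    Signal model (log2 scale): r[probe, sample] = baseline(probe) +
    effect(probe, group) + replicate noise, with baseline ~
    N(mu_base, noise_sd^2) shared across groups and replicate noise scaled
    so the linear-ratio CV equals ``replicate_cv`` in expectation.  The
    Input channel is lognormal around ``input_brightness`` and MeDIP =
    Input * 2^r, so both channels are strictly positive by construction.
    """
    rng = np.random.default_rng([cfg.seed, 23])
    probes = design.probes
    n_probes = len(probes)
    prom_ids = probes["promoter_id"].to_numpy()

    offsets = {g: np.zeros(n_probes) for g in cfg.groups}
    regions = []
    for idx, direction, effect in cfg.planted_dmrs:
        gid = f"g{idx:05d}"
        mask = prom_ids == gid
        member = np.flatnonzero(mask)
        if member.size < 2:
            raise ValueError(f"planted region on {gid} is covered by "
                             f"{member.size} probe(s); at least 2 are required")
        if member.size >= 4:
            member = member[1:-1]  # interior probes: region strictly inside the promoter
        enriched_group = cfg.groups[0] if direction == "hyper" else cfg.groups[1]
        offsets[enriched_group][member] += effect
        regions.append(TruthRegion(
            chrom=str(probes["chrom"].iloc[member[0]]),
            start=int(probes["start"].iloc[member].min()),
            end=int(probes["end"].iloc[member].max()),
            direction=direction, effect=float(effect), promoter_id=gid))

    baseline = rng.normal(cfg.mu_base, cfg.noise_sd, n_probes)
    sigma_rep = (math.sqrt(math.log1p(cfg.replicate_cv ** 2)) / math.log(2)
                 if cfg.replicate_cv > 0 else 0.0)

    sample_ids, groups_col, reps_col = [], [], []
    medip_cols, input_cols = {}, {}
    for g in cfg.groups:
        for rep in range(1, cfg.n_replicates_per_group + 1):
            sid = f"{g}_r{rep}"
            r = baseline + offsets[g]
            if sigma_rep > 0:
                r = r + rng.normal(0.0, sigma_rep, n_probes)
            inp = cfg.input_brightness * np.exp2(rng.normal(0.0, cfg.input_log2_sd, n_probes))
            med = inp * np.exp2(r)
            sample_ids.append(sid)
            groups_col.append(g)
            reps_col.append(rep)
            medip_cols[sid] = med
            input_cols[sid] = inp

    index = pd.Index(probes["probe_id"], name="probe_id")
    medip = pd.DataFrame(medip_cols, index=index)
    input_ = pd.DataFrame(input_cols, index=index)
    samples = pd.DataFrame({"group": groups_col, "replicate": reps_col},
                           index=pd.Index(sample_ids, name="sample_id"))
    if promoter_classes is None and promoters is not None:
        promoter_classes = {p.gene_id: cpg.classify_promoter(promoters.sequences[p.gene_id])
                            for p in promoters if p.gene_id in promoters.sequences}
    truth = GroundTruth(regions=tuple(regions),
                        promoter_classes=promoter_classes or {})
    return IntensityMatrix(medip=medip, input_=input_, samples=samples), truth


# ---------------------------------------------------------------------------
# bisulfite clones


def synthetic_amplicon(length: int, n_cpgs: int, seed: int = 0) -> tuple[str, tuple[int, ...]]:
    """A synthetic bisulfite amplicon: CpG-free background with ``n_cpgs``
    CG dinucleotides placed at evenly spaced positions (e.g. 301 bp with 30
    CpGs mimics a typical Irs2-style amplicon geometry)."""
    if length < 4 * n_cpgs:
        raise ValueError("amplicon too short for the requested CpG count")
    rng = np.random.default_rng([seed, 31])
    seq = list(_cpg_free_background(rng, length))
    positions = []
    for k in range(n_cpgs):
        pos = int(round((k + 0.5) * length / n_cpgs)) - 1
        pos = min(max(pos, 0), length - 2)
        seq[pos], seq[pos + 1] = "C", "G"
        positions.append(pos)
    out = "".join(seq)
    assert find_cpg_positions(out) == tuple(positions)
    return out, tuple(positions)


def gen_bsp_clones(reference: str, meth_profile, n_subjects: int = 4,
                   clones_per_subject: int = 10, conversion_rate: float = 0.99,
                   seed: int = 0,
                   groups: dict[str, tuple[str, str]] | None = None) -> CloneSet:
    """Simulate bisulfite-converted clones of a reference amplicon.

    ``meth_profile`` gives the per-CpG-site methylation probability: a
    scalar, an array of length n_cpgs, or a dict subject -> array.  Each
    CpG cytosine stays C with its site probability; each non-CpG cytosine
    converts to T with probability ``conversion_rate``.
    """
    cpg_positions = find_cpg_positions(reference)
    if not cpg_positions:
        raise ValueError("reference amplicon contains no CpG site")
    if not (0.0 < conversion_rate <= 1.0):
        raise ValueError("conversion_rate must be in (0, 1]")
    if clones_per_subject < 1 or n_subjects < 1:
        raise ValueError("need at least one subject and one clone")
    n_sites = len(cpg_positions)

    def profile_for(subject: str) -> np.ndarray:
        if isinstance(meth_profile, dict):
            p = np.asarray(meth_profile[subject], dtype=float)
        else:
            p = np.asarray(meth_profile, dtype=float)
        if p.ndim == 0:
            p = np.full(n_sites, float(p))
        if p.shape != (n_sites,):
            raise ValueError(f"profile length {p.shape} != number of CpG sites {n_sites}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("site probabilities must lie in [0, 1]")
        return p

    rng = np.random.default_rng([seed, 37])
    ref = reference.upper()
    cpg_set = set(cpg_positions)
    non_cpg_c = [i for i, b in enumerate(ref) if b == "C" and i not in cpg_set]
    clones: dict[str, list[str]] = {}
    for s in range(n_subjects):
        subject = f"m{s + 1:02d}"
        p = profile_for(subject)
        subject_clones = []
        for _ in range(clones_per_subject):
            clone = list(ref)
            methylated = rng.random(n_sites) < p
            for k, pos in enumerate(cpg_positions):
                if not methylated[k]:
                    clone[pos] = "T"
            if non_cpg_c:
                converted = rng.random(len(non_cpg_c)) < conversion_rate
                for i, pos in enumerate(non_cpg_c):
                    if converted[i]:
                        clone[pos] = "T"
            subject_clones.append("".join(clone))
        clones[subject] = subject_clones
    return CloneSet(reference=reference, clones=clones, groups=groups or {})


# ---------------------------------------------------------------------------
# phenotypes


def default_phenotype_means() -> dict[str, dict[str, float]]:
    """Plausible 8-week male C57BL/6 values reproducing the study's
    qualitative pattern: postweaning HF raises weight, both diets raise
    fasting glucose and OGTT excursions, the diets interact on insulin."""
    return {
        "body_weight": {"CON-CON": 22.0, "CON-HF": 26.0, "HF-CON": 22.5, "HF-HF": 27.0},
        "fasting_glucose": {"CON-CON": 5.0, "CON-HF": 6.5, "HF-CON": 6.0, "HF-HF": 7.0},
        "fasting_insulin": {"CON-CON": 10.0, "CON-HF": 14.0, "HF-CON": 12.0, "HF-HF": 22.0},
        "ogtt_glucose_0": {"CON-CON": 5.0, "CON-HF": 6.5, "HF-CON": 6.0, "HF-HF": 7.0},
        "ogtt_glucose_30": {"CON-CON": 13.0, "CON-HF": 16.0, "HF-CON": 15.5, "HF-HF": 18.0},
        "ogtt_glucose_60": {"CON-CON": 10.0, "CON-HF": 13.0, "HF-CON": 12.5, "HF-HF": 15.0},
        "ogtt_glucose_120": {"CON-CON": 7.0, "CON-HF": 9.5, "HF-CON": 9.0, "HF-HF": 11.0},
    }


def default_phenotype_sds() -> dict[str, float]:
    return {"body_weight": 1.5, "fasting_glucose": 0.6, "fasting_insulin": 3.0,
            "ogtt_glucose_0": 0.6, "ogtt_glucose_30": 1.5,
            "ogtt_glucose_60": 1.2, "ogtt_glucose_120": 1.0}


def gen_phenotypes(group_means: dict[str, dict[str, float]], sd,
                   n_per_group: int = 10, seed: int = 0) -> pd.DataFrame:
    """Balanced 2x2 factorial phenotype table, ``n_per_group`` animals per
    cell.  ``group_means`` maps trait -> {group label: mean}; ``sd`` is a
    scalar or a trait -> sd dict.  Positive-valued traits (glucose,
    insulin, OGTT) are redrawn if a draw comes out non-positive."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (ANOVA undefined otherwise)")
    for trait, cells in group_means.items():
        missing = [g for g in PHENO_GROUPS if g not in cells]
        if missing:
            raise ValueError(f"trait {trait!r} missing cell mean(s) for {missing}")
    rng = np.random.default_rng([seed, 41])
    rows = []
    for g in PHENO_GROUPS:
        maternal, offspring = g.split("-")
        for k in range(n_per_group):
            row = {"animal_id": f"{g}_{k + 1:02d}",
                   "maternal_diet": maternal, "offspring_diet": offspring}
            for trait, cells in group_means.items():
                s = sd[trait] if isinstance(sd, dict) else float(sd)
                val = rng.normal(cells[g], s)
                if trait.startswith(("fasting", "ogtt")):
                    tries = 0
                    while val <= 0 and tries < 100:
                        val = rng.normal(cells[g], s)
                        tries += 1
                    if val <= 0:
                        raise ValueError(f"could not draw a positive value for {trait!r}")
                row[trait] = val
            rows.append(row)
    return pd.DataFrame(rows)
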