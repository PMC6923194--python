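# Methods

`medipchip` reimplements, as a tested library, the analysis chain of a
MeDIP promoter tiling-array study of differential DNA methylation between
two groups of mouse livers (treatment "HF-CON" vs control "CON-CON", three
array replicates each), together with the validation-arm computations
(bisulfite clone ratios, comparative-Ct expression, HOMA-IR, OGTT AUC,
two-way diet ANOVA) and a synthetic-data generator that emulates the
design end to end.

## Array model and enrichment

Each promoter is a strand-aware window from 1,300 bp upstream to 500 bp
downstream of its TSS, tiled left-to-right by fixed-length probes.  Every
sample contributes a MeDIP and an Input channel on a linear scale, both
strictly positive (enforced at read time), and the working quantity is the
per-probe, per-sample enrichment r = log2(MeDIP/Input).  No between-array
normalization is applied by default; a per-sample median-centering of r is
available behind a flag (`log_ratio(..., median_center=True)`) because the
original normalization of such arrays is generally vendor-internal and
unstated.  Coordinates are 0-based half-open internally; BED/TSV on disk.

## Peak calling

Peak finding follows the NimbleScan-style sliding-window recipe: a 750-bp
window centred on each probe's midpoint, a per-window score of
-log10 p with a cutoff of 2, runs of at least two consecutive qualifying
probes, and merging of peaks within 500 bp of each other.  The vendor's
per-window test statistic is not published, so the scorer is a documented
choice here: a one-sided two-sample Kolmogorov–Smirnov comparison of the
window's values on the *group-mean* enrichment track against the
array-wide distribution (alternative: window stochastically greater), with

    D = sup_t [F_array(t) - F_window(t)],   p = exp(-2 m n D^2 / (m + n)).

This is the classic one-sided Smirnov tail bound; it is monotone in D and
cheap to evaluate exactly.  The statistic D is computed by an order-
statistics shortcut that is verified in the tests against an independent
brute-force evaluation and against `scipy.stats.ks_2samp` (alternative
`"less"`).  The scorer is isolated behind `window_score` so an alternative
(e.g. a one-sided Wilcoxon) could be swapped without touching run
detection or merging.  Windows with fewer than two probes score 0; runs
never cross chromosome boundaries; score ties at exactly the cutoff are
included.  Merging uses genomic distance between peak boundaries, is
order-independent and idempotent, and is run to a fixed point.

Scoring group means rather than individual samples is a documented default
(whether the original pipeline intersected per-sample calls is unstated).
Candidate regions for the differential step are the union of peaks called
on either group's track: regions enriched in the treatment track can
become hypermethylated DEPs, regions enriched in the control track
hypomethylated ones.

## M' and DEP filtering

For a candidate region, M' is the unweighted arithmetic mean of r over
(member probes x treatment samples) minus the same mean for the control
group.  A region passes if

1. at least one group has a median member-probe group-mean r >= 0.3 and
   M' is non-zero (M' > 0 => hypermethylated, M' < 0 => hypomethylated;
   the symmetric reading is required for hypomethylated regions to exist
   at all), and
2. in each group separately, at least half of the member probes have a
   replicate CV <= 0.8, where CV = sd/mean (ddof = 1) of the linear
   MeDIP/Input ratio across that group's replicates.

"At least half ... may have" is read as "must have" — the permissive
reading filters nothing.  Medians with even probe counts are midpoints of
the central pair.  Output is sorted by |M'| descending.  A DEP spanning
probes of k promoters carries all k gene ids; its CpG class is that of the
promoter contributing the most member probes (first promoter wins ties).
Tallies by direction, direction x class and chromosome assert their own
conservation identities on every run.

## CpG classes

Promoters are classified by scanning 500-bp windows at a 5-bp step (plus a
final window flush with the sequence end): HCP if any window has CpG
observed/expected > 0.75 and GC > 0.55, LCP if no window reaches 0.48,
ICP otherwise — the Weber-style scheme standard for mouse promoters; all
four thresholds are parameters.  The ratio is (#CG x L)/(#C x #G) over the
window's L counted bases; N bases are excluded from all counts and windows
with more than 10% N are skipped.  CpG is its own reverse complement, so
only one strand is scanned.

## Synthetic data

The generator defines the conditions under which the pipeline is tested.

* **Scale.** Default 500 promoters / ~4,000 probes (50-bp probes every
  250 bp => 8 probes per 1,800-bp window) so a full pipeline run takes a
  fraction of a second; the published full scale (22,327 promoters,
  ~180,000 probes) is reachable through the same config and is checked as
  an arithmetic scale test.
* **Sequences.** Backgrounds are random at ~40% GC with every CpG
  dinucleotide removed, so background windows have obs/exp exactly 0; HCP
  and ICP promoters carry a deterministic 500-bp motif block (obs/exp
  0.889 at GC 0.60, and 0.62 at GC 0.44 respectively) aligned to the
  classifier's step.  This makes the emitted class certain by
  construction; every sequence is still re-classified and the generator
  fails loudly on any mismatch.  Real promoters have graded CpG density
  rather than block structure, so classifier performance on these
  sequences demonstrates correctness of the scan, not discrimination
  power on borderline real promoters.
* **Signal.** Per-probe baseline log2 enrichment is N(mu_base = 0.5,
  noise_sd^2 = 0.3^2), shared by both groups, so unplanted promoters
  straddle the 0.3 median filter realistically.  A planted region adds the
  effect (in log2 units) to the *methylated* group's track — the
  treatment group for "hyper", the control group for "hypo" — giving
  M' = +effect and -effect respectively while keeping the region
  detectable as a peak in the enriched group's track (a region depressed
  below a flat baseline is invisible to an enrichment peak finder).
  Planted regions span the interior probes of their promoter and must be
  covered by at least two probes, else the generator errors.
* **Noise.** Replicate noise is lognormal on the ratio: a log2-normal
  deviate with sigma = sqrt(ln(1 + cv^2))/ln 2, so the across-replicate
  CV of the linear MeDIP/Input ratio equals `replicate_cv` (default 0.3,
  a typical mid-range array replicate CV well inside the 0.8 filter) in
  expectation.  The Input channel is lognormal around a fixed brightness,
  so both channels are positive by construction.  No dye bias, spatial
  artifacts or fragment-level simulation — the model is the simplest one
  that makes M', the median filter and the CV filter all well-defined,
  and it is a stand-in: the original study does not describe its intensity
  distributions.
* **Clones.** Bisulfite clones are the reference with each CpG cytosine
  kept as C with its site probability and each non-CpG cytosine converted
  to T independently with the conversion rate (a standard conversion-QC
  assumption).  Default 10+ clones per subject.
* **Phenotypes.** Balanced 2x2 (maternal x offspring diet) tables at
  n = 10 per cell with OGTT sampling at 0/30/60/120 min.  Cell means are
  package defaults chosen as plausible 8-week male C57BL/6 values
  reproducing the study's qualitative pattern (postweaning fat raises
  weight, both exposures raise glucose, the diets interact on insulin).

All generators are bit-for-bit deterministic under a fixed seed.

## Bisulfite clone analysis

Calls at each CpG site are C => methylated, T => unmethylated, anything
else ambiguous; ambiguous calls are excluded from denominators rather than
counted unmethylated (counting them down-biases the ratio).  Conversion
efficiency is the fraction of non-CpG reference cytosines read as T;
clones below 0.95 are dropped by the QC filter (idempotent; clones with no
non-CpG cytosine to judge are kept).  The mouse is the statistical unit:
clones within a subject are pooled into one ratio before any group test,
matching an n-per-group design; how the original study aggregated clones
is unstated, so pooling is a documented choice.  Primer intervals can be
excluded from CpG scoring since bisulfite primers are degenerate there.

## Metabolic statistics

* HOMA-IR = glucose[mmol/L] x insulin[uIU/mL] / 22.5 (Matthews).
* OGTT AUC is the total trapezoidal area over 0–120 min (in mmol/L*min);
  incremental AUC above baseline is available behind a flag since the
  variant used originally is ambiguous.
* 2^-ddCt uses the control-control group mean dCt as calibrator, making
  the calibrator's geometric-mean fold exactly 1 — an identity the tests
  assert.
* The two-way ANOVA uses the textbook partitioned sums of squares for
  balanced designs (SS_A + SS_B + SS_AB + SS_E == SS_total to 1e-9
  relative, asserted) and statsmodels Type-II sums of squares when
  unbalanced.  A constant response reports F and p as not-applicable
  (NaN) rather than erroring.  Empty cells fail naming the cell.
* `t_from_summary` is a Welch t with Satterthwaite df from means,
  dispersions (SD or SEM) and group sizes.  Note that published
  dam-weight values (23.33 +/- 1.40 vs 19.17 +/- 1.14, n = 20/group,
  labelled SEM) give t ≈ 2.30 — significant at 0.05 but not an extreme t;
  the operation supports both dispersion conventions and takes no side on
  which the original values were.

## Problem sizes used in the checks

Monte-Carlo suites are sized to be decisive yet quick: 50 seeds x 20
planted DMRs for recovery (1,000 regions), 100 seeds for M' bias at low
noise, 1,000 random score vectors against the peak-caller oracle, 200
randomized peaks against the filter predicate, 2,000 null simulations for
ANOVA type-I error (the [0.035, 0.065] acceptance band is about +/- 3
binomial SEs around 0.05), and clone sets large enough that exact binomial
99% intervals are tight.  The acceptance script re-runs the recovery
experiment at 25 seeds and reports pooled recall, precision, direction
accuracy and M' bias.

## Known limitations

* The per-window test statistic, array normalization and clone
  aggregation of the original pipeline are unpublished; the choices here
  are documented defaults, not claims about the vendor implementation,
  and the published genome-wide DMR counts are therefore not a
  reproduction target.
* Synthetic promoter backgrounds are CpG-free and class blocks are
  deterministic; planted effects are additive and noise homoscedastic.
  Passing recovery tests show the pipeline's logic is correct under its
  assumed signal model, not that the model captures real MeDIP biases
  (CpG-density-dependent enrichment, probe affinity, dye effects).
* Gene annotation is against the synthetic promoter set only; no real
  genome coordinates, and no GO/KEGG enrichment (an external-service
  step).
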