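# Methods

## Study design assumed by the package

The analysis targets a two-region (grey matter GM / white matter WM),
four-group human brain cohort: middle-aged lesion-free controls (MA) and
Alzheimer-type cases grouped by Braak stage (I-II, III-IV, V-VI), with
4–7 samples per group per region.  Group sizes this small rule out
normality checks, so the whole statistical layer is rank-based.

## Fatty-acyl panel

Compositions are expressed in mol% over a 26-species GC panel
(14:0 … 24:6n-3).  Raw peak areas are accepted and normalized internally
(mol%_i = 100·area_i/Σareas, assuming areas are mole-proportional);
already-normalized tables must sum to 100 ± 0.5 — the window absorbs the
rounding of published medians.  Species outside the panel are accepted if
their "C:Dn-x" label parses; they enter all sums by their carbon number,
double-bond count and series, with a warning.

Indices are linear functionals of the double-bond class sums (mono … hexa)
and chain-length sums; the two peroxidizability variants PI(a) and PI(b)
differ only in their class coefficients (PI(a): 0.025/1/2/4/6/8,
PI(b): 0.015/1/2/3/4/5), so PI(b) ≤ PI(a) and PI(b) ≤ DBI coefficient-wise
on every profile.  Enzyme activities are product/substrate mol% ratios and
are explicitly *estimates* — no claim about true kinetics is made.  A zero
substrate makes the ratio undefined; undefined values propagate as NaN
rather than exceptions so a single degenerate sample cannot abort a cohort
run, and group summaries report the effective n after exclusion.

**Aggregation order matters.** Indices and ratios are computed per sample
and only then summarized as median [Q1;Q3] (quartiles by linear
interpolation between order statistics, the common "type 7" rule; the
convention is fixed here because published tables rarely state one).  The
median of per-sample ratios generally differs from the ratio of median
compositions — published index medians show exactly this signature (e.g.
a GM Elovl6 median of 0.93 against 25.0/26.0 = 0.96 from the median
composition), which is why the worked-example checks on summed indices
carry a 2 % relative tolerance rather than exact equality.

A known internal inconsistency of the source tables is reproduced, not
repaired: the printed peroxisomal β-oxidation medians (GM 1.48, WM 0.22)
cannot be obtained as 22:6n-3/24:6n-3 of the printed medians
(2.90/0.14 ≈ 20.7).  The package implements the stated formula verbatim;
per-sample aggregation alone cannot explain a 14-fold gap, so the printed
rows were presumably derived from a different quantity.  No acceptance
check relies on this ratio.

## LC-MS feature processing

The pipeline starts at the molecular-feature table (vendor peak picking
is out of scope) and applies stages in a fixed order: minimum-ion filter →
QC-presence filter → drift correction → (optional) internal-standard
normalization → statistics.  Filters are idempotent and boundary-inclusive
("at least 2 ions", "at least 70 % of QCs").

**Drift correction.** Pooled-QC injections every 5th position monitor
instrument drift.  Per feature, a locally weighted degree-1 regression
(LOESS, default span 0.75, two robustifying iterations) of QC intensity on
injection order estimates the trend; every sample is rescaled by
(QC median / trend at its order), with linear extrapolation beyond the
terminal QCs and correction factors clipped to [0.2, 5] to prevent
blow-ups at run edges.  The trend is fitted on log intensities and
exponentiated by default, which keeps corrected intensities positive; a
linear-domain option exists.  The span, degree and domain are package
choices — published pipelines typically name only "a LOESS approach".
Features with fewer than 4 usable QC values (or a degenerate fit) pass
through unchanged and are flagged.  With sparse QCs and a wide span the
local fit can interpolate the QC points almost exactly, so QC CV after
correction underestimates residual technical variance; study-sample
correction quality is the meaningful criterion.

**Alignment.** The compound windows "0.1 % ± 0.25 min" (RT) and
"30.0 ppm ± 2.0 mDa" (mass) are read as relative-OR-absolute tolerances: a
pair matches if it is within the larger term of each dimension.  This is
the common alignment dialect and the generous reading; a strict-AND
variant is available behind a flag.  Candidate pairs are resolved to a
one-to-one matching greedily by smallest combined normalized distance,
ties broken by smaller ppm error, then smaller RT gap, then the
lexicographic id pair — deterministic and symmetric in the inputs.

Missing values are never imputed in this module; downstream statistics use
available-case analysis per variable.

## Annotation

Reference entries carry a source class that sets their mass-accuracy
limit: db30 (HMDB-like, |ppm| < 30) or db20 (LIPID MAPS-like, |ppm| < 20),
strict inequality in both.  Each entry is matched under its own source
limit (rather than running two sequential searches).  Adducts are explicit
configuration with literature-standard shifts; the defaults ([M+H]+,
[M+NH4]+, [M+Na]+ positive; [M−H]−, [M+CH3COO]− negative) reflect an
ammonium-acetate mobile phase.  RT confirmation is inclusive at ≤ 0.2 min
by default (a documented package choice).  MS/MS spectral matching is out
of scope; hit confidence is limited to mass_only / mass_rt.

The bundled reference table is a constructed, synthetic stand-in: no
public database snapshot is deposited with the source study, so neutral
masses are back-calculated from reported feature m/z values under assumed
per-class default adducts.  It is self-consistent for round-trip tests and
demonstration, not an authoritative mass list.

## Statistics

* **Mann-Whitney U** (two-sided): exact tie-aware permutation null by full
  enumeration of group labelings for combined n ≤ 12; above that, the
  normal approximation with tie and continuity correction.  The exact
  two-sided p is the fraction of labelings with |U − n1·n2/2| at least the
  observed distance (equals the classical doubled tail on tie-free data).
  Note that for a complete 4-vs-6 separation the exact p is 2/210 ≈ 0.0095
  while the continuity-corrected normal approximation gives ≈ 0.011;
  published small-cohort tables often show the latter.
* **Kruskal-Wallis** with tie correction and the χ² reference (df = k−1);
  **Dunn's post-hoc** z on mean pooled ranks with the tie-corrected
  variance, reported *unadjusted* across pairs by default (mirroring how
  bare post-hoc p-values are usually printed); Bonferroni adjustment is a
  flag.
* **Spearman stage trend** on mid-ranks (the stage coding MA=0 … V-VI=3 is
  heavily tied by design; any strictly monotone coding gives identical
  results).  Two-sided p from the t approximation with n−2 df; exact
  permutation enumeration available for n ≤ 10.
* **BH-FDR** step-up with an explicit family size m ≥ the number of
  supplied p-values, because reported subsets are corrected against stated
  families (51 for the fatty-acid panel; 2,048 for the lipidome-wide
  screen; 25/57 for per-region identified-lipid correlations).
* **ΔΔCT**: ΔCT = CT(target) − CT(reference gene) per sample, ΔΔCT
  subtracts the calibrator group's mean ΔCT, fold = 2^(−ΔΔCT); the
  calibrator group's mean ΔΔCT is 0 by construction.

Variables are screened for annotation at raw p < 0.01 (strict), matching
the convention of annotating only the strongest region contrasts.

## Synthetic data

The cohort generator starts from the bundled GM/WM median compositions,
scales species i by exp(β_i · stage_rank) to inject monotone trends,
perturbs in log space with zero-mean noise of s.d. 1/dispersion, and
renormalizes to 100 (logistic-normal compositional noise).  The
logistic-normal choice keeps the template as the approximate compositional
median and gives per-species control of spread; a Dirichlet would couple
all variances through one concentration parameter.  The default
dispersion of 25 (σ_log = 0.04) produces IQRs around 5 % of the median,
within a factor of ~2 of the published control-group IQRs — a calibration
choice, not a claim about the true variance structure, which only
quartiles document.  Default group sizes echo the study design (GM:
4/6/6/6; WM: 6/7/6/6; the source states the MA lipidomics subgroup sizes
inconsistently between its methods and figure legends — the methods-text
values are used).

The run generator interleaves pooled QCs at every 5th injection,
multiplies lognormal baselines (technical CV 0.10 for QCs, plus
biological CV 0.30 for study samples) by a shared drift curve (linear /
exponential / quadratic, default 2-fold linear), applies optional
two-group log2-fold effects and MCAR missingness, and can draw feature
masses from reference entries plus adduct plus Gaussian ppm noise.
What the generators deliberately do not emulate: correlated lipid
co-regulation, intensity-dependent (left-censored) missingness (available
as a stress-test option but off by default), retention-time drift, and
multi-batch structure — so passing recovery tests demonstrates correctness
of the algorithms under the stated noise model, not performance on every
real-data pathology.

## Problem sizes and numerical choices

Calibration suites use 5,000-replicate null simulations (Kruskal-Wallis
and stage trend, 4 groups × 6), 100-replicate end-to-end null pipelines
(100 features × 20 study samples), 200-replicate trend recovery at n = 24,
and 200-feature / 40-injection drift recovery — sizes chosen to make
Monte-Carlo error small relative to the tested margins while keeping the
default test run in tens of seconds.  Exact-test switch points (combined
n ≤ 12 for Mann-Whitney, n ≤ 10 for Spearman permutation) are fixed
constants.  All simulation randomness flows from explicit integer seeds
via numpy Generators; reports are row-ordered deterministically (panel
print order for fatty-acid variables, feature id for the lipidome table),
so identical configs and seeds reproduce reports byte-for-byte.

## Known limitations

* Enzyme-activity ratios are flux proxies; no kinetic interpretation.
* The bundled lipid reference is synthetic (see Annotation) and sum-
  composition shorthand names are not isomer-resolved.
* Single-run drift correction only; no multi-batch harmonization.
* FDR with m larger than the supplied subset is exact only when the
  subset contains the family's smallest p-values.
* Sex-stratified analyses are not implemented (underpowered at these n).
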