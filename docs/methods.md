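# Methods

This note records the models, conventions and numerical choices behind
`cleavekit`, in the order the pipeline uses them.

## Time base and lineage conventions

All times are decimal hours post activation (hpa); activation of the
reconstructed NT oocyte, or sperm injection for ICSI controls, defines
t = 0. A division is one timestamp: the mother's `end_time` equals both
daughters' `birth_time` (checked to 1e-6 h at validation). Lineage labels
(`1`, `1.1`, `1.2`, ...) are assigned by annotation order and carry no
biological meaning; sister ordering in statistics is by label. M-phase
aberrancies observed at a division are attributed to the mother cell — the
M phase belongs to the dividing cell. Cells alive at the observation
horizon (default 96 hpa) are `censored` there; their cycle lengths are
treated as missing, never horizon-truncated, and no survival-style
correction is applied anywhere. A `divided` cell may carry either two
annotated daughters or none (a division observed at the edge of the
annotation); exactly one daughter is a structure error.

## Timing features

`div1, div2.1, div2.2, div3.1, div3.4, div4.1, div4.8` are the times the
embryo reaches 2, 3, 4, 5, 8, 9 and 16 cells. They are computed as pooled
order statistics of all observed division-completion times, not per-round
ones: in poorly synchronized embryos cleavage rounds can overlap (a
granddaughter may divide before its aunt), and the cell count at time t is
1 plus the number of divisions before t regardless of round. Because any
unobserved division lies beyond the horizon, observed order statistics
remain exact when later cells are censored or arrested.

`cc_k` is the per-embryo mean cycle length of the cells of round k,
defined only when all 2^(k−1) cells of that round divided — a partial
average over the faster cells would bias slow embryos low (a `partial`
flag enables the biased variant explicitly). Inter-stages are
`diff2 = div2.2 − div2.1`, `diff3 = div3.4 − div3.1`,
`diff4 = div4.8 − div4.1`; whole cleavage-stage lengths are last-exit to
last-exit (`stage_k = div_k,last − div_{k−1},last`). The alternative
first-entry convention would count the inter-stage twice and is not used.
`ck1` is `div1` minus the annotated cytokinesis onset; whether the
original annotation starts at anaphase or furrow onset is a property of
the input, not of this package.

Speed classification at the three-cell transition uses cutoffs
(35, 41) hpa: three-group fast/intermediate/slow, or two-group fast/slow
at the midpoint 38 hpa. The two-group midpoint is a documented,
overridable choice; the source classification window is stated as a range
without a single threshold.

## Statistics

*Wilcoxon rank-sum*: exact two-sided p by dynamic-programming enumeration
of the rank-sum null distribution when the combined n ≤ 20 and the data
are tie-free; otherwise a normal approximation with tie correction and
continuity correction. Two-sided p is twice the smaller tail, capped at 1.

*Fisher 2×2*: two-sided p as the sum of hypergeometric probabilities no
greater than the observed table's (with a 1 + 1e-7 relative slack against
floating-point near-ties); the estimate is the sample odds ratio, with 0
and infinity allowed. Zero-margin tables return p = 1 with a flag.

*"Median average deviation"* is read as the unscaled median absolute
deviation about the median.

*Mother–daughter correlation* pairs each round-k cell with each of its two
round-(k+1) daughters (two pairs per mother); a per-embryo-mean variant is
available. *Sister statistics* order pairs by lineage label and count the
divided-within-horizon contingency once per unordered pair.

*Aberrancy logistic regression* fits logit P(aberrant) = β₀ + β₁·length by
iteratively reweighted least squares (Newton scoring), with a Wald
two-sided p for β₁. Complete or quasi-complete separation is detected
(vanishing weights with diverging coefficients) and reported as a flag on
the result rather than an exception or a silently huge coefficient.

No multiple-testing correction is applied by default, matching per-test
reporting; the tidy output marks p < 0.01.

## Window predictor

The classifier is 1–3 closed intervals, one per feature; inside all
intervals predicts blastocyst. Candidate interval endpoints are midpoints
between consecutive sorted unique feature values plus ±∞, so the search is
exact over all distinct data partitions and the optimal F is invariant
under strictly monotone feature transforms. The search enumerates the
Cartesian product of endpoint pairs — O(∏ mᵢ² · n), no pruning that could
change the argmax — with deterministic tie-breaking: higher accuracy, then
smaller window volume (interval widths clipped to the data range,
multiplied across axes), then the lexicographically smallest lower-bound
vector. F is the harmonic mean 2·pr·sn/(pr + sn) with the 0/0 cases
defined as 0; accuracy is always reported alongside. Evaluation is
in-sample, matching the source analysis; embryos missing a panel feature
are excluded per-combination and counted, never imputed. The
`WindowPredictor`/`WindowPredictorResults` pair wraps this as a fitted
model with a `summary()`.

## Amino-acid turnover

rate = (C_control − C_sample)[µmol/L] × drop volume[µL] /
(n_embryos × hours), giving pmol·embryo⁻¹·h⁻¹; positive is depletion
(consumption), negative appearance (release). Inputs are assumed
dilution-corrected; a `dilution` argument applies e.g. the 12.5× assay
correction when they are raw readings. *Turnover* of a profile is the sum
of absolute rates. The panel is the 20 proteinogenic amino acids minus
proline and cysteine (undetectable by o-phthaldialdehyde HPLC); unknown
names pass through with a warning. Matrix cells are replicate means with
SEM and n.

Rows (amino acids) cluster on 1 − Spearman ρ with complete linkage; a
constant row has undefined ρ and is assigned the maximum distance 2 with a
warning. Columns (group × stage window) cluster on Euclidean distance with
Ward's criterion as implemented by scipy on the distance matrix (the
Lance–Williams "ward.D2"-style recurrence; the linkage method is a
parameter). The rank-correlation matrix is computed as Pearson correlation
of row ranks directly, which degrades gracefully for constant rows.
Heatmap colors are presentation-only; every assertion in the test suite is
on numbers. Dendrograms export to Newick text.

## Synthetic cohorts

The generator is a branching simulation of cleavage rounds 1–4 (the
16-cell stage is the last annotated event; its cells appear as censored
leaves). Cell-cycle lengths are log-normal — positive support,
median-parameterizable, heavy right tail matching the irregular long
cycles seen in cloned embryos — with

log L = μ_k + u_embryo + w_pair + e_cell,

where u is a shared embryo effect, w is shared by a sister pair and e is
per-cell noise driving sister asynchrony (hence diff2/diff3). For round
transitions, the daughter pair's shared term inherits a coefficient times
the mother's own deviation; the configuration states target
mother–daughter correlations and the generator solves for the coefficient
analytically from the variance components (bisection on the closed-form
correlation, smallest-|a| branch). A negative round-2→3 target yields the
anticoupling of cloned embryos — a long two-cell stage followed by faster
third cycles. μ_k is the log target median minus an analytic Jensen
correction (averaging log-normals inflates the per-embryo mean) minus a
small scripted residual adjustment, so `cycle_median` is the realized
median of per-embryo mean cycle lengths.

Third-round cells draw an M-phase aberrancy from a logistic model in their
own cycle length. Under the `nt_strict` arrest rule an aberrant third
division arrests both daughters and vetoes blastocyst formation — cloned
embryos were never observed to survive such an error — while `tolerant`
(the fertilized default) lets development continue. Blastocyst outcome is
otherwise Bernoulli from a logistic model on one standardized timing
feature (`div2.1` for NT, `cc1` for ICSI). Randomness is governed by one
seed with per-embryo substreams, so cohorts are byte-reproducible and
stable under subsetting.

### Preset calibration (scripts/calibrate_presets.py)

The ICSI baseline absolute medians are assumptions — the source reports
differences and inter-stage medians, not absolute cycle lengths — set to
(18, 19, 12.5, 12.5) h for rounds 1–4, placing the three-cell transition
near the 35–41 hpa classification window as observed. The NT preset is
that baseline plus the reported offsets: cc1 −0.8 h (slightly shorter),
cc2 +2.3 h, cc3 +3.4 h, cc4 unchanged. The scripted calibration then
fixes, in order: per-round cell-noise dispersions to the reported
inter-stage medians (diff2 = 1.0/1.7 h, diff3 = 1.7/4.3 h for ICSI/NT);
mother–daughter correlation targets to the reported r² ladder (ICSI
0.281/0.381/0.474; NT ≈ 0 early, −0.69 for the 2→3 anticoupling, 0.663
for 3→4); the NT outcome intercept/slope so the fast/slow blastocyst rates
at the 38-hpa split are 48.9%/27.8%; and the ICSI outcome intercept/slope
so the overall rate is 41.4% and the mean in-sample accuracy of the best
F-score window on cc1 at n = 500 is 66.7%. All tuned constants are frozen
in the presets; the script reproduces them.

### What the simulator does and does not emulate

It reproduces the timing structure (stage medians, synchrony, correlation
ladder, speed–outcome coupling, arrest behavior) and the staged media
profiles with their one-stage NT lag and arginine crossover. It does not
model cell fusion, fragmentation, spatial arrangement, imaging artifacts,
the 20-minute acquisition grid (available as `time_grid = 1/3 h`, off by
default since annotated event times are already interpolated), embryo
death before the first division, or gene expression. Within-group sister
correlations are weaker than the reported pooled values (which mix rounds
and between-embryo variance); they are not calibration targets. Passing
tests therefore demonstrate that the *pipeline* recovers the statistical
structure it is pointed at — not that real embryos satisfy the generator's
assumptions.

The spent-media generator writes long-format concentration tables:
per-amino-acid baselines minus rate·n·t/V, Gaussian measurement noise, and
matched embryo-free controls. The NT 24–48 hpa column equals the ICSI
0–24 hpa column by construction (the metabolic lag), and NT arginine is
scaled below ICSI before 72 hpa and above after.

## Problem sizes

Acceptance-style checks use cohorts of 500–2000 embryos per group —
comfortably beyond the study's observational scale (tens to hundreds per
group) — chosen so parameter-recovery tolerances (±0.2–0.3 h on medians,
±4–5 percentage points on rates) sit several standard errors wide. The
full test suite runs in well under a minute on one CPU.

## Known limitations

* Cell fusion reduces the cell count; the pooled order-statistic features
  ignore this (fused cells are terminal in the data model).
* The exact Wilcoxon path refuses ties rather than enumerating the
  permutation distribution of tied ranks.
* The window search is exponential in dimensions (capped at 3) and
  intended for panels, not general feature selection; in-sample scores
  overstate generalization (a cross-validation flag is deliberately out of
  scope here).
* Logistic Wald p-values are first-order; with few aberrant events a
  likelihood-ratio or exact test would be preferable.
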