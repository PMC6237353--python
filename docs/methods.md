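# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Internal-standard quantification and calibration

Quantification is the IS ratio rule
`conc = area_analyte / area_IS × conc_IS × dilution_factor` (µM). It is
exactly homogeneous: scaling both areas together is neutral, scaling the
dilution scales the result. Values below the detection limit are kept
numeric and *flagged*, never censored to missing, because downstream RSD
computations need a complete vector.

Calibration supports two response models:

* **linear, 1/x² weighting** (default): weighted least squares with
  weights 1/conc². Over a ~6-decade, 11-level range (3.463 × 10⁻⁴ to
  161.2 µM) electrospray response noise is roughly proportional to
  concentration; inverse-squared-concentration weights make each level
  contribute comparably, which lowers low-end relative bias relative to
  OLS (verified by Monte-Carlo in the test suite).
* **quadratic, log–log weighting**: the quadratic is fitted in
  log₁₀(conc)–log₁₀(response) space, unweighted — the log transform is
  itself the variance stabiliser for proportional noise, and bending
  responses are much closer to polynomial on that scale.

The reported correlation coefficient `r` is Pearson's r between fitted
and observed response *on the regression scale* (raw or log–log). A
single undefined "correlation coefficient" is conventional on vendor
software; defining it on the fitted scale makes it meaningful for both
curve kinds.

**Inversion.** Raw-scale lines invert algebraically. Everything else
(log–log curves, raw quadratics) is inverted by bracketed root finding
(Brent) on the forward model over the fitted concentration range: the
forward model is evaluated on a 1025-point grid (geometric when the
range is positive), sign changes are bracketed, and each bracket is
solved to near machine precision. Two roots inside the range raise an
explicit ambiguity error — never a silent choice. A response below the
curve's bottom end is reported as concentration 0 with a below-range
(below-LOD) flag; above the top end, linear curves extrapolate with a
flag and curved models raise.

**Detection limits.** For the flow-injection assay LOD = LOQ = 10 × the
mean blank concentration. For the chromatographic assay LOD =
3 × (lowest measurable standard concentration / its S/N) — the
concentration at which the analyte would reach S/N = 3.

## Lipid nomenclature and isotope deconvolution

Species are named class + carbons:double bonds — `PCaaC34:0` (diacyl),
`PCaeC36:2` (acyl-alkyl), `lysoPCaC20:2`, `SM(d18:0/C18:1)` (sphingoid
and fatty acid both stated; the short form `SMC16:0` gives only the
fatty acid), carnitines `C2:0` / bare `C0`. The grammar deliberately
resolves neither double-bond positions nor the per-chain carbon split.

Flow injection offers no chromatographic separation, so species of one
class and carbon count that differ by one double bond sit 2 Da apart and
the M+2 isotopologue of the lighter (more unsaturated) species falls on
its neighbour's monoisotopic transition. The isotope envelope is modelled
as a **carbon-only binomial**: each of the n carbons is ¹³C with
probability 0.0107, a_k = C(n,k)·p^k·(1−p)^(n−k), truncated at the
requested number of peaks and renormalised (ratios such as
a₁/a₀ = n·p/(1−p) are preserved exactly). H/N/O/P isotopes are ignored:
at +2 Da the ¹³C₂ term dominates for lipid-sized molecules, and ¹⁸O/³⁴S
corrections would require elemental formulas the nomenclature cannot
supply.

The envelope's carbon count is chain carbons plus a per-class backbone:
PC 8, lysoPC 8, SM 5 (+ sphingoid, default 18 when the short form hides
it), carnitine 7 — all overridable. Nominal masses come from an affine
model (base + 14·C − 2·DB with per-class/bond-code bases calibrated
against real species); only the "+2 Da neighbour" relation inside a
series is consumed, so small absolute base errors are inert.

Per series sorted by descending double bonds, the mixing matrix is lower
bidiagonal (diagonal a₀, first subdiagonal a₂ wherever the mass step is
exactly 2 Da), and the correction solves M·x = observed by forward
substitution — this propagates through the whole chain, which subsumes
M+4-and-beyond effects. Negative solutions (noise exceeding the
predicted isotope contribution) are clipped to zero and flagged rather
than raised, again because downstream statistics need complete vectors.

## Drift and batch correction

Two QC kinds are distinguished: pooled technical-replicate injections
(`qc_train`) interleaved through the sequence train the models;
extraction-replicate QCs (`qc_test`) test how corrections generalise.

All corrections are **multiplicative** (ratio to trend). ESI drift acts
proportionally, and ratio corrections preserve non-negativity where
subtracting a trend would not.

* `is_norm` divides each feature by its IS intensity in the same
  injection, rescaled by the IS grand mean to keep the raw scale.
  Injections with missing/zero IS become missing, with a warning.
* `linear_sequence` fits, per feature and per batch, OLS of QC_train
  intensity on injection order, then divides every injection by the
  fitted trend and re-anchors at the mean fitted QC level. Fewer than
  two usable QCs → the feature passes through unchanged. Per-batch
  fitting is the default (a single global line cannot follow
  batch-specific drift).
* `batch_anchor` runs the within-batch linear correction, then rescales
  each feature per batch so its QC_train mean equals the grand QC_train
  mean. On a single batch this reduces exactly to `linear_sequence`.
  It occupies the external-batch-tool slot of the seven-way comparison:
  the original comparison included third-party batch-correction tools
  whose internals are out of scope here, so a QC-anchored method with
  the same interface fills that position, and the benchmark labels say
  `batch_anchor`, not the tool names.

The default strategy set is the four base methods plus
`is_norm→linear_sequence`, `is_norm→batch_anchor` and
`linear_sequence→batch_anchor` (IS-first orderings are the natural
combinations; "linear sequence plus between-batch rescale" *is*
`batch_anchor`, so the distinct seventh entry chains the two named
steps). Strategies are scored per feature by RSD over QC_train and
QC_test separately, with counts below 15% and 30% RSD; RSD uses the
sample (n−1) standard deviation throughout because QC sets are small.

A no-harm property holds on drift-free data: fitting two parameters to
n QCs absorbs ~2/n of the variance, so the correction leaves i.i.d.-noise
RSDs essentially unchanged at realistic QC counts (tested at n = 50).

## Annotation filter, lipid flagging, cross-check

The putative-identification filter passes a feature iff its
spectral-library match score is **strictly** greater than the threshold
(default 90 — a score of exactly 90 fails) and at least `min_libraries`
(default 1) of the six exact-mass databases (BioCyc, HMDB, KEGG,
LipidMaps, PubChem, SMPDB) agree. Unannotated features fail and are
tallied separately. The pass count is monotone non-increasing in both
knobs.

Lipid flagging treats any feature within `mz_tol` (default 0.01 Th) of a
class-diagnostic fragment — by default the phosphocholine head group at
184.0733 Th shared by PC, lysoPC and SM — as that fragment, and pairs it
with every feature co-eluting within `rt_tol` (default 0.05 min) at
higher m/z. All pairs are emitted in a deterministic order (|Δrt|, then
descending mean intensity, then ids); selecting a single best parent is
left to the caller. The defaults reflect sub-ppm-calibrated Orbitrap
data, where tight windows are safe; both are configurable, since the
correct RT tolerance depends on peak widths.

The targeted/non-targeted cross-check compares each target's protonated
mass (monoisotopic + 1.007276; positive mode assumed) against the feature
list under a tight window (default ±0.005 Da → `confirmed`) and a wide
one (default ±0.5 Da). A hit only in the wide window (`wide_only`) is
the signature of a targeted false positive: something isobaric at unit
resolution that high resolution separates.

## Precision and accuracy

`precision_report` distinguishes technical RSD (within a replicate
group, i.e. repeated injections of one extract, averaged across groups),
within-batch RSD (across replicate-group means inside a batch, averaged
across batches) and between-batch RSD (across per-batch mean levels).
The between-batch scope is deliberately computed on batch *means*: with
two batches at levels 100 and 200 and no within-batch spread it reports
sd(100,200)/150 = 47.1%, isolating the batch effect from the replicate
count. Accuracy is measured/certified × 100 with an inclusive default
band of 50–150%; the certificate's expanded uncertainty is carried along
for reporting. The platform comparison declares the side with strictly
lower RSD the winner per matched compound (ties explicit), and the
feature-count summary reports both the ratio ("X% of") and the increment
("X% more") for positive-vs-negative mode and HILIC-vs-C18, because the
two readings of "more" are easy to conflate.

The compound↔feature mapping between platforms is always an explicit
user-supplied table; nothing auto-matches silently.

## Synthetic data

Noise is multiplicative lognormal with unit mean (σ² = ln(1 + cv²)),
keeping intensities positive and noise proportional to signal.

* `make_targeted_run`: 11 calibration levels (geometric ladder,
  3.463 × 10⁻⁴–161.2 µM), blanks, and replicate samples; analyte and IS
  areas get independent noise, so replicate concentration RSD ≈
  √2 × noise_cv. With cv = 0 the quantification pipeline recovers the
  truth exactly. Defaults (12 replicates, one batch) mirror a
  reference-material replicate design.
* `make_lipid_run`: observed = M·truth for a canonical series, with
  optional noise — the exact forward model of the deconvolution.
* `make_drift_table`: per feature, intensity = (base + slope·order) ×
  batch offset × noise, slope drawn uniformly so the accumulated drift
  over the sequence is within ± `slope_range` of the base (0.3 default);
  a pooled QC_train every 10th injection (plus a trailing anchor), a
  pooled QC_test at the half-cadence offset — the QC_test cadence is a
  design choice here, since only the training-QC frequency is fixed by
  the emulated design. The truth table stores bases, slopes and offsets
  for exact recovery tests.
* `make_annotations`: score > 90 with probability `p_high_score`,
  independent library hits with probability `p_library_hit` per
  database, so the default filter's expected pass fraction is
  `p_high_score · (1 − (1 − p_library_hit)⁶)` — a closed form the tests
  check at n = 10,000 within 3σ.

Because the generators draw independent features with clean linear
drift, passing benchmarks demonstrate correctness of the corrections
under their own generative assumptions — not performance on real data,
where drift is nonlinear, features are correlated, and missingness is
structured. That gap is intentional: nonlinear (LOESS-type) drift models
are out of scope.

Problem sizes used by the tests and the acceptance script (200 features,
80 samples, 10,000 tuples/features, series length ≤ 10, ≤ 1000
Monte-Carlo repetitions) were chosen as the smallest scales at which the
checked properties are statistically decisive.

## Numerical conventions and limitations

* Delimited text only; comma default, tab on request, decimal point
  always. Empty cells and `NA` are missing; literal zeros stay zeros
  (blank logic needs them). Floats are written with 9 significant
  digits, making write→read an identity at that precision and repeated
  writes byte-identical. xlsx is supported read-only via a conversion
  command.
* Feature ids are synthesized as `m/z@RT` (4 + 2 decimals) when absent.
* Weighted fits use closed-form least squares (scaled design matrix,
  `lstsq`); no iterative optimisation anywhere except bracketed
  root finding for curve inversion.
* Degenerate inputs degrade explicitly: < 2 QCs → passthrough with
  `fit_ok = False`; non-positive fitted trends → missing + warning;
  RSD of < 2 values or a zero mean → NaN markers; a batch without QCs
  for a feature → reported uncorrectable.
* Known limitations: carbon-only isotope model (no O/S isotopes, no
  elemental formulas), linear drift model only, no spectral similarity
  scoring, no peak picking or integration, no multivariate statistics.
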