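# metlab

Post-acquisition computation for combined **targeted** and **non-targeted
metabolomics**: everything that happens after peak integration and feature
extraction, for workflows that pair triple-quadrupole MRM panels
(chromatographic and flow-injection) with high-resolution Orbitrap feature
tables. It is aimed at analytical-chemistry groups who need the data
processing behind a platform comparison to be reproducible and testable
rather than spread across spreadsheets.

## What it computes

**Internal-standard quantification.** For each analyte with an assigned
(ideally isotope-labelled) internal standard,

```
Conc_analyte = Area_analyte / Area_IS × Conc_IS × Dilution_factor
```

plus weighted calibration curves — linear with 1/x² weighting or quadratic
in log₁₀–log₁₀ space — with algebraic/bracketed inversion, and detection
limits (10 × mean blank concentration for flow injection; 3 × conc/S·N for
the chromatographic assay).

**Isotope-overlap deconvolution.** Flow-injected lipid classes
(PC, lysoPC, SM, acylcarnitines, named as class + carbons:double bonds,
e.g. `PCaaC34:0`, `SM(d18:0/C18:1)`) interfere within a carbon series:
the M+2 (²·¹³C) isotopologue of a species lands on the monoisotopic mass
of its one-fewer-double-bond neighbour, 2 Da up. With a carbon-binomial
envelope (p₁₃C = 0.0107), observed = **M**·truth with **M**
lower-bidiagonal (Mᵢᵢ = a₀, Mᵢ₊₁,ᵢ = a₂); the package builds **M** per
series and inverts it by forward substitution.

**QC-anchored signal-drift and batch correction.** Per-feature linear
regression of pooled-QC intensity on injection order (ratio-to-trend
correction), internal-standard normalisation, and a two-stage batch
anchor (within-batch linear correction, then between-batch rescaling of
QC means) — seven strategies in total, benchmarked by per-feature RSD on
training and test QCs and counts of features below 15% / 30% RSD.

**Annotation filtering and cross-checks.** The level-2 putative
identification rule (spectral-library match score strictly above 90 AND
≥ 1 exact-mass database agreeing), fragment→parent lipid flagging (m/z
184.0733 phosphocholine head group co-eluting with a heavier parent), and
a wide/narrow (±0.5 Da vs ±0.005 Da) mass cross-check that exposes
targeted false positives.

**Precision and accuracy reports.** Technical / within-batch /
between-batch RSDs, accuracy against certified reference concentrations,
matched-compound targeted-vs-non-targeted RSD duels and
chromatography/ionisation feature-count comparisons.

A seeded synthetic-data module generates inputs with the statistical
structure each stage assumes (proportional noise, isotope overlap, linear
drift + batch offsets + QC every 10th injection, score/library-hit
annotations) together with the generating truth, so the whole pipeline is
testable offline.

## Worked example

```python
import numpy as np
from metlab import isotope_decon as iso, targeted_quant as tq
from metlab import synthetic_data as sd, drift_correct as dc

# IS quantification: area ratio 2.0, IS at 0.5 µM, 10x dilution
print(tq.quantify_is(2.0, 1.0, 0.5, 10.0))      # -> 10.0  (µM)

# isotope deconvolution of a PC C34 series (double bonds 2, 1, 0)
series = iso.series_from_names(["PCaaC34:2", "PCaaC34:1", "PCaaC34:0"])
M = iso.overlap_matrix(series)
truth = np.array([1000.0, 1000.0, 1000.0])
corrected, _ = iso.deconvolve_areas(M @ truth, M)
print(corrected)                                 # -> [1000. 1000. 1000.]

# drift benchmark on a simulated 200-feature, 80-sample sequence
spec = sd.DriftSpec(slope_range=0.3, noise_cv=0.05, seed=1)
table, sheet, _ = sd.make_drift_table(200, 80, spec)
before = dc.qc_rsds(table, sheet, "qc_train")
after = dc.qc_rsds(dc.linear_sequence_correct(table, sheet), sheet, "qc_train")
print(round(before.median(), 1), round(after.median(), 1))  # -> 6.9 4.5
```

The first number is the median training-QC RSD (%) with ±30%-per-sequence
linear drift and 5% multiplicative noise left uncorrected; the second is
the same median after ratio-to-trend linear sequence correction, i.e. the
correction removes the drift component and leaves roughly the noise floor.

The same operations are available from a thin CLI
(`metlab quantify | deconvolve | drift | idfilter | lipidflag | precision |
accuracy | compare | featcount | simulate | validate | convert-xlsx`); all
inputs and outputs are plain CSV/TSV.

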