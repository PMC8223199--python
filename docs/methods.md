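# Methods

## Model and procedure

`msiadducts` operationalizes a simple chemical model of positive-mode
MALDI-MSI spectra: every detected peak is either a protonated metabolite
[M+H]⁺, an adduct of one (the same ion plus a net composition change —
¹³C-for-¹²C, Na-for-H, K-for-H, an intact matrix molecule, or a matrix
molecule that lost water), a matrix-only cluster, or noise. Two consequences
are exploited:

1. a parent/adduct pair differs in mass by exactly the monoisotopic mass of
   the net composition change, up to measurement error;
2. the adduct forms where its parent is abundant, so the two ion images are
   positively correlated across pixels, whereas coincidental mass matches
   between unrelated ions are not.

The pipeline therefore computes all pairwise mass differences, matches them
against a registry of known composition changes under a mass-accuracy
tolerance, removes peaks present in a matrix-only (blank) measurement, and
screens the surviving candidates by per-pixel Pearson correlation.

## Exact masses

All masses derive from a bundled table of monoisotopic isotope masses
(≥ 6 decimals; C 12 exactly, H 1.0078250, O 15.9949146, ¹⁰⁷Ag 106.9050916,
electron 0.0005486, …). Protonation adds the proton mass, i.e. the H-atom
mass minus the electron mass (1.0072765 Da); Δmass between two protonated
species is unaffected by this convention, but absolute m/z values (e.g.
[PC(36:1)+H]⁺ = 788.616) reproduce reference values only with it. Formulas
use signed counts (`NaH-1` = gain Na, lose H) and bracketed isotopes
(`[13C]`, `[107Ag]`), so one dialect covers neutral molecules and net
changes alike, and is expressible in a plain CSV registry
(`name,formula,category`). No Δmass is hand-entered anywhere: registry
entries store formulas and derive their masses.

## Tolerances

Mass accuracy is a relative (ppm) quantity `p`. A single measured mass is
matched within `p·m`. A mass *difference* carries the error of two measured
masses; the default propagates them in quadrature, `p·√(m_A² + m_B²)`, with
a linear option `p·(m_A + m_B)` that is strictly more permissive. Quadrature
is the standard propagation for independent errors and is the tighter of the
two defensible readings; the choice is exposed on `ToleranceModel`. Default
accuracy is 5 ppm, typical of Orbitrap-class MSI data.

## Preprocessing

Four conditioning filters reproduce common vendor-export behavior: greedy
ascending binning (ppm-scaled or absolute width; merged m/z is the
total-intensity-weighted centroid, per-pixel intensities are summed, so per-
pixel totals are conserved), an intensity threshold (keep peaks ≥ 0.05% of
the dataset maximum; "maximum" is read as the global maximum single-pixel
intensity by default, with a mean-spectrum alternative since the phrase is
ambiguous in common usage), a pixel-frequency filter (detected in
≥ ⌈f·n_pixels⌉ pixels — ceiling, so 1% of 150 pixels means 2, not 1), and a
top-N filter (by summed intensity, ties to the lower m/z for determinism).
All filters are idempotent. In `run_pipeline` they are opt-in: vendor peak
lists usually arrive already thresholded, and recovery scores on synthetic
data are defined over everything planted.

Blank subtraction removes every sample peak within `p·m` of any blank peak
and reports the removals; re-subtracting the survivors removes nothing.

## Spatial screening

Pearson r is computed over **all** pixels, zeros included: a pixel where a
peak was not detected is a true zero, and co-absence is spatial information.
(A `nonzero_only` mask restricts to pixels where either peak was detected,
for users who disagree.) p-values use the exact t transform with n−2 degrees
of freedom; constant vectors have undefined r and are reported missing with
p = 1. All screens additionally require r > 0 — the hypothesis is
co-localization, not mere dependence.

* **Bonferroni**: `min(1, m·p) < α`, m = number of tested pairs, α = 0.05.
* **Storey q-values**: π₀ is estimated on the grid λ = 0.05…0.95 (step
  0.05) via `π₀(λ) = #{p>λ}/(m(1−λ))`, extrapolated to λ = 1 with a cubic
  polynomial smoother and clipped to (0, 1]; q-values are the step-up
  minima `min_{p_j ≥ p_i} π₀·m·p_j/rank(p_j)`. With π₀ = 1 this reduces
  exactly to Benjamini–Hochberg, which the tests exploit as an oracle.
  q-values are computed over the positively correlated pairs only; default
  cutoff q < 10⁻⁷. Fewer than 10 p-values → π₀ fixed at 1 with a warning.
* **Direct cutoff**: r > r_min strictly (r = 0.3 is the conservative
  choice; r = 0.1 is the default reporting screen).

Pixels are treated as independent samples; no spatial-autocorrelation
correction is applied. This overstates the effective sample size on smooth
images, which is acceptable here because the screens are used as ranking
devices with very strict cutoffs rather than as calibrated tests.

## Synthetic data

The generator plants the structure the method assumes, with defaults chosen
as the reference study conditions: a 32×32 raster, 20 parent ions with one
DHB−H₂O adduct each at yield 0.3, multiplicative log-normal pixel noise with
CV 0.2 on the adduct images, 1 ppm mass jitter, 15 matrix peaks, 40
background peaks, m/z 150–900, peak amplitudes log-uniform over two decades
(10³–10⁵).

* Parents are 2-D Gaussian blobs (random center; σ uniform between ~w/12
  and w/4 pixels) — smooth, tissue-like localization.
* An adduct's noise-free image is yield × parent image; log-normal noise
  (unit mean, chosen CV) is applied i.i.d. per pixel. Log-normal rather
  than additive Gaussian because ion intensities are positive and
  heteroscedastic, and because corr(B, y·B·ε) is then directly estimable by
  Monte-Carlo, which the tests use as an independent oracle.
* Matrix peaks are spatially near-uniform (level + 5% Gaussian ripple), as
  matrix coats the whole slide; they double as the blank peak list.
* Background peaks are spatially unstructured: i.i.d. log-normal images.
  They model chance mass matches between ions with no spatial relationship —
  the null hypothesis the screens are calibrated against. This is a
  deliberate idealization: real confounders can be spatially structured
  (two unrelated but co-localized metabolites), and such pairs pass any
  correlation screen by construction. Passing tests therefore demonstrate
  algorithmic correctness and screen calibration under the stated null, not
  robustness to structured biological confounding, which requires orthogonal
  evidence (e.g. on-tissue MS²) and is out of scope.
* m/z positions keep ≥ 4× the jitter scale apart so planted identities stay
  unambiguous; collisions are re-drawn (bounded attempts).

Everything is reproducible from a single integer seed.

## Numerical choices and degenerate inputs

* Binning is single-linkage in ascending m/z (gap < width at the lighter
  peak joins a bin): deterministic and order-independent for sorted input;
  zero-intensity bins fall back to unweighted mean positions.
* Pair tables for n peaks are exactly n(n−1)/2 rows ordered by
  (parent m/z, adduct m/z); a chunked generator keeps 10⁴-peak datasets
  (~5×10⁷ pairs) workable without materializing the table.
* Ambiguous matches (one Δmass, several registry entries) are all emitted,
  flagged, never resolved — disambiguation needs MS² and is downstream.
* |r| = 1 maps to p = 0 (the t statistic diverges); Bonferroni caps at 1.
* Histogram bins are fixed-width from 0 Da; default 0.005 Da, wide enough
  to collect 5-ppm-scale scatter at m/z ≲ 1000 yet narrow enough to
  separate DHB (154.027) from neighboring organic deltas.
* Registry entries closer than 10⁻⁴ Da trigger a collision warning;
  duplicate names replace with a warning.

## Problem sizes

The test suite and the acceptance script run the pipeline end-to-end at the
default synthetic conditions (≈ 95 peaks × 1024 pixels, ≈ 4500 pairs) and
the screen-calibration scenario (480 peaks × 1024 pixels, ≈ 115 000 pairs);
oracle-equivalence checks use 100 random instances of ~30 peaks. These sizes
exercise every code path, including the chunked pair generator, at a scale
where brute-force oracles remain exact.

## Known limitations

* Positive mode, charge +1 only; average (abundance-weighted) masses not
  supported.
* The built-in registry covers the adducts named above; broader
  transformation lists load from CSV.
* Spatially structured confounders evade the correlation screens (see
  above).
* Profile-mode imzML is rejected rather than centroided; peak picking is
  vendor territory.
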