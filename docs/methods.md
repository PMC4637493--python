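# Methods

## The single-marker model

For a marker *k* and analyte *m* measured on the same chromatographic
method, the relative correction factor is the ratio of
concentration-normalised detector responses,

    f = (W_k · A_m) / (W_m · A_k),

with W the solution concentrations (µg/mL) and A the peak areas.  f is
dimensionless and invariant to a common rescaling of both areas
(detector gain) or of both concentrations, which is what makes it
transferable across injection volumes, instruments and columns.  Once f
is frozen, a sample run needs only the marker's calibration: the
marker's area gives W_k, and

    W_m = (W_k · A_m) / (f · A_k)

is the unique rearrangement used for quantification.  Contents in mg/g
follow from the extraction arithmetic: a mass of powder (default
0.1 g) refluxed and brought to a final volume (default 10 mL), so
content = concentration × volume / (mass × 1000).

**Exactness.**  If the detector is proportional (zero calibration
intercept), the single-marker route is an algebraic identity with the
external-standard route: on noiseless data every accuracy
100 × W_qams / W_es equals 100% exactly, and the test suite asserts
this to 1e-9 relative on a zero-intercept study.  With the small
non-zero intercepts of the reference calibrations (|b|/A of order
1e-4 at working concentrations) the identity is only approximate: f
acquires a weak dependence on the concentration at which the standards
were prepared, leaving a residual bias that stays in the per-mille
range on noiseless defaults (also asserted).  This is a property of
the method itself, not of the implementation.

**Marker choice.**  Neobavaisoflavone is the default marker
(commercially available, comparatively stable content across batches);
it is configurable.  Bavachalcone and corylin are excluded from
single-marker quantification by default — in the reference assay their
separation and abundance were too poor for a stable factor — but a
config with a different `qams_exclusions` tuple re-enables them.

## Calibration conventions

* Ordinary least squares of area on concentration, unweighted; R² is
  the squared Pearson correlation; the residual SD uses the n − 2
  denominator.  At least three distinct levels are required.
* LOD = 3σ/S, LOQ = 10σ/S with σ the regression residual SD and S the
  slope, so LOQ/LOD ≡ 10/3.  The published limit pairs of this assay
  family show exactly that ratio, which is what fixed the convention;
  the alternative σ sources (blank SD, S/N = 3) are not implemented.
* The linear range is the span of the supplied levels.  Areas
  inverting above the range are extrapolated but flagged
  `above_range`; inversions below the LOQ return the (possibly
  negative) concentration flagged `below_loq`, and the quantification
  layer renders such cells as missing ("—" in wide reports) rather
  than as zeros.
* Replicate injections are averaged on the area scale before
  inversion, after rescaling to the 10 µL reference injection volume;
  this keeps the external-standard and single-marker routes symmetric.

## The synthetic study generator

The generator emulates the data-generating process the analysis
assumes; its defaults are the study conditions.

* **Detector truth** — the published nine-analyte calibration
  parameters (slope, intercept per analyte) are the simulation truth;
  the published linear ranges bound the six geometrically spaced
  calibration levels.  Raw areas were never published, so the absolute
  area scale is anchored only by these parameters; any common scale
  factor is unidentifiable and cancels from every ratio the method
  uses.
* **Sample truth** — the thirteen published batch compositions
  (mg/g), with unquantifiable cells as zero content.  A zero-content
  analyte produces an intercept-only response flagged `blank`.
* **Noise** — observed area = expected area × mean-one lognormal
  factor with a stated CV (default 0.02, matching the percent-scale
  RSDs of replicate injections in this assay family).  Multiplicative
  noise is the right shape for integrated peak areas; additive noise
  would make small peaks implausibly erratic.
* **Volume scaling** — expected areas scale exactly linearly with
  injection volume relative to 10 µL.  Real assays show a small
  systematic drift of f with volume; that drift is deliberately not
  modelled, so simulated per-volume f values are flat up to noise.
* **Replication** — 3 injections per sample and per standard level
  (the reference study's n = 3), 6 replicates for the validation sets
  (precision per day, repeatability preps, spike recoveries), two
  precision days with a lognormal between-day factor of CV 1%,
  stability at 0/2/4/8/12/24 h with drift-free truth.
* **Spike recovery** — 0.50 g of the repeatability sample spiked at
  100% of native content; the spiked extract is measured through the
  full area → curve → amount pathway.  Because the base amount is
  subtracted as a known constant, the relative noise on the recovered
  margin is twice the area CV — recoveries at CV 2% therefore scatter
  with ≈4% SD per replicate (≈1.6% on the 6-replicate mean), matching
  the few-percent spread real recovery tables show.
* **Determinism** — one integer seed drives a single
  `numpy.random.Generator`; equal truth objects give bit-identical
  bundles.

The signal-level simulator (Gaussian peaks on a linear baseline with
white noise, trapezoidal integration against an endpoint-interpolated
local baseline, S/N as height over noise-region SD) exists to exercise
the peak-integration front end; the study-level generator writes areas
directly because every downstream computation consumes areas only.
Peak tailing, UV spectra, detector saturation, retention-time drift
and carryover are out of scope, so passing tests say nothing about
those failure modes in real data.

## Validation metrics

All dispersion metrics are RSD = 100 × s/mean with the sample (n − 1)
SD — the convention that reproduces the published per-volume f RSDs
(3.5 / 2.3 / 2.7 / 3.6 for the recoverable columns).  Intraday
precision is the RSD of the first day's replicates; interday precision
pools all replicates across days (the stricter of the two common
conventions; the across-day-means alternative is not implemented).
Recovery is the marginal formula 100 × (measured − base)/spiked.
Robustness across instrument × column groups is summarised as
100 × (max − min)/mean of the per-group f.

## Numerical choices

* Chromatogram grid: 0–60 min at 0.01 min spacing (6001 points); the
  trapezoid error on a σ = 0.15 min Gaussian is ~5e-5 relative, well
  inside the 0.1% closed-form tolerance asserted in tests.  Grids must
  cover every peak ± 5σ.
* Negative window integrals (pure-noise windows) are clipped to zero
  and flagged rather than propagated.
* S/N on a noiseless trace is reported as `inf`, not an error.
* Report rounding: contents to 4 significant figures, f to 3, RSDs
  to 2; full precision is preserved in the in-memory results, and CSV
  round-trips of raw data use `%.17g`.
* Accuracies are reported to 4 significant figures, the precision of
  the published content tables.

## Known data inconsistencies honoured, not repaired

The published tables of the reference study are internally
inconsistent in two places, and the package treats them as fixtures
only where they are self-consistent:

* Applying the f formula to the published calibration lines at equal
  concentrations gives, e.g., f ≈ 0.217 for isobavachin (the slope
  ratio), while the published per-volume table prints 0.683; no
  orientation of the formula reconciles all columns.  The
  implementation follows the formula literally; the published
  per-volume columns are used solely as inputs to the summary
  statistics (whose printed means/RSDs they do reproduce).  Simulated
  studies are self-consistent by construction, so their f values sit
  near the slope ratios.
* The two published content tables pair correctly only for a subset of
  cells; `refdata.matched_accuracy_pairs()` validates every candidate
  pairing numerically (printed accuracy must equal the recomputed
  ratio at printed precision) and exposes only the 48 consistent
  pairs, which include the headline 92.89% and 109.5% extremes.
* The bavachin mean (2.92) and the bavachin/bavachinin RSDs of the
  per-volume table are not recoverable from their rounded columns and
  are not used as recomputation fixtures.

## Problem sizes

Default simulated studies are small (9 analytes × 13 samples × 3
replicates plus standards), so a full pipeline run takes ~10 ms; the
Monte-Carlo characterisations use 200 independent studies, chosen to
put ~13 000 accuracy cells behind the band-coverage estimate while the
whole acceptance script stays in seconds.
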