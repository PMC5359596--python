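# Methods

## The forward model

The simulator uses a lumped passive-membrane model, not a cable-equation or
Schwan-type electromagnetic solution. A cell exposed to a uniform
extracellular field carrying a constant current pulse develops a local
membrane potential change

    ΔV(θ, t) = k · I · (R/g) · cos θ · (1 − e^(−t·g/τ_m))

where `θ` is the angle between the outward membrane normal and the field
direction (anode → cathode), `I` the pulse amplitude in arbitrary drive
units, `R` the baseline relative membrane resistance, `g` the drug-induced
conductance fold, and `τ_m` the membrane time constant. The choices encoded
here:

* **Plateau Ohm's law.** At plateau, `ΔV ∝ R/g` with constant current. The
  analysis pipeline assumes exactly this, so the lumped model is a
  closed-form oracle for it; nothing downstream depends on the neglected
  spatial details.
* **RC charging accelerates with conductance.** `τ_eff = τ_m/g`, as for a
  passive RC membrane: opening channels speeds charging and shrinks the
  plateau by the same factor `1/g`.
* **Pulse timing.** Defaults: `τ_m = 3 ms`, phase duration 80 ms, plateau
  sampled at 75 ms = 25 τ. The pulse must be many time constants long so the
  plateau is fully established; at 25 τ the residual charging error is
  ~1e-11, far below every tolerance used in the tests. Biphasic pulses flip
  sign in the second phase; charging is restarted per phase (the inter-phase
  residual is negligible at these durations).
* **Drive calibration.** `k` (`DRIVE_GAIN_MV = 33 mV`/drive unit) and the
  dye sensitivity (−0.0015 /mV, negative because a di-4-ANEPPS-like dye dims
  on depolarization) put the control plateau |ΔF/F| at ≈5 %, the upper end
  of the regime a fast dye produces at currents below the electroporation
  threshold. Absolute currents and fields are not modeled; the method only
  uses response *ratios*, so drive units are arbitrary.

**Drug model.** Whole-membrane conductance follows a Hill relation
`g(c) = 1 + (g_max − 1)·c^h/(c^h + EC50^h)`. Antagonist runs scale the
agonist-added conductance by a fractional block `1/(1 + (c/IC50)^h)` at a
fixed agonist concentration.

**Rectification.** The drug-*added* conductance `g − 1` applies fully on the
depolarized hemisphere (`cos θ ≥ 0`) and scaled by the rectification ratio
on the hyperpolarized hemisphere: `g_hyp = 1 + (g − 1)·rectification`. This
keeps the control condition exactly ohmic (`g = 1` on both sides at zero
dose) while reproducing the split-slope signature of an outward-rectifying
channel at dose, without channel-level kinetics. Scaling the *total* fold
instead would fabricate rectification in drug-free cells.

## What the synthetic data emulates — and what it does not

Each sampling area is rendered as 6 non-overlapping cells drawn as membrane
annuli (ring width 3 px, radius 16–22 px, membrane-localized dye over a dim
interior at 25 % of membrane brightness), background 200 counts, on a
192×192 16-bit frame. Emulated: cos θ polarization along the field axis,
linear dye response, Poisson shot noise plus 6-count Gaussian read noise,
2 % bleaching between passages applied multiplicatively to the whole frame,
and an integer stage-repositioning shift of up to ±3 px between passages.
Resting membrane fluorescence defaults to 40 000 counts — bright staining
that uses the camera's dynamic range, the photon regime in which this
instrument class operates (see *Known limitations* for why this matters).

Not emulated: optical PSF and defocus, sub-pixel drift, cell-to-cell shape
irregularity (cells are circles), photodynamic damage, receptor
desensitization, and temporal structure within a passage (frames exist only
at the two protocol sample times). Passing tests therefore demonstrate the
correctness and statistical behavior of the *pipeline* under the stated
noise model, not robustness to optical or biological artifacts absent from
the generator.

Per-stream reproducibility: one RNG per (well, area), seeded from
(plate seed, well index, area index), so results are independent of
execution order and bit-identical across reruns.

## Image analysis

1. **Registration.** Integer-pixel shift maximizing normalized
   cross-correlation within ±5 px, ties broken toward the smaller shift.
   Sub-pixel interpolation is deliberately omitted — the emulated stage's
   residual error is below a pixel, and interpolation would smooth ΔF
   structure.
2. **Binning.** 4×4 block averaging of raw counts *before* ratioing —
   the lower-variance order under Poisson noise.
3. **Shape mask.** Foreground = pixels above 0.2 × the 99.5th-percentile
   intensity in *both* the lightly smoothed (3×3 uniform filter) and the raw
   binned frame; components < 8 px dropped; mask = foreground within
   3 binned px of the object boundary (erosion difference). The double
   threshold matters: thresholding the smoothed frame alone dilates the
   object by ~1 px and admits a ring of background pixels whose ΔF/F is
   pure noise — enough to bias the slope by tens of percent through
   regression dilution. The mask is built once from the reference resting
   frame and reused for the test passage, because pixel pairing requires a
   single common support.
4. **ΔF/F_R.** Per mask pixel, `(F_S − F_R)/F_R`; pixels with `F_R ≤ 50`
   counts or |ΔF/F| > 0.5 are excluded; an area with > 50 % exclusions is
   rejected.

## Slope, conductance, CRC, QC

* **Through-origin OLS** of test on reference ΔF/F is the Rd/Rc estimator;
  the Ohm relation has no intercept (a free-intercept variant and a
  through-origin Theil–Sen fallback exist behind flags for diagnostics and
  heavy-tailed noise). Pairs with |x| < 0.002 (deadband) are dropped: they
  sit near the perpendicular axis and carry no slope information. Split
  slopes require ≥ 20 pairs per side; a whole-area fit requires ≥ 50 pairs.
* **Per-well statistic** = mean of per-area Gd/Gc (each area contributes its
  own regression), with SE across areas — not a pooled regression, so one
  aberrant area cannot dominate a well.
* **4PL fit** on log10 concentration, parameters (bottom, top, log10 EC50,
  hill), trust-region least squares with tolerances 1e-12, initialization
  from the data (bottom/top from the response extremes, EC50 at the median
  log concentration, hill 1), hill bounded to [0.3, 5] to stabilize sparse
  designs, weights 1/SE² by default. A response window below
  max(0.2, 3×median SE) in Gd/Gc units is reported as the flat-curve
  outcome (the mock-solution result) instead of a meaningless EC50 — 0.2 is
  several times the per-well SE at default noise yet far below any real
  response window (≈4 at the default 5-fold saturation). EC50s outside the
  tested range are flagged censored, not extrapolated. The bottom asymptote
  is free by default (a `bottom_fixed=1` mode exists): control conductance
  is itself an estimate, not a constraint.
* **Antagonist runs** fit a descending 4PL against antagonist concentration;
  a compound whose maximal inhibition is below 50 % of the agonist-alone
  window is called inactive, with no IC50.
* **QC.** Zhang Z-factor with sample (n−1) standard deviations (replicate
  counts are small); Z′ contrasts the lowest- and highest-concentration
  wells of the reference agonist; CV_max is the largest per-concentration
  CV across replicate curves; EC50 spread is reported both as max/min
  fold-change (primary) and as max relative deviation from the mean
  (`relative_spread`). Thresholds: CV_max < 20 %, fold-change < 2,
  Z′ > 0.4.

## Numerical and degenerate-input conventions

Coordinates are 0-based (row, col); masks are sorted coordinate lists.
Registration ties break lexicographically on (|dr|+|dc|, dr, dc); a flat
frame is unregistrable (error). An empty foreground, an undersized mask,
too many excluded pixels, a non-positive slope, fewer than 4 distinct
nonzero concentrations, constant input to min–max normalization, and
groups without separation in the Z-factor all raise explicit errors rather
than returning sentinel values. Analysis failures are isolated per sampling
area; a plate result is built from the surviving areas and failed areas are
listed with reasons.

## Known limitations

* **Regression dilution.** Noise in the reference-passage ΔF/F (the
  regressor) biases the through-origin OLS slope downward by
  ≈ σ²_signal/(σ²_signal + σ²_noise). The pipeline applies no correction —
  the estimator is plain linear regression by design — so the assay is only
  accurate in a photon-rich regime. At the defaults (40 000-count staining,
  4× binning) the residual attenuation is ~1–2 %, visible as control-well
  Gd/Gc of ≈ 1.01–1.02; at 5× dimmer staining it grows to tens of percent.
  Users adapting the pipeline to dim data should prefer longer exposures or
  coarser binning over post-hoc correction.
* The simulator's default plate is one 8-well row with 5 sampling areas of
  6 cells each at 192×192 px — a deliberately desk-scale stand-in for a
  production run (whole multiwell plates, thousands of cells per area).
  All statistical checks in the test suite and acceptance script use these
  sizes (20 seed-varied plates for the EC50-recovery statistics).
* Only uniform in-plane fields and centrally symmetric cells are modeled;
  the whole-cell null and perpendicular-axis null are exact consequences of
  that symmetry.
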