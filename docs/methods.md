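# Methods

## The measurement and the model

Ribonucleoside monophosphates (rNMPs) mis-incorporated into genomic DNA are
alkali-labile: incubation in NaOH converts each residual rNMP into a
single-strand break.  Running the hydrolysate on a denaturing (alkaline)
agarose gel therefore turns the *density of incorporated ribonucleotides*
into a *fragment-length distribution*, visible as a smear after
mass-proportional staining.  The package inverts this measurement.

The model has three ingredients.

1. **Uniform breaks → exponential lengths.**  If `k` breaks fall at
   uniformly random positions on a linear genome of `m0` nucleotides, the
   lengths of the `k + 1` resulting fragments are exchangeable with mean
   `m0 / (k + 1)`, and for large `k` the marginal length distribution
   converges to Exponential(mean `m = m0 / k`).  The breakage statistic is
   the inversion of this relation: `k = m0 / m`.  We implement the exact
   combinatorial model (integer break positions drawn without replacement),
   so `sum(lengths) == m0` holds exactly and the count is `k + 1`, one more
   than the large-`k` approximation; the discrepancy is documented on the
   round-trip identity `breaks_from_mean(m0, expected_mean_length(m0, k)) =
   k + 1` and is negligible at the `k ≥ 10^3` scales of interest.

2. **Log-linear migration.**  Migration distance follows `d = a + b·ln(sz)`
   with `b < 0`; `a` and `b` are re-fitted per gel from a marker ladder by
   ordinary least squares of distance on log-size.  Because the
   coefficients are always re-fitted, the base of the logarithm is a pure
   reparameterization (`b` rescales by `ln 10`); we use the natural log.
   Inversion is `sz = exp((d − a)/b)`, restricted to the marker hull
   `[size_min, size_max]` — log-linear migration fails near the well and
   the dye front, so sizes outside the calibrated window are treated as
   unresolvable and their intensity is excluded (and reported).

3. **Mass-proportional staining.**  An intercalating stain deposits
   intensity proportional to fragment *length*.  This is precisely why the
   intensity of a distance bin divided by the fragment size at the bin
   centre is proportional to the *number* of fragments there.  The forward
   simulator embodies the same premise (one intensity unit per nucleotide),
   so simulator/estimator closure tests the inference, not a shared
   shortcut.

## The inverse pipeline

Image → profile: lane intensity at each migration depth is the sum of
pixel values across the lane's columns; distances are measured in mm from
the well.

Background: morphological opening (running minimum then running maximum
over a `window_mm` window), the standard baseline model for gel traces.
Two numerical choices matter and are deliberate:

* the opening is computed on a median-prefiltered copy (~1 mm window) and
  then subtracted from the raw trace.  On a noisy trace the raw running
  minimum sits ~2.5 noise SD below the true background; the residual
  offset, once divided by small fragment sizes, badly contaminates the
  fragment-count weights.  Pre-smoothing before the rolling baseline is
  what rolling-ball background removers do for the same reason.
* the default window is 50 mm (half the default lane).  A whole-genome
  digest is a smear tens of mm wide; a window narrower than the smear
  (e.g. 10 mm) treats the smear itself as background and removes most of
  the signal.  The window must exceed the widest genuine feature; for
  band-only lanes a much smaller window also works.

A `global-minimum` method (subtract the profile minimum) is available as a
trivial fallback and is idempotent.

Smoothing: convolution with a normalized Gaussian kernel whose truncation
window is 3% of the lane length, with `σ = window/4` (the kernel spans
about ±2σ).  The 3% figure is conventional for gel densitometry software
but ambiguous between "window" and "σ"; both the window fraction and the
σ ratio are configurable.  Symmetric reflect padding makes the convolution
conserve the profile integral exactly.

Binning: the histogram is built on the *distance* axis with 0.5 mm bins
(the natural gel coordinate; bin width configurable), anchored at the
start of the first sample's support.  Bin centres are mapped to sizes
through the calibration; dividing by the bin-centre size (rather than a
bin-average size) is a second-order approximation at 0.5 mm widths.

Mean estimation, two estimators:

* **weighted mean** (default): `m̂ = Σ(w·s)/Σ(w)` over in-window bins.
  Simple, but biased when the window truncates the exponential — a lower
  cut at `L` inflates the mean by ≈ `L`.
* **truncated-exponential MLE**: maximizes the exponential likelihood
  conditioned on the window `[L, U]`, computed stably in `log m` with a
  bounded scalar optimization bracketed three decades around the weighted
  mean; bracket hits raise a convergence error with diagnostics.  This is
  the principled correction when a material count fraction falls outside
  the window, and it is the estimator used in the package's own
  parameter-recovery validation, where true means (1000–10000 nt) sit
  close to the 200 nt lower cut of the default ladder.

Both are computed on every run; the report carries the alternative value
whenever the two disagree by more than 10%.

Uncertainty (an extension beyond the minimal procedure): multinomial
bootstrap over bins with a user-set total pseudo-count, percentile
intervals, seeded; the point estimate is independent of the bootstrap
seed.

Lanes are compared by the ratio of breaks per genome relative to a
designated control lane; comparisons across different `m0` are refused.

`m0` is a required explicit parameter with no default: whether the loaded
DNA represents a haploid (~3.1 Gnt) or diploid (~6.2 Gnt) human genome —
or anything else — is a property of the experiment the software cannot
guess.

## The forward simulator and what passing tests show

The simulator renders a fragment set (or marker ladder) as: delta deposits
of mass = length at `d = a + b·ln(sz)` on a pixel grid (default
10 px/mm over a 100 mm lane), Gaussian band spread (`σ = 0.5` mm) with a
discretely normalized kernel so deposited mass is conserved, a constant
baseline, and additive Gaussian detector noise, floored at zero.
Fragments migrating off the lane are dropped and their mass reported
(`clipped_mass`), keeping the bookkeeping identity exact.  Gel images
place lanes as vertical stripes with a Hann horizontal taper normalized so
column sums reproduce each profile exactly; images are written as 16-bit
TIFF (primary) and 8-bit PNG.

Default conditions emulated: a 10 Mnt genome load; a marker ladder at
{200, 500, 1000, 2000, 5000, 10000, 20000, 50000} nt with equal mass per
band (1e6 units), as commercial ladders approximate; migration
coefficients `a = 110` mm, `b = −8.686` mm per ln-nt, placing that window
between ~16 and ~64 mm; baseline at a few percent of peak signal and noise
`σ = 100` intensity units ≈ 0.2% of the peak pixel signal, the regime of a
cooled-CCD gel imager.  Noise seeds are mandatory; per-lane noise streams
are derived from the gel seed plus a CRC of the lane id, so identical
configs give bit-identical outputs.

Features of real gels deliberately *not* modelled: staining saturation
and nonlinearity (the stain-detection linearity of real imagers is
uncharacterized here; no correction is applied on the inverse side
either), lane distortion (smiling, bleed), field/reptation physics, and
sequence-context-dependent breakage.  Passing recovery tests therefore
show that the inference is correct *under its own stated assumptions* —
exponential lengths, log-linear migration, mass-proportional linear
staining, additive noise — not that those assumptions hold on any
particular real gel.

## Validation by parameter recovery

The headline check simulates gels with 1000, 2000, 5000 and 10000 breaks
on a 10 Mnt genome (mean fragment sizes 10000–1000 nt spanning the ladder
window) at the default noise/band settings, renders the image, and runs
the complete inverse pipeline — lane extraction from the TIFF, background
removal, smoothing, marker peak detection and rank-order pairing,
calibration refit, truncated-MLE estimation.  Across seeds the recovered
break counts sit within a few percent of truth (well inside the 15%
acceptance band) with perfect rank ordering, and the refit migration
coefficients land within 2% of the configured ones.  The 10 Mnt problem
size keeps the whole study sub-second while leaving >10^3 fragments per
lane, ample for the exponential limit to hold.

## Known limitations

* The weighted-mean estimator is reported faithfully but is biased under
  truncation; users comparing absolute (not relative) breakage levels
  should prefer the truncated MLE.
* Rank-order pairing of detected marker peaks to ladder sizes assumes all
  and only the ladder bands are detected; the peak count is checked and a
  mismatch is a hard error rather than a silent mis-pairing.
* Heavy truncation (≥50% of lane intensity outside the window) triggers a
  loud warning: the estimate then reflects the resolvable window more than
  the lane.
* Breaks are counted, not attributed: alkali-labile lesions other than
  rNMPs are indistinguishable to this assay.
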