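# Methods

This note records the models implemented in `massphot`, the defaults and
why they were chosen, the numerical choices that matter, and what the
synthetic data do and do not establish about real measurements.

## Signal model

A landing event is the irreversible binding of one molecule to the
coverslip.  Its ratiometric contrast (fractional reflectivity change) is
modelled as linear in length,

    c = b + κ·L·(1 + ε),      ε ~ N(0, cv(L)),

stored as a positive magnitude.  Defaults: κ = 1.22×10⁻⁵ per bp for dsDNA
and 7.1×10⁻⁶ per nt for ssDNA (half the doubled per-bp-equivalent slope of
1.42×10⁻⁵), intercept b = 0.  The per-species coefficient of variation
switches from `cv_small` (2%) below `crossover_length` (400 bp) to
`cv_large` (6%) above it.  This is a phenomenological stand-in for the
observed growth of peak width with molecular size (surface footprint
approaching the diffraction limit); published data do not include numeric
peak widths, so these values are plausible defaults, configurable
everywhere.  The replication studies that state "CV ≤ 5%" as part of
their protocol use `cv_large = 5%`.

## Kinetics

Every molecule binds independently, exactly once, with an exponential
waiting time from sample addition (t = 0) at rate

    k_i = α · L_i^β,      β = −0.72,

the diffusion scaling law for DNA.  Acquisition observes only
[t₀, t_final] = [15, 135] s, so the expected in-window yield of species i
is g(k_i) = e^{−k_i t₀} − e^{−k_i t_final}.

Default generator scaling factor: **α = 0.5** (units s⁻¹·bp^0.72).  This
puts k between ~0.011 s⁻¹ (200 bp) and ~0.003 s⁻¹ (1200 bp): depletion is
clearly visible (in-window yields 0.62 vs 0.29, a two-fold counting bias
across the ladder) while every k_i stays below the in-window-yield
turnover ln(t_final/t₀)/(t_final − t₀) ≈ 0.018 s⁻¹, so raw counts decrease
monotonically with length — the regime the correction procedure assumes.
No unbinding is modelled (tight binding on an amino-silanized surface).

## Diffusion correction

The observed count a_i (Gaussian peak area in events) is corrected to

    a′_i = a_i · e^{k_i t₀} / (1 − e^{−k_i (t_final − t₀)}) = a_i / g(k_i),

which is ≥ a_i always, then renormalized into mole fractions.  The
average rate k is the maximum-likelihood rate of a single exponential
truncated to the window, fitted on the pooled arrival times of all
species; the score equation `1/k − mean(t − t₀) = ΔT/(e^{kΔT} − 1)` is
solved by bracketing, with the standard error from the observed Fisher
information.  A sample mean at or past the window midpoint means no
depletion is detectable (flat-likelihood limit); this is flagged and the
correction refused rather than extrapolated.

**Choice of mean length.**  Turning k into α requires an average length:
α = k/⟨L⟩^β.  Numerically, the pooled truncated-exponential MLE converges
to the *count-weighted mean of the per-species rates*, i.e. to
α·⟨L^β⟩ — not to α·⟨L⟩^β.  Pairing k with the arithmetic
abundance-weighted mean therefore overestimates α systematically
(by 30–50% at the default depletion strength, leaving a +1.5 to +2.7
percentage-point excess on the shortest species of an equimolar ladder),
whereas pairing it with the **power mean of order β**,

    ⟨L⟩_eff = ( Σ a_i L_i^β / Σ a_i )^{1/β},

makes α̂ exactly consistent and collapses the residual bias below 0.1
percentage points.  `correct_abundances` therefore defaults to this
"effective" mean; the arithmetic mean (`"weighted"`) and the literal
printed convention Σ L_i a_i / N (`"literal"`, a mean only when the a_i
are fractions) remain selectable.  The weights are the raw
(uncorrected) areas in a single pass; an optional fixed-point iteration
to self-consistency between ⟨L⟩ and a′_i exists but is off by default, as
it compounds rather than cures the arithmetic-mean bias.

## Detection

Movie frames are averaged in consecutive non-overlapping batches of
`n_binned` frames and neighbouring batches ratioed:
`diff_j = (batch_{j+1} − batch_j)/batch_j`, so only reflectivity changes
survive the static background.

* **Candidate search** runs on the differential frame smoothed with a
  Gaussian matched to the PSF (σ = `psf_sigma_px`, default 1.4 px).
  Matched filtering gains ≈2.5× in single-pixel SNR, which matters
  because a landing in the middle of a batch splits its amplitude between
  two consecutive differential frames (fractions f and 1 − f).
* **Threshold 1** is a multiplier of the robust noise scale
  (1.4826 × median absolute deviation) of the smoothed frame.  The
  package defaults mirror the published analysis settings (1, raised to
  3 for long ssDNA); under this package's scale-free semantics those
  values admit abundant noise maxima, so the recovery and
  false-positive studies run at threshold 5, where the Gaussian tail
  bound keeps expected false positives ≤1 per 100 frames of 128×128 px.
* **Threshold 2** is a radial-symmetry score in [0, 1]: the fraction of
  gradient energy in the candidate patch pointing at the patch centre.
  It is 1 for a perfect radially symmetric PSF, invariant under 90°
  rotation, lower for stretched or noisy patches, and filtering on it is
  monotone by construction.  Pure-noise patches score ≈0.5–0.6 on
  average, so this criterion discriminates shape, not amplitude.
* **Deduplication:** detections at the same site (within
  `patch_radius_px`) in consecutive differential frames are one event;
  the first-appearance timestamp is kept, with the larger amplitude's
  position and score.
* **Quantification:** the contrast is the amplitude of a 2-D Gaussian
  (free centre within ±2 px, free width and offset) fitted to the
  ratiometric difference between the batch *after* and the batch
  *before* the landing boundary (skipping the batch containing the
  landing).  A single-differential-frame amplitude would be biased low
  by up to 50% for mid-batch landings; the straddling difference
  measures the full step regardless of landing phase.  Measured over
  many injected events, the mean amplitude bias is ≈+1.4% with ≈6%
  per-event scatter at 10× noise.  Events in the first or last batch
  fall back to the single-frame fit (edge effect, not used in studies).

## Distribution analysis

The kernel density estimate uses an absolute bandwidth in contrast units
(default 2.1×10⁻⁴); prominent maxima of the KDE initialize the
sum-of-Gaussians least-squares fit to the event histogram (the component
count can be forced to the nominal species count, in which case the
prominence threshold is relaxed until enough maxima exist).  Fitting to
the KDE curve instead of the histogram is available (`target="kde"`) and
rescaled to the same count-per-bin amplitude convention, so peak areas
`a = A σ √2π ≈ n_events × bin width` either way.

Numerical choices that proved necessary:

* **Bin width** must resolve the narrowest peak; the default 1×10⁻⁴ is
  adequate for broad peaks but the pipeline derives
  `bin_width = min_species σ / 4` from the contrast model when one is
  known (the 100 bp peak at 2% CV is only 2.4×10⁻⁵ wide).
* **Parameter scaling:** amplitudes (~10²), centroids (~10⁻³) and widths
  (~10⁻⁵) differ by orders of magnitude; the trust-region fit uses
  per-parameter `x_scale` seeded from the initial values, without which
  it is ill-conditioned and can stall or swap components.
* **Seeding and bounds:** each component's σ is seeded from the spread of
  the events nearest its guess and its amplitude from their *count*
  (individual histogram bins are Poisson-noisy and can be zero even at a
  peak); each centroid is bounded to within half the gap to its nearest
  neighbouring guess, which removes label-swap local minima.
* Non-convergence is reported (flag plus residual RMS), never hidden; an
  under-parameterized fit simply shows a large residual.

## Calibration

Ordinary least squares of peak-mean contrast on nominal length, free
intercept by default (a through-origin flag covers the strict
proportionality reading).  Species are excluded from the fit only by
explicit label (e.g. the 2000 bp fragment, whose size approaches the
diffraction limit); nothing is auto-detected.  Length conversion for
error evaluation uses the replicate-averaged slope and intercept.  With
an unbiased generator this protocol makes the *grand-mean* deviation
vanish identically (OLS residuals average to zero and averaging fits
across replicates preserves this), so the reproduction studies report
grand-mean length errors at machine precision; the per-species,
per-replicate scatter (±1 bp at 2000 events/species) is the informative
spread.  Error SDs use the sample convention (ddof = 1).  Mass-domain
conversion divides the slope by 0.649 kDa/bp (dsDNA) or 0.3245 kDa/nt
(ssDNA); a per-nt ssDNA slope is doubled before per-bp comparisons.

## Study sizes

The replication studies simulate ≥2000 in-window events per species
(5 replicates for the dsDNA calibration ladder, 4 species × 3 replicates
for ssDNA), an equimolar 200–1200 bp ladder for the correction round
trip, and 120 injected PSFs at 8× differential noise RMS in a
2000-frame, 128×128 px movie for detection recovery.  All studies are
seeded and complete in seconds to a few minutes on one CPU.

## What the synthetic data do not show

The generator emulates the *assumed* structure of the analysis: linear
contrast, Gaussian peak spread, exponential depletion with the β = −0.72
law, a Gaussian PSF, and Gaussian shot noise on a static background.
Passing tests therefore demonstrate that the pipeline inverts its own
generative model without bias at realistic sizes — not that real
instruments obey it.  Specifically out of scope: sequence-dependent
contrast (GC content, nicking, supercoiling), PSF deformation beyond the
diffraction limit (handled only by relaxing the symmetry threshold),
focus drift and flat-fielding, unbinding on non-functionalized glass,
detection-efficiency loss for the smallest fragments (reported as-is,
uncorrected), and absolute molar concentrations (detection-volume
geometry is not modelled; only relative fractions are reported).
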