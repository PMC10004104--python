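# Methods

This note documents the models, conventions and numerical choices behind
`lmposl`, and what the closed-loop validation does and does not
demonstrate.

## Relative luminescence efficiency and the composite model

The relative efficiency of a foil for protons is the per-unit-dose OSL
signal relative to ⁶⁰Co gamma reference irradiation,
η = (OSL_p/D_p)·(D_γ/OSL_γ).  It is scale-invariant in both the signal
units and the reference-dose units, which the test suite asserts as a
property.

Its energy dependence is modelled as an additive composite of a step and
a weak linear term,

    η(E) = A · step((E − E₀)/w) + s·E + c,

with the logistic function as the default step shape.  The roles of the
parameters: A is the plateau amplitude contributed by the step, E₀ the
threshold energy of the quenching drop, w the transition width, s the
weak residual energy dependence above ~20 MeV, and c an optional
intercept **fixed at 0 by default** — no observable in the analysis
constrains it separately from A at the energies of interest, so freeing
it only inflates the covariance.  The additive form is chosen so that the
plateau value is A + s·E (0.56 + 0.0015·58.8 ≈ 0.648 for the reference
LMP parameterisation) while η → s·E + c → ≈ 0 below threshold.
Error-function and arctangent step shapes are retained behind
`compare_step_shapes` as a comparison harness, not an automatic selector;
the logistic stays the default.

### Fitting

`QuenchingModel` performs weighted least squares of η against the
*median* kinetic energy of the local proton spectrum.  Weights default to
w_i = 1/max(IQR_i, 0.1 MeV): a broader local spectrum means the single
median is a poorer summary of what the foil saw, so the point counts
less.  The floor (0.1 MeV) keeps entrance-region points, whose spectra
are very narrow, from dominating the fit outright.  The opposite reading
(w_i = IQR_i) is available as `weight_mode="iqr"` since the weighting
direction is a convention, not a law.  χ² is reported as the weighted
residual sum Σ w_i r_i², reduced χ² as χ²/(n−k); parameter covariance is
the Gauss–Newton (JᵀJ)⁻¹ scaled by the reduced χ².  Optimisation uses a
bounded trust-region reflective solver (A > 0, E₀ ≥ 0, w > 0) with tight
tolerances; non-convergence raises an error carrying the last iterate,
and a data set whose energies all lie on one side of the starting
threshold is rejected as unidentifiable.

### Correction and its guards

Correction divides each measured dose by η̂(E_median) with a floor of
0.05: below the quenching threshold the model tends to zero and an
unbounded division would amplify noise without limit.  Floored depths are
flagged, never dropped.  When building the efficiency profile from a foil
stack, a depth is excluded (with a warning) when the reference dose there
falls below 1 % of the entrance dose: the foil signal at such depths is
camera noise floor, and the ratio of two near-zero numbers is undefined
within noise.  This plays the role that manual outlier rejection plays in
real measurement campaigns; no other automatic outlier rule is applied.

The foil doses entering the profile are absolute (Gy, via the per-foil
⁶⁰Co calibration); the *relative* reference depth–dose curve is anchored
so that its mean over the first 5 mm equals the delivered entrance dose.
This preserves the absolute efficiency scale — the entrance efficiency
comes out near 0.65, not 1 — while keeping the ratio insensitive to the
reference curve's arbitrary normalisation.

## Transport surrogate

The analysis only consumes relative depth–dose curves and per-depth
energy spectra, so a full condensed-history Monte Carlo is replaced by a
1-D continuous-slowing-down model:

* Bragg–Kleeman range–energy relation R(E) = αEᵖ with α = 2.2×10⁻³
  cm·MeV⁻ᵖ and p = 1.77 (standard literature values for protons in
  water; `RangeEnergyRelation.calibrated` rescales α to a user-supplied
  anchor).  This puts R(58.8 MeV) ≈ 29.8 mm, within 5 % of the 29 mm
  clinical anchor, and residual ranges of 2.2 mm at 13.4 MeV and 4.4 mm
  at 20 MeV.
* Initial energies are drawn from a normal distribution (default mean
  58.4 MeV, FWHM 1.4 MeV) hard-truncated above at 58.55 MeV — the
  accelerator's energy ceiling.  Note that the truncation pulls the
  *sample* median at the surface down to ≈ 58.09 MeV; the test suite
  checks the entrance spectrum against the analytic truncated-normal
  median rather than against the nominal mean.
* Range straggling is Gaussian in range space, σ_R = k·Rᵐ with
  k = 0.012 cm^(1−m), m = 0.935.  Because straggling is applied to the
  range, back-computed energies at shallow depths can individually exceed
  the energy cutoff; medians and doses are unaffected.
* Dose is scored per 0.05 mm slab as the energy lost in the slab: with
  S(z) = Σ_alive E_i(z) evaluated at slab edges, the slab dose is
  S(z_j) − S(z_{j+1}), so stopping protons deposit their full residual
  energy in their final slab and the scoring is exactly
  energy-conserving by construction (the suite verifies closure against
  the entrance spectrum to 0.5 %).
* No nuclear interactions, lateral transport, Coulomb scattering or
  secondaries.  These shape the absolute dose at the few-percent level in
  reality; the closed-loop validation is insensitive to them because the
  same surrogate generates and analyses the data.

Quantiles of unbinned spectra use linear interpolation of the empirical
CDF (numpy's default, "type 7"); pooled weighted spectra use the
midpoint-CDF rule; histogram-only spectra interpolate linearly within
bins.  An empty spectrum (depth beyond range) is an error for summary
statistics and a dropped observation in the profile.

### SOBP

A spread-out Bragg peak is composed by shifting the pristine beam
upstream through PMMA degraders (WET factor 1.15) — each component is
re-simulated with its range offset, so its spectra are exact within the
surrogate — and solving non-negative least-squares weights that flatten
the composite over a chosen plateau, scaled so the plateau mean is
exactly 1.  Fluence losses in the modulator are folded into the solved
weights.  The default modulator (the package's own configuration, since
no standard step set exists for this geometry) uses 10 components with
1.3 mm WET spacing and a 17–28 mm plateau; flatness on the constructed
set is < 3 % (tested).  Pooled per-depth medians and IQRs are recomputed
from the weighted union of component samples, never averaged from
component summaries; as expected, the SOBP median at a given depth is
below the pristine median and its IQR is broader.

## Phantom bookkeeping

Foils are 0.54 mm thick with WET 1.05; plates are 2.4 mm with WET 1.15
(three plates totalling 7.2 mm).  A foil's scoring depth is the upstream
cumulative WET plus a within-foil offset.  The default attribution point
is the centre of the 0.4 mm grain layer (offset 0.5·0.4·1.05 = 0.21 mm):
the OSL powder sediments to the lower part of the foil before the
silicone cures, so the optically active layer does not sit at the foil
front.  `front` and `mid` conventions are selectable for sensitivity
checks; switching conventions shifts all foil depths by a constant and
leaves depth differences intact.  The full 40-foil stack arithmetic gives
a total WET of 30.96 mm (40·0.54·1.05 + 7.2·1.15); a commonly quoted
value for this stack is 30.6 mm, which its own constants do not
reproduce — the computed value is used.  Foils map to the nearest scoring
slab, ties to the shallower one.

## Imaging chain

The processing order is fixed: drift-correct → subtract background →
locate → flat-field → align → extract.  Choices worth recording:

* **Drift** is a fractional sensitivity increase (default 0.1/min) and
  the correction is divisive with Δt measured from the session's first
  acquisition.  Correcting both signal and background *before*
  subtraction is what makes the result independent of acquisition order;
  the suite tests this equivalence on constructed frames.
* **Background subtraction** clips at zero so negative noise excursions
  cannot bias ROI means; the fraction of clipped pixels inside the
  located disc is recorded and logged when above 0.1 %.
* **Localisation** thresholds the live view at the 30 % quantile of the
  full frame and takes the largest 4-connected component (minimum area
  1000 px).  Because that quantile typically sits *below* the background
  median, more than half of the noisy background exceeds the threshold;
  a binary opening (disk radius 2) is applied before labelling to stop
  supra-threshold background speckle from percolating into the detector
  component.  Without this cleanup the stated threshold rule is unusable
  on noisy frames.
* **Marker** — the detector's orientation mark is modelled as a dim notch
  on the disc rim; its angle is the minimum of the rim-band angular
  intensity profile (36 bins of 10°, parabolic sub-bin refinement,
  accurate to ~1–2°).
* **Flat-field** gain is central-circle-mean(flat)/flat, so
  multiplication *removes* the vignette.  The literal alternative
  (multiplying by the flat normalised to its central mean, which imprints
  the pattern instead) is kept behind `literal_gain=True` for
  comparison.
* **Alignment** composes the translation (centre → (512, 512)) and the
  rotation (marker → up) into a single affine map, evaluated with one
  bilinear interpolation pass — mathematically identical to
  translate-then-rotate about (512, 512) but with one resampling instead
  of two.  Out-of-frame pixels are zero-filled.  Coordinates are 0-based;
  (512, 512) is used verbatim as the alignment target of a 1024-frame.
* **No median filters** anywhere in the chain.

## Synthetic data generator

A frame is (1 + rate·t)·[bg + vignette·jitter·gain·dose·disc] plus
optional Poisson shot noise and Gaussian read noise, quantised to 16
bits.  The vignette multiplies only the optical signal — the sensor's
background offset is not light and is not vignetted; this also keeps the
quantile-threshold localisation well-posed on low-noise frames.
Defaults: background 100 ADU, read noise 5 ADU, shot noise on, vignette
10 % at the corner, 250 ADU/Gy, disc radius 330 px, marker notch 12° wide
at 55 % rim intensity.  Sessions stagger timestamps at 0.1 min per frame,
so the drift factor spans ≈ 1–1.8 across a 40-foil session.

Per-pixel noise averages to ~0.01 % over the ~2.8×10⁵ ROI pixels, so the
foil-to-foil scatter that a realistic fit must tolerate is instead
produced by a per-frame multiplicative gain jitter (sd 1.5 %, modelling
LED power and repositioning variation between readouts); the resulting
scatter on a proton/gamma signal ratio is ≈ 2 %.  Quenching is applied at
the foil's single attributed depth by default; `integrate_foil=True`
averages η over the foil's 0.55 mm WET per surviving proton to probe the
thick-detector caveat for stopping protons.  OSL response is assumed
linear in dose throughout the simulated range (≤ 60 Gy), well inside the
material's linear regime.

What passing closed-loop tests show: every pipeline stage is
self-consistent and the correction exactly inverts the quenching the
generator applied, at realistic noise levels.  What they do not show:
fidelity of the transport surrogate to a real beamline, real foil
non-uniformities, OSL decay-curve kinetics, readout bleaching, or the
behaviour of the efficiency model under spectra more skewed than the
surrogate produces (deep SOBP regions in real data under-respond even
after correction; that discrepancy is outside this package's scope).

## Validation problem sizes

The closed-loop checks run at desk scale: 10⁵ protons for the pristine
loop, 5×10⁴ per SOBP component (10 components), 2×10⁴ protons for the
spectra behind the parameter-recovery study (25 replicates × 40
observations, noise sd 0.03).  These sizes give Monte-Carlo scatter well
below the tolerances being asserted; all randomness flows from a single
seed and identical seeds give bit-identical outputs.
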