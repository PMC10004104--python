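# lmposl

Proton-energy-dependent luminescence-efficiency (quenching) correction for
2-D dosimetry with LiMgPO₄ (LMP) silicone-foil OSL detectors.

## The problem

Flexible silicone foils loaded with LiMgPO₄:Tb,B powder store a dose-
proportional optically-stimulated-luminescence (OSL) signal and are read
out as 16-bit camera images, which makes them attractive for verifying
ocular proton-therapy treatment plans: a stack of foils in a PMMA phantom
samples the whole depth–dose curve in one irradiation.  Like every OSL
material, LMP under-responds where the ionisation density is high: a foil
calibrated against ⁶⁰Co reads roughly 35–40 % low in the entrance region
of a ~58.8 MeV proton beam, and far lower near the Bragg peak, where the
protons are slow.  Correcting a measured depth–dose curve therefore
requires knowing the relative luminescence efficiency

η(E) = (OSL_p / D_p) · (D_γ / OSL_γ)

as a function of the local proton kinetic-energy spectrum.

## What the package does

* **`lmposl.imaging`** — the six-step 2-D image-correction chain: sensor
  drift correction (divisive, `1 + rate·t`), per-detector background
  subtraction, detector localisation (30 % intensity-quantile threshold),
  flat-field correction, spatial alignment (centre → (512, 512), rim
  marker → "up"), and extraction of the ROI statistic (mean ± sd over a
  central circle of radius 300 px).  No median filtering anywhere — it
  biases the mean dose.
* **`lmposl.transport`** — a 1-D CSDA surrogate built on the
  Bragg–Kleeman relation R(E) = αEᵖ with Gaussian range straggling:
  depth–dose curves on a 0.05 mm grid and per-depth kinetic-energy
  spectra (600 bins, 0–60 MeV) summarised by median and IQR; SOBP
  composition by PMMA range-shifting with non-negative least-squares
  flattening weights.
* **`lmposl.phantom`** — water-equivalent-depth bookkeeping for the
  40-foil/PMMA stack (foil WET 1.05, PMMA WET 1.15, grain-layer scoring
  convention).
* **`lmposl.efficiency`** — the composite efficiency model
  η(E) = A·logistic((E−E₀)/w) + s·E (+ c), fitted to per-depth
  efficiency observations against the median kinetic energy with 1/IQR
  weights, statsmodels-style: `QuenchingModel(...).fit()` returns a
  `QuenchingResults` with estimates, standard errors, χ² diagnostics, a
  `summary()` table and a `correct()` method that divides measured doses
  by the modelled efficiency (floored at 0.05 to bound distal
  amplification).
* **`lmposl.synthdata` / `lmposl.pipeline`** — a synthetic camera-session
  generator (drift, vignette, shot/read noise, random placement, rim
  marker, per-frame gain jitter) and the end-to-end closed loop used to
  validate the whole chain without measured data.

The reference parameterisation for LMP foils is A = 0.56,
E₀ = 13.73 MeV, s = 0.0015 MeV⁻¹: the efficiency plateaus at
η(58.8 MeV) ≈ 0.648 and collapses below 0.05 under ~13 MeV
(residual range ≈ 2 mm of water).

## Worked example

Fit the quenching model to noisy synthetic efficiency observations whose
median energies and IQRs come from the transport surrogate:

```python
import numpy as np
from lmposl import BeamModel, LMP_REFERENCE_CURVE, QuenchingModel, synthdata, transport

depths, spectra = synthdata.spectra_for_energy_span(
    BeamModel(), n_depths=40, n_protons=20000, seed=1)
med, iqr = zip(*(transport.spectrum_summary(s) for s in spectra))
obs = synthdata.make_efficiency_observations(
    LMP_REFERENCE_CURVE, np.array(med), np.array(iqr), noise_sd=0.03,
    rng=np.random.default_rng(1), depths_mm=depths)
result = QuenchingModel.from_observations(obs).fit()
print(result.summary())
```

```
Quenching efficiency model (composite logistic step + linear)
============================================================
parameter         estimate       std err
------------------------------------------------------------
amplitude          0.52852        0.0146
center              13.636          0.15
width              0.62219          0.13
slope            0.0022558      0.000346
------------------------------------------------------------
n_obs = 40   chi2 = 0.01734   reduced chi2 = 0.0004816
```

One noisy replicate recovers the generating parameters to within a few
standard errors: the efficiency step sits at ≈ 13.6 MeV with amplitude
≈ 0.53 and a weak residual slope.  `result.correct(dose, e_median)` then
divides measured doses by η̂ at the local median energy:

```python
corrected, floored = result.correct(np.array([7.46, 16.41]), np.array([57.8, 17.8]))
# corrected -> [11.32, 28.89], floored -> [False, False]
```

A full closed loop (transport → synthetic session → image chain → fit →
correction) is one call:

```python
from lmposl import run_closed_loop
loop = run_closed_loop(mode="pristine", n_protons=100_000, seed=42)
print(loop.max_relative_deviation(min_median_energy=14.0))  # ≈ 4.5 (percent)
```

There is also a CLI (`osl synth`, `osl process`, `osl simulate`,
`osl fit-efficiency`, `osl correct`) for running the stages on files.

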