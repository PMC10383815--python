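# Methods

This note records the statistical and numerical conventions behind `dtsq`,
the choices made where the design was genuinely open, and what the
synthetic generators do and do not emulate.

## Risk ranking (fmeca)

Factors are scored 1–5 for severity, occurrence and detectability
(RPN = S·O·D spans 1–125; the upper bound is configurable but defaults
to 5). The three-level classification brackets the mean RPN with a
two-sided Student-t interval on n−1 degrees of freedom — with 26 factors,
mean 38.23 and SD 42.88 this yields the 20.91–55.55 band used to separate
high from medium risk. Ties exactly on a bound classify as *medium*.
Registers need n ≥ 3; a zero-variance register degenerates to a single
point and everything classifies medium.

## Designs and coding (doe)

The screening design is the 12-run Plackett–Burman matrix (Paley cyclic
construction) plus center replicates; balance and orthogonality are
checked by brute force on every generated or loaded design. The
optimization design is a 2³ + 6 axial + 3 center CCD with rotatable
α = 1.682; axial settings snap to hardware grids where they exist (FID
sizes on the power-of-two-derived grid, scan counts on multiples of 8), so
the realized axials are NS ∈ {16, 96}, TD ∈ {16384, 131072}, Tₗ ∈ {16.59,
33.41 s}.

Coding is the piecewise-linear map fixed by the explicit low/center/high
anchors (several screening factors have non-midpoint centers, e.g.
concentration 0.5/2/5 mmol/L). Coded values of snapped axials follow from
their actual settings — NS codes to ±5/3 and TD to −1.5/+2.0 — rather
than the nominal ±α.

Timing is closed-form: AQ = TD/(2·SW·f) with the spectral width converted
to Hz at 500.13 MHz, Tₗ = AQ + D₁, and
T_q = (NS + DS)·(Tₗ + D₈ + overhead)/60 minutes. The 2.75 s per-scan
overhead is a calibration constant fixed once against the packaged
optimization run table (it reproduces all 17 printed times to ±0.05 min);
it is not a spectrometer specification.

## Regression (modeling)

All fits are ordinary least squares on the coded design (statsmodels
behind the module surface). Screening models are intercept + all main
effects over all runs including centers; a factor is *significant* when
the two-sided 95% t confidence interval of its coefficient excludes zero.
Response surfaces use explicitly supplied quadratic-subset terms. On these
balanced, near-orthogonal designs partial-least-squares fits coincide with
OLS (verified numerically), so OLS is used for its determinism and
closed-form covariance.

Coefficients are reported on two scales: raw coded units, and
*unit-variance* units in which each coefficient is multiplied by the
sample SD (ddof = 1) of its factor column over the design, interactions by
the product of the factor SDs and squares by the square. The second scale
is what MODDE-style coefficient tables and plots print; the scan-count SNR
coefficient, for example, is 375.5 per coded unit and 345.6 per factor SD.
Square-term unit-variance values are within ~10% of, but not identical
to, MODDE's (its exact centering of square columns is undocumented).

Prediction at a coded point returns x′b; the prediction variance is
x′Σx + s², with Σ the coefficient covariance and s² the residual
variance.

## Design space and MODR (design_space)

For each grid point the three responses are simulated by drawing
coefficient vectors from MVN(b̂, Σ̂) per response (one shared draw set per
map, which leaves every point's marginal distribution unchanged) plus an
independent residual draw per simulated observation. A draw fails when
accuracy > 3%, SNR < 1000 or T_q > 25 min; the combined failure event is
the union, so the combined probability dominates each per-response map.
The grid is 64 × 64 over (NS, Tₗ) at each discrete TD slice — TD only
takes hardware values, so a continuous TD axis would be fictitious — and
the design space is the region with combined failure probability ≤ 1%.
Because x′β + ε is exactly normal, the Monte-Carlo estimate is testable
against the closed-form tail Φ((limit − x′b)/√(x′Σx + s²)); the suite
checks agreement within three binomial standard errors. The default seed
(20230629) makes every map bit-reproducible; n_sim = 10,000 gives a
standard error of ~0.1 percentage points near the 1% contour.

Verification points are specified as (NS, TD, D₁) and the time lag is
derived as Tₗ = AQ(TD) + D₁ before coding, which is exactly how the
TD–D₁ interaction was kept out of the modelled space.

## Quantification (qnmr)

Integration fits Lorentzian lines plus a constant local baseline by
bounded least squares inside each window (default windows 8.00–8.22 ppm
for the standard, 1.45–1.85 ppm for the two analyte signals); areas are
analytic (h·π·FWHM/2). The proprietary "line fitting" integrator the
original workflow used is not public; this replacement is validated by
round-trip on synthetic spectra (areas to 1e-6 relative, noiseless). SNR
is fitted peak height over twice the RMS of the mean-removed intensity in
a signal-free region (default 9.5–10.0 ppm); the peak-width resolution
index is the fitted FWHM in Hz. The 1.68 ppm (H-27) signal is the default
quantitative peak; H-26 at 1.62 ppm can serve alone or averaged with it.
Raw-FID processing (Fourier transform, phasing, apodization, referencing)
is out of scope — spectra enter as processed frequency-domain arrays.

## Virtual instrument (synthetic)

Each signal's area is proportional to protons × molarity ×
(1 − exp(−Tₗ/T₁)), the saturation-recovery factor for 90° observe pulses
(a documented simplification of NOESY-presaturation dynamics). Noise is
additive Gaussian with RMS = base/√NS, reproducing the √NS SNR law; the
axis carries TD/2 points across the spectral width, so small FIDs degrade
digital resolution. Linewidth narrows by 0.12 Hz/K with temperature,
giving the screening study its temperature–resolution effect.

Defaults are the study's conditions: M_DMT = 1.46 mmol/L, sample levels
0.5–9 mmol/L, SW 12.016 ppm at 500.13 MHz, operating acquisition NS 32 /
DS 4 / TD 65536 / D₁ 18.73 s. T₁ values are not published; 3.5 s (DMT
aromatic) and 1.0 s (saponin methyls) are placeholders consistent with the
choice of a 20–25 s time lag, and the base noise RMS (0.01 at NS = 1,
linewidth 0.9 Hz) is calibrated once so the operating-point SNR falls in
the 1200–1400 range characteristic of the method. The generator emulates
relaxation bias, noise averaging and digital resolution only — not
sample-preparation variability, solvent background, ¹³C satellites or
shimming artifacts — so virtual precision (RSD ≈ 0.02%) is far tighter
than wet-lab precision (≈ 0.7–1.1%), and passing round-trip tests shows
correctness of the pipeline arithmetic, not real-world performance.

## Qualification statistics (validation)

Linearity regresses prepared on measured concentration; LOD = 3σ/slope
and LOQ = 10σ/slope with σ the residual SD on n−2 degrees of freedom (the
3/10 convention is the unique pair consistent with the published
0.0794/0.2647 limits). The paired comparison uses the t distribution on
n−1 df; per-pair relative deviations take the qNMR value as denominator
and the mean relative deviation compares column means. The uncertainty
budget is the GUM root sum of squares of relative standard uncertainties
with coverage factor k = 2; component inputs must be supplied (the
published 1.21% combined value derives from supplementary data that are
not reproduced here). Specificity is a boolean check: the analyte-window
area of a negative control must stay below 1% (configurable) of the
sample's.

## Known limitations

* The screening study's published r² triple (0.644/0.705/0.787) and its
  temperature–resolution significance cannot be regenerated from the
  printed design and response tables by any least-squares or
  partial-least-squares variant examined; `fit_screening` reports the
  statistics the tables actually imply (0.823/0.769/0.776, with scan
  count and delay/FID-size flags reproduced).
* MODDE's exact uncertainty-propagation scheme and its square-column
  centering are undocumented; the Monte-Carlo scheme here is standard
  predictive simulation and is validated against its own analytic form.
* Problem sizes in the shipped analyses (64 × 64 × 10,000 maps, ≤ 200
  replicate recovery studies, 25-seed noise sweeps) are the package's
  reference scales; all are seconds-to-minutes on one CPU.
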