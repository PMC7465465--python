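# Methods

## Quantification model

The package quantifies one target compound against an isotope-labeled
internal standard (IS) from single-quadrupole SIM chromatograms. The
response factor of a compound is RF = peak area / concentration; the
relative response factor RRF = RF_analyte / RF_IS is measured on a
co-mixed dilution series and averaged with an **unweighted arithmetic
mean** across levels (the per-level values are reported, and their sample
RSD quantifies the spread; for a single level the sample RSD is undefined
and is reported as 0.0 with n recorded). The analyte level in a sample is

    conc_A = area_A · (conc_IS / area_IS) / RRF,

with units following the IS reference. Three IS bases are explicit,
because the water and air workflows differ silently in practice:

* `ng_ml_in_sample` — IS spiked into the original sample (the standard
  workflow). The result already is the in-sample concentration; losses
  and the prep concentration factor cancel. Only an aliquot dilution
  (e.g. 50× for sprayer rinses) is folded back in.
* `ng_ml_in_extract` — IS added to the final extract; the concentration
  factor CF = sample volume / residue volume is divided out.
* `ug_total` — an absolute IS amount (air samplers: 25 µL × 100 µg/mL =
  2.5 µg); the result is an absolute amount, reported as total ng.

The core property the tests exercise: any multiplicative factor acting on
both areas (ion suppression, injection variability, evaporation losses)
cancels exactly in the ratio. Suppression of the sorbent-resin + PUF
matrix (35–46 % of solvent response) therefore leaves IS-corrected
results unbiased while biasing external (area-only) calibration by the
suppression factor itself.

## Assumptions

* Analyte and IS co-elute and experience identical suppression — true for
  an isotopologue pair, the reason a labeled IS is used at all.
* The detector is linear over the working range; no saturation model.
* The D₃ label is isotopically pure and adds a fixed +3 Da to every
  channel; no D/H exchange or label scrambling.
* SIM channels are nominal integer m/z (unit-resolution quadrupole); only
  chlorine isotopologues are modeled (binomial with ³⁵Cl = 0.7576,
  ³⁷Cl = 0.2424). C/H/O isotope contributions and fine structure are out
  of scope. The exact abundances are used rather than the colloquial
  "3:1" so that pattern tests are exact; the di-chloro M : M+2 ratio is
  then 1.5627 ("3:2").

## Peak processing

Baseline and noise are estimated from a configurable **blank region**
(default 0.5–2.0 min, before the 4.4 min elution): baseline = mean
intensity, noise = sd (ddof = 1). The apex is the global maximum of the
baseline-corrected trace inside the retention window (default
4.0–4.8 min); ties break toward the earlier time; an apex ≤ 3× noise sd
is a "no peak" outcome, returned as `None`, never an exception. Areas are
trapezoidal over apex ± 4σ (default half-width 0.2 min), which keeps
> 99.99 % of a Gaussian peak; channels are integrated independently at a
shared apex (taken from the most intense quant channel) and then summed
— equivalent to summing first on a shared grid, but stated for
bit-reproducibility. S/N = apex height / blank noise sd, a common
single-quadrupole convention chosen over peak-to-peak noise for
testability. The blank region must not overlap the integration window
(configuration error).

## Synthetic data

The generator emulates the validation experiments, not a general LC–MS
instrument. Peaks are Gaussian at 4.4 min with σ = 0.05 min on a
0–13 min grid sampled every 0.01 min (matching a 13-min gradient method).
Each channel's area follows the closed form

    area = base_response · concentration · ion_fraction ·
           isotopologue_fraction · suppression,

with the fragment:precursor response split defaulting to 3:1 (the
fragment ion of dicamba is markedly more intense than the precursor; the
exact ratio is instrument-dependent and configurable) and isotopologue
fractions from the chlorine pattern. `base_response` = 100 area units
per ng/mL is an arbitrary instrument constant shared by analyte and IS
(RRF = 1 by default; `is_base_response` overrides it to test RRF ≠ 1).
Suppression is drawn uniformly per sample from the matrix band
(resin+PUF 0.35–0.46, water 0.93–1.05, solvent exactly 1) and applied
identically to analyte and IS. Noise is additive i.i.d. Gaussian on
intensity; the default sd is chosen so the lowest calibration level
(24.414 ng/mL) sits at S/N ≈ 10 on its strongest channel, tying the
simulated noise floor to the instrument LOQ. Seeding: one master seed;
per-sample generators derive from a CRC-32 hash of (seed, sample_id), so
runs are reproducible and insensitive to sample ordering.

Design presets encode the study conditions: calibration = 7 two-fold
levels from 1562.5 ng/mL × 3 replicate days; RRF series = stocks
10/5/2.5/1.25/0.625 µg/mL mixed 190 µL + 10 µL with 100 µg/mL IS (final
analyte 95 % of nominal, IS 5 µg/mL everywhere); water recovery =
0.1/1/10 ng/mL spikes (IS 0.2/1/10) in 500 mL concentrated 1000× by SPE;
air recovery = 1/5/10 ng/mL (IS 2.5/6.5/11.25) in 40 mL concentrated
80×; rinses = three groups with true concentrations near 285.6, 112.7
and 74.0 ng/mL (diluted basis, truth CV 3 %, four replicates, IS 40/20/20
ng/mL, 50× aliquot dilution); air chamber = total amounts near 700 and
4500 ng per sampler (truth CV 13 %, IS 2.5 µg absolute, 10 mL → 200 µL).
Recovery and rinse injections are simulated at the post-concentration
extract levels so simulated S/N matches what the instrument would see.

**What the generator does not emulate** — retention-time drift, peak
tailing, carryover, interfering matrix peaks, detector saturation,
sorbent mass effects, and day-to-day sensitivity drift. Passing tests
therefore demonstrate the correctness of the calculus and the internal
consistency of the isotope-dilution mechanism, not robustness of real
chromatography; recovery means near 100 % reflect an unbiased generator; real spike
recoveries show level-dependent bias the generator does not model.

## Validation calculus

* **Linearity** is fitted on raw areas vs concentration (ordinary least
  squares over all points; R² = squared Pearson correlation), matching
  the external-calibration convention for this check, with per-level RSDs
  computed across replicate days. Pass requires R² ≥ 0.990 and every
  per-level RSD ≤ 20 %.
* **LOD/LOQ** interpolate the concentration at observed S/N 3 and 10,
  linearly in log(conc) vs log(S/N) — exact when height is proportional
  to concentration over a constant noise floor. Thresholds outside the
  probed S/N range raise an error rather than extrapolate. The method
  LOD divides the instrument LOD by an **explicit** concentration
  factor; no prep-specific value is hard-coded, since the stated prep
  volumes (CF 1000 for water, 50–80 for air) and the published method
  LODs cannot be reconciled by any single CF.
* **Recovery** = measured/nominal × 100 per spike level, mean ± RSD over
  replicates.
* **Matrix effect** = 100 × matrix-matched area / solvent area;
  < 100 % suppression, > 100 % enhancement.
* **Replicate summaries** report the arithmetic mean to 1 decimal and the
  sample RSD (n−1) to the integer percent, both rounded half-up via
  decimal arithmetic — binary-float half-up would misround hand-checkable
  decimal cases such as a mean of exactly 73.95.

## Numerical choices and degenerate inputs

Trapezoidal integration on the default grid reproduces an analytic
Gaussian's area to < 0.01 %. Negative raw areas (possible under heavy
noise after baseline subtraction) clip to zero. A zero-noise trace treats
any strictly positive apex as a peak; S/N is ∞ for a positive peak on a
noiseless baseline and 0 for a flat trace. `quantify` rejects a zero IS
area with a dedicated error (a lost IS invalidates the sample) but maps a
zero analyte area to 0 with a `no_peak` flag downstream.

## Problem sizes

The test suite and the acceptance script use desk-scale runs: 100 seeded
repetitions of both recovery designs (41 injections each), 200
repetitions of the area-level linearity study, and 8 replicate
injections per point of the S/N dilution series. These sizes give
Monte-Carlo standard errors comfortably below the decision margins they
feed (pass-rate thresholds at 95 %) while keeping a full run in the
seconds-to-a-minute range.

## Known limitations

Single analyte/IS pair per batch (no multi-analyte panels); no
calibration-curve quantification path beyond the linearity check; no
mzML ingestion (long CSV is the native format; traces from other tools
can be reshaped trivially); replicate "days" are labels, not a
variance-component model.
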