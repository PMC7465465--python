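# sidquant

Stable-isotope-dilution quantification of a chlorinated analyte from
single-quadrupole **SIM LC–MS** data, built around the herbicide dicamba
and its D₃-labeled internal standard (IS).

Dicamba is moderately volatile and prone to vapor drift onto non-target
crops, so it must be monitored in air samplers and water samples (sprayer
rinses, surface water) at ng/mL levels. Triple-quadrupole MRM methods are
the usual answer; a single-quadrupole instrument in selected-ion-monitoring
(SIM) mode is far cheaper and reaches comparable sensitivity — *if* the
heavy matrix effects of sorbent-resin extracts can be corrected. This
package implements that correction and the validation calculus around it,
driven by a synthetic SIM-chromatogram generator that reproduces the
structure of the underlying validation experiments.

## The method

For an analyte *A* and a co-eluting isotope-labeled internal standard IS
spiked at a known level at the start of sample prep, the **response
factor** of each compound is RF = area / concentration, and the
**relative response factor** is

```
RRF = (area_A / conc_A) · (conc_IS / area_IS)
```

averaged over a co-mixed dilution series. One injection then quantifies
the analyte directly, with no per-batch calibration curve:

```
conc_A = area_A · (conc_IS / area_IS) · (1 / RRF)
```

Because ion suppression in the ESI source scales the analyte and IS areas
by the same factor, it cancels exactly in the ratio — the package
demonstrates this quantitatively for the 35–46 % suppression band of
sorbent-resin + polyurethane-foam (PUF) extracts.

Supporting machinery:

* **Isotope model** — binomial ³⁵Cl/³⁷Cl isotopologue patterns
  (M : M+2 ≈ 3 : 2 for two chlorines) and SIM channel derivation: quant
  channels m/z 175 + 219 (fragment + precursor) for dicamba,
  178 + 222 for the D₃ IS, with the M+2 ions as confirmation channels.
* **Peak processing** — blank-region baseline/noise estimation, windowed
  apex detection, trapezoidal integration, summed fragment+precursor
  quantification areas, S/N = apex height / blank noise sd.
* **Validation calculus** — linearity (R² ≥ 0.990, per-level RSD ≤ 20 %),
  LOD/LOQ at observed S/N 3 and 10 with method-LOD propagation through
  the prep concentration factor, spike recovery, percent matrix effect,
  and replicate summaries with report-table rounding.
* **Sample-prep back-calculation** — SPE concentration factors
  (500 mL → 500 µL), aliquot dilutions (50× rinses), and absolute-amount
  (total ng per air sampler) reporting.
* **Synthetic data** — seeded generator for the calibration series
  (7 two-fold levels from 1562.5 ng/mL), the RRF series
  (10→0.625 µg/mL mixed 190 µL + 10 µL with IS), water/air recovery
  designs, paired matrix-effect injections, sprayer-rinse replicates and
  vapor-chamber air samplers, each with a ground-truth manifest.

## Worked example

`examples/suppression_cancellation.py` calibrates an RRF from a noise-free
co-mixed series and quantifies a 5 ng/mL sample under resin+PUF-level ion
suppression, with and without the IS:

```
suppression  IS-corrected  external-only  (true = 5.00 ng/mL)
   0.350         5.000         1.750
   0.378         5.000         1.887
   0.405         5.000         2.025
   0.432         5.000         2.162
   0.460         5.000         2.300
```

The IS-corrected result recovers the true concentration at every
suppression level; external (area-only) calibration reads low by exactly
the suppression factor. The other examples cover isotope-pattern/channel
derivation (`isotope_channels.py`), the full rinse workflow with 50×
back-dilution (`simulate_and_quantify.py`), the complete validation study
(`method_validation.py`), and air-sampler totals with chamber turnover
arithmetic (`air_chamber.py`).

A thin CLI wraps the same pipeline for batch use:

```
sidquant simulate --design rrf_series --seed 1 --out-dir rrf
sidquant rrf --chromatograms rrf/chromatograms.csv \
             --samplesheet rrf/sample_sheet.csv --out rrf.json
sidquant quantify --chromatograms batch.csv --samplesheet sheet.csv \
                  --rrf rrf.json --out results.csv
```

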