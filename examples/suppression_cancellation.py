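"""Why the isotope-labeled internal standard is required.

Sorbent resin + PUF extract suppresses ionization to 35-46% of the
solvent response. Because analyte and IS are suppressed identically,
their area ratio -- and hence the RRF-based result -- is unchanged, while
external (area-only) calibration is biased by the suppression factor.
"""

import numpy as np

import sidquant as sq

config = sq.PipelineConfig()
rrf_out = sq.generate_design(sq.design_defaults("rrf_series", noise_sd=0.0))
areas = sq.measure_areas(config, rrf_out.chromatograms)
merged = rrf_out.sample_sheet.merge(areas, on="sample_id")
cal = sq.compute_rrf(
    (r.nominal_analyte, r.analyte_area, r.is_reference, r.is_area)
    for r in merged.itertuples()
)
slope = sq.closed_form_quant_area(1.0, sq.DICAMBA)

true_conc = 5.0
print("suppression  IS-corrected  external-only  (true = 5.00 ng/mL)")
for s in np.linspace(0.35, 0.46, 5):
    chrom = sq.simulate_injection(true_conc, 5.0, suppression=float(s),
                                  noise_sd=0.0)
    a = sq.summed_quant_area(chrom, sq.DICAMBA).area
    b = sq.summed_quant_area(chrom, sq.D3_DICAMBA).area
    corrected = sq.quantify(a, b, 5.0, cal.rrf_mean)
    external = sq.external_quantify(a, slope)
    print(f"   {s:.3f}       {corrected:7.3f}       {external:7.3f}")
# The IS-corrected column recovers 5.00 at every suppression level; the
# external column reads ~ 5 x suppression, i.e. a 54-65% underestimate.
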