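import numpy as np
import pandas as pd
import pytest

import sidquant as sq


@pytest.fixture(scope="session")
def config():
    return sq.PipelineConfig()


@pytest.fixture(scope="session")
def clean_injection():
    """Noise-free injection: analyte 10 ng/mL, IS 5 ng/mL, no suppression."""
    return sq.simulate_injection(10.0, 5.0, noise_sd=0.0, sample_id="clean")


@pytest.fixture()
def rrf_batch():
    """Noise-free RRF series batch: chromatograms + sheet + calibration."""
    out = sq.generate_design(sq.design_defaults("rrf_series", noise_sd=0.0))
    return out


def measure_rrf(config, design_output):
    """Helper: averaged RRF from a generated rrf_series batch."""
    areas = sq.measure_areas(config, design_output.chromatograms)
    merged = design_output.sample_sheet.merge(areas, on="sample_id")
    series = [
        (r.nominal_analyte, r.analyte_area, r.is_reference, r.is_area)
        for r in merged.itertuples()
    ]
    return sq.compute_rrf(series)


@pytest.fixture()
def toy_chromatogram():
    """Hand-built two-channel trace with a clean triangular peak at 4.4."""
    t = np.arange(0.0, 13.0 + 1e-9, 0.01)
    peak = np.zeros_like(t)
    apex = int(round(4.4 / 0.01))
    peak[apex - 2 : apex + 3] = [1.0, 5.0, 10.0, 5.0, 1.0]
    return sq.SIMChromatogram(
        sample_id="toy", time=t, channels={175.0: peak, 219.0: 0.5 * peak}
    )
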