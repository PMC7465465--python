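"""Synthetic SIM chromatogram generator and experiment designs."""

import numpy as np
import pandas as pd
import pytest

import sidquant as sq
from sidquant.simulate import (
    CALIBRATION_LEVELS,
    channel_weights,
    closed_form_channel_areas,
    gaussian_truncation_fraction,
    rrf_series_mix,
)


def test_empty_sample_is_flat_zero():
    chrom = sq.simulate_injection(0.0, 0.0, noise_sd=0.0)
    for trace in chrom.channels.values():
        assert np.all(trace == 0.0)


def test_symmetric_compounds_give_equal_summed_areas():
    chrom = sq.simulate_injection(3.0, 3.0, suppression=0.8, noise_sd=0.0)
    a = sq.summed_quant_area(chrom, sq.DICAMBA)
    b = sq.summed_quant_area(chrom, sq.D3_DICAMBA)
    assert a.area == pytest.approx(b.area, rel=1e-12)


def test_area_ratio_is_concentration_ratio_times_rrf(clean_injection):
    a = sq.summed_quant_area(clean_injection, sq.DICAMBA)
    b = sq.summed_quant_area(clean_injection, sq.D3_DICAMBA)
    # equal base responses: RRF = 1, so ratio = 10/5 = 2
    assert a.area / b.area == pytest.approx(2.0, rel=1e-9)


def test_rrf_differs_from_one_when_is_response_overridden():
    model = sq.InstrumentModel(base_response=100.0, is_base_response=50.0)
    chrom = sq.simulate_injection(5.0, 5.0, noise_sd=0.0, model=model)
    a = sq.summed_quant_area(chrom, sq.DICAMBA)
    b = sq.summed_quant_area(chrom, sq.D3_DICAMBA)
    assert a.area / b.area == pytest.approx(2.0, rel=1e-9)


def test_integrated_areas_match_closed_form_within_0p1_percent():
    chrom = sq.simulate_injection(50.0, 20.0, suppression=0.7, noise_sd=0.0)
    for spec, conc in ((sq.DICAMBA, 50.0), (sq.D3_DICAMBA, 20.0)):
        expected = closed_form_channel_areas(conc, spec, suppression=0.7)
        for mz in spec.quant_channels:
            apex = sq.detect_peak(chrom, mz)
            peak = sq.integrate_peak(chrom, mz, apex)
            assert peak.area == pytest.approx(expected[mz], rel=1e-3)


def test_fragment_channel_more_intense_than_precursor(clean_injection):
    frag = clean_injection.channels[175].max()
    prec = clean_injection.channels[219].max()
    assert frag == pytest.approx(3 * prec, rel=1e-9)


def test_confirm_channels_follow_isotopologue_proportions(clean_injection):
    pattern = sq.chlorine_pattern(2)
    ratio = clean_injection.channels[175].max() / clean_injection.channels[177].max()
    assert ratio == pytest.approx(pattern.m_mplus2_ratio, rel=1e-9)


def test_suppression_scales_both_compounds_identically():
    """The area ratio is invariant to suppression (noise-free)."""
    ratios = []
    for s in (0.35, 0.46, 1.0):
        chrom = sq.simulate_injection(8.0, 4.0, suppression=s, noise_sd=0.0)
        a = sq.summed_quant_area(chrom, sq.DICAMBA)
        b = sq.summed_quant_area(chrom, sq.D3_DICAMBA)
        ratios.append(a.area / b.area)
    assert max(ratios) - min(ratios) < 1e-9


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        sq.simulate_injection(-1.0, 0.0)
    with pytest.raises(ValueError):
        sq.simulate_injection(1.0, 1.0, suppression=0.0)
    with pytest.raises(ValueError):
        sq.simulate_injection(1.0, 1.0, noise_sd=-1.0)


def test_calibration_series_is_twofold_from_1562p5():
    design = sq.design_defaults("calibration")
    assert design.levels == pytest.approx(
        [1562.5, 781.25, 390.625, 195.3125, 97.65625, 48.828125, 24.4140625]
    )
    assert CALIBRATION_LEVELS[0] / CALIBRATION_LEVELS[-1] == pytest.approx(64)


def test_rrf_series_mixing_arithmetic():
    """190 uL analyte + 10 uL of 100 ug/mL IS -> 0.95x nominal, IS 5 ug/mL."""
    analyte, is_conc = rrf_series_mix()
    assert is_conc == pytest.approx(5000.0)
    stocks_ng = [10000.0, 5000.0, 2500.0, 1250.0, 625.0]
    assert analyte == pytest.approx([0.95 * c for c in stocks_ng])
    assert analyte == pytest.approx([9500.0, 4750.0, 2375.0, 1187.5, 593.75])


def test_recovery_designs_reproduce_level_pairings():
    water = sq.design_defaults("recovery_water")
    assert water.levels == [0.1, 1.0, 10.0]
    assert water.is_levels == [0.2, 1.0, 10.0]
    assert water.concentration_factor == pytest.approx(1000.0)
    air = sq.design_defaults("recovery_air")
    assert air.levels == [1.0, 5.0, 10.0]
    assert air.is_levels == [2.5, 6.5, 11.25]
    assert air.concentration_factor == pytest.approx(80.0)


def test_unknown_design_kind_rejected():
    with pytest.raises(ValueError):
        sq.design_defaults("nope")


def test_generation_is_deterministic_under_fixed_seed():
    a = sq.generate_design(sq.design_defaults("recovery_water", seed=11))
    b = sq.generate_design(sq.design_defaults("recovery_water", seed=11))
    assert a.manifest == b.manifest
    pd.testing.assert_frame_equal(a.sample_sheet, b.sample_sheet)
    for ca, cb in zip(a.chromatograms, b.chromatograms):
        assert ca.sample_id == cb.sample_id
        for mz in ca.channels:
            np.testing.assert_array_equal(ca.channels[mz], cb.channels[mz])


def test_manifest_and_sample_sheet_are_consistent():
    out = sq.generate_design(sq.design_defaults("rinse", seed=4))
    sheet_ids = list(out.sample_sheet["sample_id"])
    manifest_ids = [s["sample_id"] for s in out.manifest["samples"]]
    assert sheet_ids == manifest_ids
    assert len(set(sheet_ids)) == len(sheet_ids)
    assert len(out.chromatograms) == len(sheet_ids)


def test_matrix_effect_design_emits_paired_injections():
    out = sq.generate_design(sq.design_defaults("matrix_effect", seed=1))
    sheet = out.sample_sheet
    solvent = sheet[sheet["matrix"] == "solvent"]
    matrix = sheet[sheet["matrix"] == "resin_puf"]
    assert len(solvent) == len(matrix) == 3
    # identical nominal concentrations within each pair
    assert set(solvent["nominal_analyte"]) == set(matrix["nominal_analyte"])


def test_default_noise_puts_lowest_calibration_level_at_loq():
    """Noise floor calibrated so 24.4 ng/mL reaches S/N ~ 10."""
    noise = sq.default_noise_sd()
    model = sq.DEFAULT_INSTRUMENT
    w = max(channel_weights(sq.DICAMBA, model).values())
    height = (
        model.base_response
        * CALIBRATION_LEVELS[-1]
        * w
        / (model.peak_sigma_min * np.sqrt(2 * np.pi))
    )
    assert height / noise == pytest.approx(10.0, rel=1e-12)


def test_truncation_fraction_of_default_window():
    # 4 sigma window keeps > 99.99% of the Gaussian peak area
    assert gaussian_truncation_fraction(0.2, 0.05) > 0.9999
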