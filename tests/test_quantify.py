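"""RRF calculus, direct quantification, and prep back-calculation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sidquant as sq
from sidquant.errors import ConfigurationError, InternalStandardError
from sidquant.quantify import SamplePrepFactors

from conftest import measure_rrf


class TestComputeRRF:
    def test_equal_responses_give_unit_rrf(self):
        cal = sq.compute_rrf([(10, 1000, 5, 500)])
        lv = cal.per_level[0]
        assert lv.rf_analyte == pytest.approx(100.0)
        assert lv.rf_is == pytest.approx(100.0)
        assert cal.rrf_mean == pytest.approx(1.0)
        assert cal.rrf_rsd == 0.0

    def test_doubled_analyte_response_gives_rrf_two(self):
        cal = sq.compute_rrf([(10, 2000, 5, 500)])
        assert cal.rrf_mean == pytest.approx(2.0)

    def test_noise_free_series_has_zero_rsd(self, config, rrf_batch):
        cal = measure_rrf(config, rrf_batch)
        rrfs = [lv.rrf for lv in cal.per_level]
        assert len(rrfs) == 5
        assert max(rrfs) - min(rrfs) < 1e-9
        assert cal.rrf_rsd < 1e-7
        assert cal.rrf_mean == pytest.approx(1.0, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            sq.compute_rrf([(10, 0, 5, 500)])
        with pytest.raises(ValueError):
            sq.compute_rrf([])


class TestQuantify:
    def test_direct_substitution(self):
        assert sq.quantify(800, 500, 5, 1.0) == pytest.approx(8.0)

    def test_rinse_scale_arithmetic(self):
        # IS at 200 uL x 100 ug/mL in 500 mL = 40 ng/mL in-sample
        assert sq.quantify(7140, 1000, 40, 1.0) == pytest.approx(285.6)

    def test_zero_analyte_area_gives_zero(self):
        assert sq.quantify(0.0, 500, 5, 1.0) == 0.0

    def test_lost_internal_standard_is_an_error(self):
        with pytest.raises(InternalStandardError):
            sq.quantify(800, 0.0, 5, 1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        k=st.floats(min_value=1e-3, max_value=1e3),
        area_a=st.floats(min_value=1e-6, max_value=1e6),
        area_is=st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_homogeneous_in_joint_area_scaling(self, k, area_a, area_is):
        """Scaling both areas by k leaves the result unchanged: this is
        exactly how ion suppression cancels."""
        base = sq.quantify(area_a, area_is, 5.0, 1.3)
        scaled = sq.quantify(k * area_a, k * area_is, 5.0, 1.3)
        assert scaled == pytest.approx(base, rel=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        k=st.floats(min_value=1e-3, max_value=1e3),
        area_a=st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_linear_in_analyte_area(self, k, area_a):
        base = sq.quantify(area_a, 400.0, 5.0, 0.8)
        assert sq.quantify(k * area_a, 400.0, 5.0, 0.8) == pytest.approx(
            k * base, rel=1e-9
        )

    def test_calibration_levels_round_trip(self, config, rrf_batch):
        """RRF fit then quantification reproduces each level's nominal."""
        cal = measure_rrf(config, rrf_batch)
        for lv in cal.per_level:
            got = sq.quantify(
                lv.analyte_area, lv.is_area, lv.is_conc, cal.rrf_mean
            )
            assert got == pytest.approx(lv.analyte_conc, rel=1e-9)


class TestBackCalculate:
    def test_rinse_dilution_restores_undiluted_concentration(self):
        prep = SamplePrepFactors(
            sample_volume_ml=500, residue_volume_ml=0.5, aliquot_dilution=50
        )
        res = sq.back_calculate(285.6, prep)
        assert res.conc_analyte == pytest.approx(14280.0)  # ~14.3 ug/mL

    def test_spe_concentration_factor(self):
        prep = SamplePrepFactors(sample_volume_ml=500, residue_volume_ml=0.5)
        assert prep.concentration_factor == pytest.approx(1000.0)

    def test_in_extract_is_reference_divides_by_cf(self):
        prep = SamplePrepFactors(
            sample_volume_ml=500,
            residue_volume_ml=0.5,
            is_basis="ng_ml_in_extract",
        )
        res = sq.back_calculate(1000.0, prep)
        assert res.conc_analyte == pytest.approx(1.0)

    def test_absolute_is_amount_reports_total_nanograms(self):
        prep = SamplePrepFactors(
            sample_volume_ml=10,
            residue_volume_ml=0.2,
            is_basis="ug_total",
            reporting_basis="total_amount",
        )
        # area ratio 1, RRF 1, IS 2.5 ug total -> 2.5 ug = 2500 ng analyte
        value = sq.quantify(1000.0, 1000.0, 2.5, 1.0)
        res = sq.back_calculate(value, prep)
        assert res.total_amount == pytest.approx(2500.0)
        assert res.conc_analyte is None

    def test_basis_mismatch_rejected(self):
        prep_kwargs = dict(
            sample_volume_ml=10, residue_volume_ml=0.2, is_basis="ug_total"
        )
        prep = SamplePrepFactors(**prep_kwargs)  # default conc_in_sample
        with pytest.raises(ConfigurationError):
            sq.back_calculate(1.0, prep)

    def test_zero_value_flags_no_peak(self):
        prep = SamplePrepFactors(sample_volume_ml=500, residue_volume_ml=0.5)
        assert "no_peak" in sq.back_calculate(0.0, prep).flags

    def test_lod_loq_flags(self):
        prep = SamplePrepFactors(sample_volume_ml=500, residue_volume_ml=0.5)
        res = sq.back_calculate(
            0.05, prep, method_lod=0.1, method_loq=0.3
        )
        # reported conc = 0.05 (dilution 1): below both thresholds
        assert {"below_lod", "below_loq"} <= res.flags


class TestAirSamplingSummary:
    def test_chamber_turnover_is_twenty_minutes(self):
        turnover, total = sq.air_sampling_summary(6.2, 310.0, 48.0)
        assert turnover == pytest.approx(20.0)
        assert total == pytest.approx(892.8)

    def test_unit_case(self):
        turnover, _ = sq.air_sampling_summary(1.0, 1000.0, 1.0)
        assert turnover == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sq.air_sampling_summary(0, 310, 48)


@pytest.mark.parametrize("suppression", [0.3, 0.35, 0.46, 0.7, 1.0, 1.1])
def test_round_trip_recovery_under_any_suppression(config, suppression):
    """Core claim: IS-corrected quantification is exact under suppression.

    Noise-free synthetic sample at any suppression in [0.3, 1.1] quantifies
    back to the generator's true concentration to < 0.5% relative error.
    """
    rrf_out = sq.generate_design(sq.design_defaults("rrf_series", noise_sd=0.0))
    cal = measure_rrf(config, rrf_out)
    true_conc, is_conc = 7.5, 5.0
    chrom = sq.simulate_injection(
        true_conc, is_conc, suppression=suppression, noise_sd=0.0
    )
    a = sq.summed_quant_area(chrom, sq.DICAMBA).area
    b = sq.summed_quant_area(chrom, sq.D3_DICAMBA).area
    got = sq.quantify(a, b, is_conc, cal.rrf_mean)
    assert got == pytest.approx(true_conc, rel=5e-3)


def test_external_quantification_inherits_suppression(config):
    """Without the IS the measurement is biased by the suppression factor."""
    slope = sq.closed_form_quant_area(1.0, sq.DICAMBA)  # area per ng/mL
    s = 0.4
    chrom = sq.simulate_injection(10.0, 0.0, suppression=s, noise_sd=0.0)
    area = sq.summed_quant_area(chrom, sq.DICAMBA).area
    got = sq.external_quantify(area, slope)
    assert got / 10.0 == pytest.approx(s, rel=1e-3)
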