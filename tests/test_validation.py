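"""Method-performance calculus: linearity, LOD/LOQ, recovery, matrix effect."""

import numpy as np
import pandas as pd
import pytest

import sidquant as sq
from sidquant.errors import ExtrapolationError
from sidquant.validation import round_half_up


class TestLinearity:
    def test_noise_free_calibration_is_perfectly_linear(self):
        df = sq.simulate_calibration_areas(area_cv=0.0, seed=0)
        res = sq.assess_linearity(df)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.passed
        assert all(rsd == pytest.approx(0.0) for rsd in res.per_level_rsd.values())

    def test_acceptance_boundary_monte_carlo(self):
        """5% multiplicative area noise, 3 days: R2 >= 0.990 nearly always."""
        passes = sum(
            sq.assess_linearity(
                sq.simulate_calibration_areas(area_cv=0.05, seed=s)
            ).r_squared
            >= 0.990
            for s in range(200)
        )
        assert passes >= 190

    def test_excessive_level_rsd_fails_the_rule(self):
        df = sq.simulate_calibration_areas(area_cv=0.0, seed=0)
        # corrupt one level's replicates to ~30% RSD
        lvl = df["concentration"].iloc[0]
        idx = df.index[df["concentration"] == lvl]
        df.loc[idx, "area"] = df.loc[idx, "area"] * np.array([1.0, 1.4, 0.6])
        res = sq.assess_linearity(df)
        assert max(res.per_level_rsd.values()) > 20
        assert not res.passed

    def test_single_concentration_rejected(self):
        df = pd.DataFrame(
            {"concentration": [1.0, 1.0], "area": [5.0, 6.0],
             "day_label": ["day1", "day2"]}
        )
        with pytest.raises(ValueError):
            sq.assess_linearity(df)


class TestLodLoq:
    def test_closed_form_noise_model(self):
        """With height = k*conc over noise sd sigma, LOD ~ 3 sigma / k."""
        rng = np.random.default_rng(0)
        sigma, k = 5.0, 12.0
        lods = []
        for _ in range(100):
            concs = np.geomspace(0.5, 50, 8)
            snr = k * concs / sigma * (1 + 0.02 * rng.standard_normal(8))
            snr = np.sort(snr)
            res = sq.estimate_lod_loq(zip(np.sort(concs), snr))
            lods.append(res.instrument_lod)
        assert np.mean(lods) == pytest.approx(3 * sigma / k, rel=0.10)

    def test_method_lod_divides_by_concentration_factor(self):
        res = sq.estimate_lod_loq(
            [(3, 1), (9, 3), (30, 10), (90, 30)], concentration_factor=90.0
        )
        assert res.instrument_lod == pytest.approx(9.0)
        assert res.method_lod == pytest.approx(0.1)

    def test_loq_lod_ratio_in_linear_noise_free_model(self):
        res = sq.estimate_lod_loq([(1, 1), (100, 100)])
        assert res.instrument_loq / res.instrument_lod == pytest.approx(
            10.0 / 3.0
        )

    def test_threshold_outside_probed_range_raises(self):
        with pytest.raises(ExtrapolationError):
            sq.estimate_lod_loq([(10, 5), (100, 50)], thresholds=(3, 10))
        with pytest.raises(ExtrapolationError):
            sq.estimate_lod_loq([(1, 0.1), (10, 1)], thresholds=(3, 10))


class TestRecovery:
    def test_recovery_percentages(self):
        df = pd.DataFrame(
            {"nominal": [0.1, 1.0], "measured": [0.128, 1.0]}
        )
        res = {r.level: r for r in sq.compute_recovery(df)}
        assert res[0.1].mean_recovery == pytest.approx(128.0)
        assert res[1.0].mean_recovery == pytest.approx(100.0)

    def test_missing_nominal_rejected(self):
        df = pd.DataFrame({"nominal": [np.nan], "measured": [1.0]})
        with pytest.raises(ValueError):
            sq.compute_recovery(df)


class TestMatrixEffect:
    @pytest.mark.parametrize(
        "matrix, solvent, effect, interp",
        [
            (40, 100, 40.0, "suppression"),  # resin+PUF band
            (100, 100, 100.0, "none"),
            (105, 100, 105.0, "enhancement"),  # water band upper edge
        ],
    )
    def test_effect_and_interpretation(self, matrix, solvent, effect, interp):
        res = sq.compute_matrix_effect(matrix, solvent)
        assert res.effect == pytest.approx(effect)
        assert res.interpretation == interp

    def test_zero_solvent_area_rejected(self):
        with pytest.raises(ValueError):
            sq.compute_matrix_effect(10, 0)

    def test_synthetic_pairs_recover_suppression_factor(self):
        """Matrix effect of simulated pairs ~ 100 x suppression factor."""
        for s in (0.35, 0.46, 1.0):
            solvent = sq.simulate_injection(100.0, 0.0, noise_sd=0.0)
            matrix = sq.simulate_injection(
                100.0, 0.0, suppression=s, noise_sd=0.0
            )
            a_m = sq.summed_quant_area(matrix, sq.DICAMBA).area
            a_s = sq.summed_quant_area(solvent, sq.DICAMBA).area
            assert sq.compute_matrix_effect(a_m, a_s).effect == pytest.approx(
                100 * s, rel=1e-6
            )


class TestReplicateSummary:
    @pytest.mark.parametrize(
        "values, mean, rsd",
        [
            ([296.5, 278.0, 293.7, 274.1], 285.6, 4),
            ([115.1, 111.9, 114.1, 109.5], 112.7, 2),
            ([76.8, 72.1, 70.6, 76.3], 74.0, 4),
        ],
    )
    def test_report_table_statistics(self, values, mean, rsd):
        s = sq.summarize_replicates(values)
        assert s.mean_rounded == mean
        assert s.rsd_rounded == rsd

    def test_identical_replicates_have_zero_rsd(self):
        s = sq.summarize_replicates([5.0, 5.0, 5.0, 5.0])
        assert s.mean_rounded == 5.0
        assert s.rsd == 0.0

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            sq.summarize_replicates([1.0])


def test_half_up_rounding_convention():
    assert round_half_up(112.65, 1) == 112.7
    assert round_half_up(3.5, 0) == 4.0
    assert round_half_up(4.15, 1) == 4.2


def test_is_corrected_recovery_invariant_to_suppression(config):
    """IS correction makes recovery exactly 100% at any suppression, while
    area-only (external) recovery degrades to ~ 100 x suppression."""
    slope = sq.closed_form_quant_area(1.0, sq.DICAMBA)
    for s in (0.35, 0.46, 0.93, 1.05):
        chrom = sq.simulate_injection(4.0, 2.0, suppression=s, noise_sd=0.0)
        a = sq.summed_quant_area(chrom, sq.DICAMBA).area
        b = sq.summed_quant_area(chrom, sq.D3_DICAMBA).area
        corrected = sq.quantify(a, b, 2.0, 1.0)
        uncorrected = sq.external_quantify(a, slope)
        assert corrected / 4.0 * 100 == pytest.approx(100.0, abs=1e-6)
        assert uncorrected / 4.0 * 100 == pytest.approx(100 * s, rel=1e-3)
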