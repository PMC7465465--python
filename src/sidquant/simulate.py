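"""Synthetic SIM chromatograms with the structure of the validation studies.

The generator emulates a single-quadrupole SIM acquisition of a
di-chlorinated analyte and its deuterated internal standard (IS):

* Gaussian elution at 4.4 min (sigma 0.05 min) on a 0-13 min gradient
  sampled every 0.01 min;
* four analyte channels (fragment/precursor and their +2 isotopologues,
  m/z 175/177/219/221 for dicamba) and the corresponding IS channels
  (178/180/222/224), with the chlorine isotopologue proportions from
  :func:`sidquant.isotopes.chlorine_pattern`;
* an in-source fragment more intense than the precursor (default 3:1
  fragment:precursor response split);
* multiplicative ion suppression applied identically to analyte and IS
  (the physical basis of isotope-dilution matrix correction);
* additive i.i.d. Gaussian baseline noise.

The closed-form channel area is ``base_response * concentration *
channel_weight * suppression`` with ``channel_weight = ion_fraction *
isotopologue_fraction``; the Gaussian trace integrates to that area, which
is what makes round-trip tests against the processing module exact.

``generate_design`` builds whole experiments -- calibration series, RRF
series, spike-recovery designs for water and air, paired matrix-effect
injections, sprayer-rinse replicates, and vapor-chamber air samplers --
together with a sample sheet and a ground-truth manifest.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from math import erf, sqrt

import numpy as np
import pandas as pd

from .chromatograms import SIMChromatogram
from .isotopes import D3_DICAMBA, DICAMBA, CompoundIonSpec

__all__ = [
    "InstrumentModel",
    "DEFAULT_INSTRUMENT",
    "SimulationDesign",
    "DesignOutput",
    "default_noise_sd",
    "channel_weights",
    "closed_form_channel_areas",
    "closed_form_quant_area",
    "simulate_injection",
    "simulate_calibration_areas",
    "design_defaults",
    "generate_design",
    "CALIBRATION_LEVELS",
    "RRF_SERIES_STOCKS_UG_ML",
    "rrf_series_mix",
    "WATER_SUPPRESSION",
    "RESIN_PUF_SUPPRESSION",
]

#: 7-level two-fold calibration series, 1562.5 down to ~24.4 ng/mL.
CALIBRATION_LEVELS: tuple[float, ...] = tuple(1562.5 / 2**k for k in range(7))

#: RRF dilution series stocks (ug/mL) before mixing with the IS solution.
RRF_SERIES_STOCKS_UG_ML: tuple[float, ...] = (10.0, 5.0, 2.5, 1.25, 0.625)

#: Ion-suppression bands observed for the two sample matrices.
WATER_SUPPRESSION: tuple[float, float] = (0.93, 1.05)
RESIN_PUF_SUPPRESSION: tuple[float, float] = (0.35, 0.46)

_SUPPRESSION_BY_MATRIX = {
    "solvent": (1.0, 1.0),
    "water": WATER_SUPPRESSION,
    "resin_puf": RESIN_PUF_SUPPRESSION,
}


@dataclass(frozen=True)
class InstrumentModel:
    """Response and peak-shape model of the simulated instrument.

    ``base_response`` is the summed-area response in intensity*min per
    ng/mL per unit channel weight; it is a single arbitrary instrument
    constant shared by analyte and IS unless ``is_base_response`` is set
    (making the true relative response factor differ from 1).
    """

    base_response: float = 100.0
    is_base_response: float | None = None
    rt_min: float = 4.4
    peak_sigma_min: float = 0.05
    t_start: float = 0.0
    t_end: float = 13.0
    dt: float = 0.01
    fragment_fraction: float = 0.75  # 3:1 fragment:precursor split
    include_confirm_channels: bool = True

    def time_grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt)) + 1
        return self.t_start + self.dt * np.arange(n)

    @property
    def is_response(self) -> float:
        return (
            self.base_response
            if self.is_base_response is None
            else self.is_base_response
        )


DEFAULT_INSTRUMENT = InstrumentModel()


def default_noise_sd(
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    snr: float = 10.0,
    conc: float = CALIBRATION_LEVELS[-1],
) -> float:
    """Baseline noise sd putting the lowest calibration level at S/N ~ snr.

    Ties the simulated noise floor to the instrument LOQ: by default the
    24.4 ng/mL standard reaches S/N 10 on its strongest channel.
    """
    weights = channel_weights(DICAMBA, model)
    w = max(weights.values())
    height = model.base_response * conc * w / (
        model.peak_sigma_min * sqrt(2.0 * np.pi)
    )
    return height / snr


def channel_weights(
    spec: CompoundIonSpec, model: InstrumentModel = DEFAULT_INSTRUMENT
) -> dict[float, float]:
    """Fraction of a compound's total response landing on each channel.

    The response splits between fragment and precursor ions by
    ``fragment_fraction`` and across isotopologues by the chlorine
    pattern; only the monitored (M and optionally M+2) channels appear.
    """
    pattern = spec.isotope_pattern
    p0 = pattern.probability(0)
    shift = spec.label_shift
    weights = {
        spec.fragment_mz + shift: model.fragment_fraction * p0,
        spec.precursor_mz + shift: (1.0 - model.fragment_fraction) * p0,
    }
    if model.include_confirm_channels and spec.n_chlorines >= 1:
        p2 = pattern.probability(2)
        weights[spec.fragment_mz + 2 + shift] = model.fragment_fraction * p2
        weights[spec.precursor_mz + 2 + shift] = (
            1.0 - model.fragment_fraction
        ) * p2
    return weights


def closed_form_channel_areas(
    conc: float,
    spec: CompoundIonSpec,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    suppression: float = 1.0,
    base_response: float | None = None,
) -> dict[float, float]:
    """Noise-free per-channel areas of the response model (intensity*min)."""
    base = model.base_response if base_response is None else base_response
    return {
        mz: base * conc * w * suppression
        for mz, w in channel_weights(spec, model).items()
    }


def closed_form_quant_area(
    conc: float,
    spec: CompoundIonSpec,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    suppression: float = 1.0,
    base_response: float | None = None,
) -> float:
    """Noise-free summed fragment+precursor quantification area."""
    areas = closed_form_channel_areas(
        conc, spec, model, suppression, base_response
    )
    return sum(areas[mz] for mz in spec.quant_channels)


def gaussian_truncation_fraction(
    halfwidth: float, sigma: float
) -> float:
    """Fraction of a Gaussian peak's area inside apex +/- halfwidth."""
    return erf(halfwidth / (sigma * sqrt(2.0)))


def _gaussian(t: np.ndarray, area: float, rt: float, sigma: float) -> np.ndarray:
    return (
        area
        / (sigma * sqrt(2.0 * np.pi))
        * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
    )


def simulate_injection(
    true_analyte_conc: float,
    true_is_conc: float,
    analyte_spec: CompoundIonSpec = DICAMBA,
    is_spec: CompoundIonSpec = D3_DICAMBA,
    *,
    suppression: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    sample_id: str = "sample",
) -> SIMChromatogram:
    """Simulate one SIM injection of analyte plus internal standard.

    Every monitored channel carries a Gaussian peak whose area follows the
    closed-form response model, scaled by one shared ``suppression``
    factor (ion suppression acts at the source, so analyte and IS are
    suppressed identically), plus additive Gaussian baseline noise.
    Channels shared between the two compounds accumulate both signals.
    """
    if true_analyte_conc < 0 or true_is_conc < 0:
        raise ValueError("concentrations must be non-negative")
    if suppression <= 0:
        raise ValueError("suppression must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = model.time_grid()
    areas: dict[float, float] = {}
    for conc, spec, base in (
        (true_analyte_conc, analyte_spec, model.base_response),
        (true_is_conc, is_spec, model.is_response),
    ):
        for mz, a in closed_form_channel_areas(
            conc, spec, model, suppression, base_response=base
        ).items():
            areas[mz] = areas.get(mz, 0.0) + a
    if rng is None:
        rng = np.random.default_rng(seed)
    channels: dict[float, np.ndarray] = {}
    for mz in sorted(areas):
        trace = _gaussian(t, areas[mz], model.rt_min, model.peak_sigma_min)
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd, size=t.shape)
        channels[mz] = trace
    return SIMChromatogram(sample_id=sample_id, time=t, channels=channels)


def rrf_series_mix(
    stocks_ug_ml: tuple[float, ...] = RRF_SERIES_STOCKS_UG_ML,
    analyte_volume_ul: float = 190.0,
    is_volume_ul: float = 10.0,
    is_stock_ug_ml: float = 100.0,
) -> tuple[list[float], float]:
    """Final concentrations (ng/mL) after co-mixing analyte and IS.

    Mixing 190 uL of each analyte dilution with 10 uL of the 100 ug/mL IS
    solution dilutes the analyte to 95% of nominal and fixes the IS at
    5 ug/mL in every level.
    """
    total = analyte_volume_ul + is_volume_ul
    analyte = [
        1000.0 * c * analyte_volume_ul / total for c in stocks_ug_ml
    ]
    is_conc = 1000.0 * is_stock_ug_ml * is_volume_ul / total
    return analyte, is_conc


@dataclass
class SimulationDesign:
    """Parameters of one simulated experiment.

    ``levels`` / ``is_levels`` are nominal analyte and IS values in the
    design's reporting basis (ng/mL in-sample, or ng total for air
    samplers); ``concentration_factor`` maps them to in-extract
    concentrations actually injected. ``truth_cv`` adds between-replicate
    biological/process variation to the true values (rinse and chamber
    designs), as a relative sd.
    """

    design_kind: str
    levels: list[float]
    is_levels: list[float]
    matrix: str = "solvent"
    suppression_range: tuple[float, float] = (1.0, 1.0)
    noise_sd: float | None = None
    replicates: int = 1
    seed: int = 0
    concentration_factor: float = 1.0
    aliquot_dilution: float = 1.0
    sample_volume_ml: float = 1.0
    residue_volume_ml: float = 1.0
    is_basis: str = "ng_ml_in_sample"
    sample_type: str = "unknown"
    group_labels: list[str] | None = None
    truth_cv: float = 0.0

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.is_levels):
            raise ValueError("levels and is_levels must have equal length")
        lo, hi = self.suppression_range
        if not (0 < lo <= hi <= 1.2):
            raise ValueError("suppression_range must satisfy 0 < lo <= hi <= 1.2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.matrix not in _SUPPRESSION_BY_MATRIX:
            raise ValueError(f"unknown matrix {self.matrix!r}")


@dataclass
class DesignOutput:
    """Chromatograms, sample sheet, and ground-truth manifest."""

    chromatograms: list[SIMChromatogram]
    sample_sheet: pd.DataFrame
    manifest: dict

    def __iter__(self):
        return iter((self.chromatograms, self.sample_sheet, self.manifest))


def _sample_rng(master_seed: int, sample_id: str) -> np.random.Generator:
    """Per-sample generator from a stable hash of (seed, sample_id)."""
    tag = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.default_rng([master_seed & 0x7FFFFFFF, tag])


def design_defaults(
    kind: str,
    seed: int = 0,
    replicates: int | None = None,
    noise_sd: float | None = None,
) -> SimulationDesign:
    """Study-condition defaults for each experiment kind.

    The defaults encode the validation designs themselves: the 7-level
    two-fold calibration from 1562.5 ng/mL, the five-level RRF series with
    co-mixed IS at 5 ug/mL, water spikes at 0.1/1/10 ng/mL (IS 0.2/1/10)
    concentrated 1000x by SPE, air spikes at 1/5/10 ng/mL (IS
    2.5/6.5/11.25) concentrated 80x, paired solvent/matrix injections,
    sprayer rinses near 285.6/112.7/74.0 ng/mL after 50x dilution, and
    48 h vapor-chamber samplers reported as total ng with 2.5 ug IS.
    """
    rrf_analyte, rrf_is = rrf_series_mix()
    presets: dict[str, SimulationDesign] = {
        "calibration": SimulationDesign(
            design_kind="calibration",
            levels=list(CALIBRATION_LEVELS),
            is_levels=[0.0] * 7,
            matrix="solvent",
            replicates=3,
            sample_type="calibration",
        ),
        "rrf_series": SimulationDesign(
            design_kind="rrf_series",
            levels=rrf_analyte,
            is_levels=[rrf_is] * len(rrf_analyte),
            matrix="solvent",
            replicates=1,
            sample_type="rrf_level",
        ),
        "recovery_water": SimulationDesign(
            design_kind="recovery_water",
            levels=[0.1, 1.0, 10.0],
            is_levels=[0.2, 1.0, 10.0],
            matrix="water",
            suppression_range=WATER_SUPPRESSION,
            replicates=6,
            concentration_factor=1000.0,
            sample_volume_ml=500.0,
            residue_volume_ml=0.5,
            sample_type="recovery",
        ),
        "recovery_air": SimulationDesign(
            design_kind="recovery_air",
            levels=[1.0, 5.0, 10.0],
            is_levels=[2.5, 6.5, 11.25],
            matrix="resin_puf",
            suppression_range=RESIN_PUF_SUPPRESSION,
            replicates=6,
            concentration_factor=80.0,
            sample_volume_ml=40.0,
            residue_volume_ml=0.5,
            sample_type="recovery",
        ),
        "matrix_effect": SimulationDesign(
            design_kind="matrix_effect",
            levels=[1000.0],
            is_levels=[1000.0],
            matrix="resin_puf",
            suppression_range=RESIN_PUF_SUPPRESSION,
            replicates=3,
            sample_type="matrix",
        ),
        "rinse": SimulationDesign(
            design_kind="rinse",
            levels=[285.6, 112.7, 74.0],
            is_levels=[40.0, 20.0, 20.0],
            matrix="water",
            suppression_range=WATER_SUPPRESSION,
            replicates=4,
            concentration_factor=1000.0,
            aliquot_dilution=50.0,
            sample_volume_ml=500.0,
            residue_volume_ml=0.5,
            sample_type="unknown",
            group_labels=["rinse1", "rinse2", "rinse3"],
            truth_cv=0.03,
        ),
        "air_chamber": SimulationDesign(
            design_kind="air_chamber",
            levels=[700.0, 4500.0],  # total ng per sampler at the two rates
            is_levels=[2.5, 2.5],  # 25 uL x 100 ug/mL = 2.5 ug total
            matrix="resin_puf",
            suppression_range=RESIN_PUF_SUPPRESSION,
            replicates=4,
            concentration_factor=1.0 / 0.2,  # report basis ng total / 0.2 mL
            sample_volume_ml=10.0,
            residue_volume_ml=0.2,
            is_basis="ug_total",
            sample_type="unknown",
            group_labels=["rate560", "rate2240"],
            truth_cv=0.13,
        ),
    }
    if kind not in presets:
        raise ValueError(
            f"unknown design_kind {kind!r}; expected one of {sorted(presets)}"
        )
    design = presets[kind]
    design.seed = seed
    if replicates is not None:
        design.replicates = replicates
    if noise_sd is not None:
        design.noise_sd = noise_sd
    return design


_SHEET_COLUMNS = [
    "sample_id",
    "sample_type",
    "matrix",
    "group",
    "day_label",
    "nominal_analyte",
    "is_reference",
    "is_basis",
    "sample_volume_ml",
    "residue_volume_ml",
    "aliquot_dilution",
]


def generate_design(
    design: SimulationDesign,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    analyte_spec: CompoundIonSpec = DICAMBA,
    is_spec: CompoundIonSpec = D3_DICAMBA,
) -> DesignOutput:
    """Generate all injections of one experiment with ground truth.

    Deterministic under a fixed ``design.seed``: per-sample generators are
    derived by stable hashing of ``(seed, sample_id)``, so adding or
    reordering samples does not perturb the others.
    """
    noise_sd = (
        default_noise_sd(model) if design.noise_sd is None else design.noise_sd
    )
    sup_lo, sup_hi = (
        design.suppression_range
        if design.matrix != "solvent"
        else (1.0, 1.0)
    )
    chroms: list[SIMChromatogram] = []
    rows: list[dict] = []
    truths: list[dict] = []

    def add_sample(
        sample_id: str,
        group: str,
        day_label: str,
        nominal: float,
        is_ref: float,
        matrix: str,
        suppression_range: tuple[float, float],
    ) -> None:
        rng = _sample_rng(design.seed, sample_id)
        true_value = nominal
        if design.truth_cv > 0:
            true_value = max(
                0.0, nominal * (1.0 + design.truth_cv * rng.standard_normal())
            )
        suppression = rng.uniform(*suppression_range)
        cf = design.concentration_factor
        inj_analyte = true_value * cf
        if design.is_basis == "ug_total":
            # is_ref is ug absolute; cf maps ng total -> in-extract ng/mL
            inj_is = is_ref * 1000.0 * cf
        else:
            inj_is = is_ref * cf
        chrom = simulate_injection(
            inj_analyte,
            inj_is,
            analyte_spec,
            is_spec,
            suppression=suppression,
            noise_sd=noise_sd,
            rng=rng,
            model=model,
            sample_id=sample_id,
        )
        chroms.append(chrom)
        rows.append(
            {
                "sample_id": sample_id,
                "sample_type": design.sample_type,
                "matrix": matrix,
                "group": group,
                "day_label": day_label,
                "nominal_analyte": nominal,
                "is_reference": is_ref,
                "is_basis": design.is_basis,
                "sample_volume_ml": design.sample_volume_ml,
                "residue_volume_ml": design.residue_volume_ml,
                "aliquot_dilution": design.aliquot_dilution,
            }
        )
        truths.append(
            {
                "sample_id": sample_id,
                "true_analyte": true_value,
                "true_is": is_ref,
                "injected_analyte_conc": inj_analyte,
                "injected_is_conc": inj_is,
                "suppression": suppression,
            }
        )

    n_levels = len(design.levels)
    for i, (level, is_level) in enumerate(
        zip(design.levels, design.is_levels)
    ):
        group = (
            design.group_labels[i]
            if design.group_labels is not None
            else f"{design.design_kind}_L{i + 1}"
        )
        for r in range(1, design.replicates + 1):
            day = f"day{r}"
            if design.design_kind == "matrix_effect":
                add_sample(
                    f"{group}_solvent_r{r}", group, day, level, is_level,
                    "solvent", (1.0, 1.0),
                )
                add_sample(
                    f"{group}_matrix_r{r}", group, day, level, is_level,
                    design.matrix, (sup_lo, sup_hi),
                )
            else:
                suffix = f"_r{r}" if design.replicates > 1 else ""
                add_sample(
                    f"{group}{suffix}", group, day, level, is_level,
                    design.matrix, (sup_lo, sup_hi),
                )

    sheet = pd.DataFrame(rows, columns=_SHEET_COLUMNS)
    manifest = {
        "design_kind": design.design_kind,
        "seed": design.seed,
        "noise_sd": noise_sd,
        "n_levels": n_levels,
        "replicates": design.replicates,
        "samples": truths,
    }
    return DesignOutput(chroms, sheet, manifest)


def simulate_calibration_areas(
    levels: tuple[float, ...] = CALIBRATION_LEVELS,
    replicates: int = 3,
    area_cv: float = 0.05,
    seed: int = 0,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    spec: CompoundIonSpec = DICAMBA,
) -> pd.DataFrame:
    """Closed-form calibration areas with multiplicative noise.

    Lightweight area-level companion to the full chromatogram generator
    for linearity Monte-Carlo studies: each replicate day's summed area is
    the closed-form value scaled by ``1 + N(0, area_cv)``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for level in levels:
        base = closed_form_quant_area(level, spec, model)
        for r in range(1, replicates + 1):
            rows.append(
                {
                    "concentration": level,
                    "day_label": f"day{r}",
                    "area": base * (1.0 + area_cv * rng.standard_normal()),
                }
            )
    return pd.DataFrame(rows)
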