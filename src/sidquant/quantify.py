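"""Relative-response-factor (RRF) quantification and prep back-calculation.

Isotope-dilution direct quantification: the response factor (RF) of a
compound is its peak area divided by its concentration, and the RRF links
the analyte to its isotopically labeled internal standard (IS),

    RRF = (area_A / conc_A) * (conc_IS / area_IS).

Because the IS is spiked at a known level at the start of sample prep and
co-elutes with the analyte, losses and ion suppression scale both areas
identically, and the analyte concentration follows directly from one
injection:

    conc_A = area_A * (conc_IS / area_IS) * (1 / RRF).

The RRF is averaged over a co-mixed dilution series to damp level-to-level
variation. The units of the result follow the IS reference: an in-sample
IS concentration (ng/mL) yields the in-sample analyte concentration; an
absolute IS amount (ug) yields the total analyte amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean

import numpy as np

from .errors import ConfigurationError, InternalStandardError

__all__ = [
    "RFLevel",
    "ResponseCalibration",
    "SamplePrepFactors",
    "QuantResult",
    "compute_rrf",
    "quantify",
    "external_quantify",
    "back_calculate",
    "air_sampling_summary",
    "rsd_percent",
]


def rsd_percent(values) -> float:
    """Relative standard deviation, sample sd (n-1) / mean * 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD requires at least 2 values")
    m = arr.mean()
    if m == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(arr.std(ddof=1) / m * 100.0)


@dataclass(frozen=True)
class RFLevel:
    """Per-level response factors and their ratio."""

    analyte_conc: float
    analyte_area: float
    is_conc: float
    is_area: float
    rf_analyte: float
    rf_is: float
    rrf: float


@dataclass(frozen=True)
class ResponseCalibration:
    """Averaged RRF over a co-mixed dilution series."""

    per_level: tuple[RFLevel, ...]
    rrf_mean: float
    rrf_rsd: float

    @property
    def n_levels(self) -> int:
        return len(self.per_level)


def compute_rrf(series) -> ResponseCalibration:
    """Average the per-level RRFs of a co-mixed analyte/IS series.

    ``series`` is an iterable of ``(analyte_conc, analyte_area, is_conc,
    is_area)`` rows; each yields RF_A = area_A/conc_A, RF_IS =
    area_IS/conc_IS and their ratio. The mean is unweighted; the RSD is
    the sample RSD over levels (0.0 for a single level, where the sample
    standard deviation is undefined).
    """
    rows = list(series)
    if not rows:
        raise ValueError("RRF series must contain at least one level")
    levels = []
    for row in rows:
        conc_a, area_a, conc_is, area_is = row
        if min(conc_a, area_a, conc_is, area_is) <= 0:
            raise ValueError(
                "RRF series requires strictly positive areas and "
                f"concentrations, got {row}"
            )
        rf_a = area_a / conc_a
        rf_is = area_is / conc_is
        levels.append(
            RFLevel(
                analyte_conc=conc_a,
                analyte_area=area_a,
                is_conc=conc_is,
                is_area=area_is,
                rf_analyte=rf_a,
                rf_is=rf_is,
                rrf=rf_a / rf_is,
            )
        )
    rrfs = [lv.rrf for lv in levels]
    rrf_rsd = rsd_percent(rrfs) if len(rrfs) >= 2 else 0.0
    return ResponseCalibration(
        per_level=tuple(levels), rrf_mean=mean(rrfs), rrf_rsd=rrf_rsd
    )


def quantify(
    area_analyte: float,
    area_is: float,
    is_reference: float,
    rrf_mean: float,
) -> float:
    """Direct IS-based quantification from one injection.

    Returns the analyte level on the same basis and in the same units as
    ``is_reference`` (in-sample ng/mL, or absolute ug). A missing analyte
    peak (area 0) quantifies to 0; a missing IS peak is an error because
    the whole calculation hinges on it.
    """
    if rrf_mean <= 0:
        raise ValueError("rrf_mean must be positive")
    if is_reference <= 0:
        raise ValueError("is_reference must be positive")
    if area_analyte < 0:
        raise ValueError("area_analyte must be non-negative")
    if area_is <= 0:
        raise InternalStandardError(
            "internal standard area is zero or negative; the IS signal was "
            "lost and the sample cannot be quantified"
        )
    return area_analyte * (is_reference / area_is) / rrf_mean


def external_quantify(area_analyte: float, slope: float) -> float:
    """External-standard quantification from a solvent calibration slope.

    No IS correction: the result inherits any ion suppression of the
    matrix. Provided as the comparison arm that shows why the isotope
    dilution route is needed.
    """
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    if area_analyte < 0:
        raise ValueError("area_analyte must be non-negative")
    return area_analyte / slope


@dataclass(frozen=True)
class SamplePrepFactors:
    """Volumes and dilutions linking extract readings to sample levels.

    ``is_basis`` states where the IS reference lives: spiked into the
    original sample as a concentration (``ng_ml_in_sample``, the default
    workflow), spiked into the final extract (``ng_ml_in_extract``), or an
    absolute spike amount (``ug_total``). ``aliquot_dilution`` is any
    dilution of the original sample before prep (e.g. 50x for hose
    rinses); the concentration factor sample_volume/residue_volume applies
    only when the IS reference is in-extract.
    """

    sample_volume_ml: float
    residue_volume_ml: float
    aliquot_dilution: float = 1.0
    is_basis: str = "ng_ml_in_sample"
    reporting_basis: str = "conc_in_sample"

    def __post_init__(self) -> None:
        if self.sample_volume_ml <= 0 or self.residue_volume_ml <= 0:
            raise ValueError("volumes must be positive")
        if self.aliquot_dilution < 1:
            raise ValueError("aliquot_dilution must be >= 1")
        if self.is_basis not in (
            "ng_ml_in_sample",
            "ng_ml_in_extract",
            "ug_total",
        ):
            raise ValueError(f"unknown is_basis {self.is_basis!r}")
        if self.reporting_basis not in ("conc_in_sample", "total_amount"):
            raise ValueError(
                f"unknown reporting_basis {self.reporting_basis!r}"
            )

    @property
    def concentration_factor(self) -> float:
        return self.sample_volume_ml / self.residue_volume_ml


@dataclass(frozen=True)
class QuantResult:
    """Back-calculated result for one sample."""

    sample_id: str
    conc_analyte: float | None  # ng/mL on the reported (undiluted) basis
    is_reference: float
    total_amount: float | None  # ng
    flags: frozenset[str] = field(default_factory=frozenset)


def back_calculate(
    value: float,
    prep: SamplePrepFactors,
    sample_id: str = "sample",
    is_reference: float = 0.0,
    method_lod: float | None = None,
    method_loq: float | None = None,
) -> QuantResult:
    """Propagate a direct quantification result through the prep chain.

    ``value`` is the :func:`quantify` output on the IS-reference basis.
    With an in-sample IS the result already is the in-(possibly diluted)-
    sample concentration, so only the aliquot dilution (and optionally the
    conversion to a total amount) applies; with an in-extract IS the
    concentration factor is divided out first; with an absolute IS amount
    (ug) the result is an absolute amount, reported as total ng.
    """
    if value < 0:
        raise ValueError("quantified value must be non-negative")
    flags: set[str] = set()
    if prep.is_basis == "ug_total":
        if prep.reporting_basis == "conc_in_sample":
            raise ConfigurationError(
                "an absolute (ug_total) IS reference cannot report an "
                "in-sample concentration; use reporting_basis='total_amount'"
            )
        total_ng = value * 1000.0
        if value == 0:
            flags.add("no_peak")
        return QuantResult(
            sample_id=sample_id,
            conc_analyte=None,
            is_reference=is_reference,
            total_amount=total_ng,
            flags=frozenset(flags),
        )
    conc = value
    if prep.is_basis == "ng_ml_in_extract":
        conc = conc / prep.concentration_factor
    conc_reported = conc * prep.aliquot_dilution
    if value == 0:
        flags.add("no_peak")
    if method_lod is not None and conc_reported < method_lod:
        flags.add("below_lod")
    if method_loq is not None and conc_reported < method_loq:
        flags.add("below_loq")
    total = None
    if prep.reporting_basis == "total_amount":
        total = conc_reported * prep.sample_volume_ml
    return QuantResult(
        sample_id=sample_id,
        conc_analyte=conc_reported,
        is_reference=is_reference,
        total_amount=total,
        flags=frozenset(flags),
    )


def air_sampling_summary(
    chamber_volume_l: float, flow_ml_min: float, duration_h: float
) -> tuple[float, float]:
    """Chamber air turnover time (min) and total sampled air volume (L)."""
    if min(chamber_volume_l, flow_ml_min, duration_h) <= 0:
        raise ValueError("all arguments must be positive")
    turnover_min = chamber_volume_l * 1000.0 / flow_ml_min
    total_air_l = flow_ml_min * duration_h * 60.0 / 1000.0
    return turnover_min, total_air_l
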