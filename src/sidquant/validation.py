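"""Method-performance calculus: linearity, LOD/LOQ, recovery, matrix effect.

The acceptance rules implemented here are the ones used to validate the
single-quadrupole method: a calibration passes linearity when the
coefficient of determination of area vs concentration reaches 0.990 and
every level's between-day area RSD stays within 20%; the instrument LOD
and LOQ are the concentrations at observed S/N 3 and 10; the method LOD
divides the instrument LOD by the sample-prep concentration factor;
recovery is measured/nominal at each spike level; and the matrix effect
is the matrix-matched response as a percentage of the solvent response
(< 100% means ion suppression, > 100% enhancement).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ExtrapolationError
from .quantify import rsd_percent

__all__ = [
    "LinearityResult",
    "SensitivityResult",
    "RecoveryResult",
    "MatrixEffectResult",
    "ReplicateSummary",
    "assess_linearity",
    "estimate_lod_loq",
    "compute_recovery",
    "compute_matrix_effect",
    "summarize_replicates",
    "round_half_up",
    "LINEARITY_MIN_R2",
    "LINEARITY_MAX_RSD",
    "LOD_SNR",
    "LOQ_SNR",
]

LINEARITY_MIN_R2 = 0.990
LINEARITY_MAX_RSD = 20.0
LOD_SNR = 3.0
LOQ_SNR = 10.0


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding, matching report-table conventions.

    Python's built-in ``round`` is banker's rounding (112.65 -> 112.6);
    report tables round half away from zero (112.65 -> 112.7).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    per_level_rsd: dict[float, float]
    passed: bool


def assess_linearity(
    measurements: pd.DataFrame,
    min_r2: float = LINEARITY_MIN_R2,
    max_rsd: float = LINEARITY_MAX_RSD,
) -> LinearityResult:
    """Linearity of area vs concentration across replicate days.

    ``measurements`` needs columns ``concentration``, ``area`` and
    (for per-level RSDs) ``day_label``. All points enter one ordinary
    least-squares fit; R^2 is the squared Pearson correlation. The method
    passes when R^2 >= ``min_r2`` and every level's between-day area RSD
    is <= ``max_rsd``.
    """
    required = {"concentration", "area"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns {sorted(missing)}")
    conc = measurements["concentration"].to_numpy(dtype=float)
    area = measurements["area"].to_numpy(dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("linearity requires >= 2 distinct concentrations")
    fit = stats.linregress(conc, area)
    per_level_rsd: dict[float, float] = {}
    for level, grp in measurements.groupby("concentration"):
        if len(grp) >= 2:
            per_level_rsd[float(level)] = rsd_percent(grp["area"])
    r2 = float(fit.rvalue**2)
    passed = r2 >= min_r2 and all(
        rsd <= max_rsd for rsd in per_level_rsd.values()
    )
    return LinearityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        per_level_rsd=per_level_rsd,
        passed=passed,
    )


@dataclass(frozen=True)
class SensitivityResult:
    instrument_lod: float
    instrument_loq: float
    method_lod: float
    concentration_factor: float


def estimate_lod_loq(
    measurements,
    thresholds: tuple[float, float] = (LOD_SNR, LOQ_SNR),
    concentration_factor: float = 1.0,
) -> SensitivityResult:
    """Concentrations at observed S/N 3 and 10 by log-log interpolation.

    ``measurements`` is an iterable of ``(concentration, snr)`` pairs
    spanning the thresholds. Interpolation is linear in log(conc) vs
    log(snr) -- exact when height scales linearly with concentration over
    a constant noise floor. Thresholds outside the probed S/N range raise
    :class:`ExtrapolationError` rather than extrapolating silently.
    """
    pairs = sorted((float(c), float(s)) for c, s in measurements)
    if len(pairs) < 2:
        raise ValueError("need >= 2 (concentration, snr) measurements")
    conc = np.array([p[0] for p in pairs])
    snr = np.array([p[1] for p in pairs])
    if np.any(conc <= 0) or np.any(snr <= 0):
        raise ValueError("concentrations and S/N must be positive")
    if not np.all(np.diff(snr) > 0):
        raise ValueError("S/N must increase monotonically with concentration")
    lod_snr, loq_snr = thresholds
    if concentration_factor <= 0:
        raise ValueError("concentration_factor must be positive")
    out = []
    for threshold in (lod_snr, loq_snr):
        if not (snr[0] <= threshold <= snr[-1]):
            raise ExtrapolationError(
                f"S/N threshold {threshold} outside probed range "
                f"[{snr[0]:.3g}, {snr[-1]:.3g}]"
            )
        out.append(
            float(
                np.exp(
                    np.interp(np.log(threshold), np.log(snr), np.log(conc))
                )
            )
        )
    lod, loq = out
    return SensitivityResult(
        instrument_lod=lod,
        instrument_loq=loq,
        method_lod=lod / concentration_factor,
        concentration_factor=concentration_factor,
    )


@dataclass(frozen=True)
class RecoveryResult:
    level: float
    mean_recovery: float
    rsd: float
    n: int


def compute_recovery(results: pd.DataFrame) -> list[RecoveryResult]:
    """Per-level mean spike recovery (%) and its RSD.

    ``results`` needs columns ``nominal`` (the spiked level) and
    ``measured`` (the quantified level, same basis). Recovery of each
    sample is measured/nominal * 100; levels are the distinct nominals.
    """
    required = {"nominal", "measured"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results missing columns {sorted(missing)}")
    if results["nominal"].isna().any() or (results["nominal"] <= 0).any():
        raise ValueError("every recovery sample needs a positive nominal")
    out = []
    for level, grp in results.groupby("nominal"):
        rec = grp["measured"].to_numpy(dtype=float) / float(level) * 100.0
        out.append(
            RecoveryResult(
                level=float(level),
                mean_recovery=float(rec.mean()),
                rsd=rsd_percent(rec) if rec.size >= 2 else 0.0,
                n=int(rec.size),
            )
        )
    return out


@dataclass(frozen=True)
class MatrixEffectResult:
    matrix: str
    effect: float

    @property
    def interpretation(self) -> str:
        if self.effect < 100.0:
            return "suppression"
        if self.effect > 100.0:
            return "enhancement"
        return "none"


def compute_matrix_effect(
    area_in_matrix: float, area_in_solvent: float, matrix: str = "matrix"
) -> MatrixEffectResult:
    """Matrix-matched response as a percentage of the solvent response."""
    if area_in_solvent <= 0:
        raise ValueError("solvent area must be positive")
    if area_in_matrix < 0:
        raise ValueError("matrix area must be non-negative")
    return MatrixEffectResult(
        matrix=matrix, effect=100.0 * area_in_matrix / area_in_solvent
    )


@dataclass(frozen=True)
class ReplicateSummary:
    values: tuple[float, ...]
    mean: float
    rsd: float
    mean_rounded: float
    rsd_rounded: float


def summarize_replicates(
    values, mean_decimals: int = 1, rsd_decimals: int = 0
) -> ReplicateSummary:
    """Mean and RSD of replicate measurements, with report rounding.

    The rounded fields follow the report-table convention: mean to one
    decimal place, RSD to the integer percent, both half-up. The rounded
    mean is computed in exact decimal arithmetic so that decimal inputs
    round the way they would by hand (e.g. the mean of values summing to
    295.8 over n=4 is exactly 73.95 and rounds up to 74.0, where binary
    floats would give 73.949999... and round down).
    """
    vals = tuple(float(v) for v in values)
    if len(vals) < 2:
        raise ValueError("replicate summary requires >= 2 values")
    m = float(np.mean(vals))
    rsd = rsd_percent(vals)
    mean_dec = sum(Decimal(repr(v)) for v in vals) / len(vals)
    q = Decimal(1).scaleb(-mean_decimals)
    return ReplicateSummary(
        values=vals,
        mean=m,
        rsd=rsd,
        mean_rounded=float(mean_dec.quantize(q, rounding=ROUND_HALF_UP)),
        rsd_rounded=round_half_up(rsd, rsd_decimals),
    )
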