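"""SIM peak detection, integration, and summed quantification areas.

A SIM acquisition yields one intensity trace per monitored m/z channel.
Processing is deliberately simple and deterministic: the baseline and the
noise level are estimated from a configurable blank region of the trace
(before elution), the apex is the global maximum of the baseline-corrected
intensity inside a retention-time window, and the area is the trapezoidal
integral over a fixed window around the apex. The quantification signal of
a compound is the sum of its fragment- and precursor-channel areas,
integrated at a shared apex taken from the most intense channel.

S/N is apex height divided by the blank-region noise standard deviation,
a common single-quadrupole convention. An apex below 3x the noise level is
a "no peak" outcome (returned as ``None``), not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, MissingChannelError
from .isotopes import CompoundIonSpec

__all__ = [
    "SIMChromatogram",
    "PeakMeasurement",
    "Apex",
    "detect_peak",
    "integrate_peak",
    "summed_quant_area",
    "DEFAULT_RT_WINDOW",
    "DEFAULT_BLANK_REGION",
    "DEFAULT_HALFWIDTH",
]

#: Retention-time search window (min) around the 4.4 min elution.
DEFAULT_RT_WINDOW: tuple[float, float] = (4.0, 4.8)
#: Pre-elution region (min) used for baseline and noise estimation.
DEFAULT_BLANK_REGION: tuple[float, float] = (0.5, 2.0)
#: Integration half-width (min); 4 sigma for the default 0.05 min peak.
DEFAULT_HALFWIDTH: float = 0.2


@dataclass
class SIMChromatogram:
    """Per-channel intensity time series for one injection.

    All channels share one strictly increasing time grid (minutes).
    """

    sample_id: str
    time: np.ndarray
    channels: dict[float, np.ndarray]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time grid must be a 1-D array of >= 2 points")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError(
                f"sample {self.sample_id!r}: times must be strictly increasing"
            )
        for mz, trace in self.channels.items():
            trace = np.asarray(trace, dtype=float)
            if trace.shape != self.time.shape:
                raise ValueError(
                    f"sample {self.sample_id!r}: channel {mz} length "
                    f"{trace.shape} does not match time grid {self.time.shape}"
                )
            if not np.all(np.isfinite(trace)):
                raise ValueError(
                    f"sample {self.sample_id!r}: channel {mz} has non-finite "
                    "intensities"
                )
            self.channels[mz] = trace

    def channel(self, mz: float) -> np.ndarray:
        try:
            return self.channels[mz]
        except KeyError:
            raise MissingChannelError(
                f"sample {self.sample_id!r}: channel m/z {mz} not acquired"
            ) from None


@dataclass(frozen=True)
class Apex:
    """Peak apex: time, baseline-corrected intensity, and grid index."""

    time: float
    intensity: float
    index: int


@dataclass(frozen=True)
class PeakMeasurement:
    """Integrated area, apex height, and S/N for a channel (set)."""

    channel_set: frozenset[float]
    rt: float
    area: float
    height: float
    snr: float
    noise_sd: float


def _blank_stats(
    chrom: SIMChromatogram,
    channel: float,
    blank_region: tuple[float, float],
) -> tuple[float, float]:
    """Baseline mean and noise sd (ddof=1) over the blank region."""
    trace = chrom.channel(channel)
    lo, hi = blank_region
    mask = (chrom.time >= lo) & (chrom.time <= hi)
    if mask.sum() < 2:
        raise ConfigurationError(
            f"blank region {blank_region} covers fewer than 2 points"
        )
    blank = trace[mask]
    return float(blank.mean()), float(blank.std(ddof=1))


def detect_peak(
    chrom: SIMChromatogram,
    channel: float,
    rt_window: tuple[float, float] = DEFAULT_RT_WINDOW,
    blank_region: tuple[float, float] = DEFAULT_BLANK_REGION,
    snr_threshold: float | None = 3.0,
) -> Apex | None:
    """Locate the apex in ``rt_window``, or return ``None`` if no peak.

    The apex is the global maximum of the baseline-corrected intensity in
    the window (ties broken toward the earlier time). It must exceed
    ``snr_threshold`` times the blank-region noise sd; on a noise-free
    trace any strictly positive apex qualifies. ``snr_threshold=None``
    disables the check and always returns the window maximum.
    """
    lo, hi = rt_window
    if lo >= hi:
        raise ValueError(f"rt_window {rt_window} is not ordered")
    if lo < chrom.time[0] or hi > chrom.time[-1]:
        raise ValueError(
            f"rt_window {rt_window} outside time span "
            f"({chrom.time[0]}, {chrom.time[-1]})"
        )
    baseline, noise_sd = _blank_stats(chrom, channel, blank_region)
    trace = chrom.channel(channel) - baseline
    mask = (chrom.time >= lo) & (chrom.time <= hi)
    idx_window = np.nonzero(mask)[0]
    local = trace[idx_window]
    i_local = int(np.argmax(local))  # argmax returns the first (earliest) max
    i = int(idx_window[i_local])
    apex_intensity = float(trace[i])
    if snr_threshold is not None and apex_intensity <= snr_threshold * noise_sd:
        return None
    return Apex(time=float(chrom.time[i]), intensity=apex_intensity, index=i)


def integrate_peak(
    chrom: SIMChromatogram,
    channel: float,
    apex: Apex,
    halfwidth: float = DEFAULT_HALFWIDTH,
    blank_region: tuple[float, float] = DEFAULT_BLANK_REGION,
) -> PeakMeasurement:
    """Trapezoidal area of the baseline-subtracted peak around ``apex``.

    Integrates over ``apex.time +/- halfwidth``. Baseline and noise sd come
    from the blank region, which must not overlap the integration window.
    A (noise-driven) negative raw area is clipped to zero.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    lo, hi = apex.time - halfwidth, apex.time + halfwidth
    blo, bhi = blank_region
    if lo <= bhi and blo <= hi:
        raise ConfigurationError(
            f"blank region {blank_region} overlaps integration window "
            f"({lo:.3f}, {hi:.3f})"
        )
    baseline, noise_sd = _blank_stats(chrom, channel, blank_region)
    trace = chrom.channel(channel) - baseline
    mask = (chrom.time >= lo) & (chrom.time <= hi)
    area = float(np.trapezoid(trace[mask], chrom.time[mask]))
    area = max(area, 0.0)
    height = float(trace[apex.index])
    if noise_sd > 0:
        snr = height / noise_sd
    else:
        snr = float("inf") if height > 0 else 0.0
    return PeakMeasurement(
        channel_set=frozenset({channel}),
        rt=apex.time,
        area=area,
        height=height,
        snr=snr,
        noise_sd=noise_sd,
    )


def summed_quant_area(
    chrom: SIMChromatogram,
    spec: CompoundIonSpec,
    rt_window: tuple[float, float] = DEFAULT_RT_WINDOW,
    halfwidth: float = DEFAULT_HALFWIDTH,
    blank_region: tuple[float, float] = DEFAULT_BLANK_REGION,
    snr_threshold: float = 3.0,
) -> PeakMeasurement | None:
    """Summed fragment+precursor quantification area for a compound.

    The apex is detected on the most intense quantification channel and
    shared across channels; each channel is then integrated independently
    at that apex and the areas summed. Height, S/N, and noise sd are
    reported from the most intense channel. Returns ``None`` when the most
    intense channel shows no peak.
    """
    quant = sorted(spec.quant_channels)
    for mz in quant:
        chrom.channel(mz)  # raise MissingChannelError up front
    # pick the channel with the highest baseline-corrected apex in-window
    best_mz, best_apex = None, None
    for mz in quant:
        apex = detect_peak(
            chrom, mz, rt_window, blank_region, snr_threshold=None
        )
        if best_apex is None or apex.intensity > best_apex.intensity:
            best_mz, best_apex = mz, apex
    confirmed = detect_peak(
        chrom, best_mz, rt_window, blank_region, snr_threshold=snr_threshold
    )
    if confirmed is None:
        return None
    measurements = [
        integrate_peak(chrom, mz, confirmed, halfwidth, blank_region)
        for mz in quant
    ]
    lead = next(m for m in measurements if m.channel_set == {best_mz})
    return PeakMeasurement(
        channel_set=frozenset(quant),
        rt=confirmed.time,
        area=float(sum(m.area for m in measurements)),
        height=lead.height,
        snr=lead.snr,
        noise_sd=lead.noise_sd,
    )
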