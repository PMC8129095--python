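"""Per-trace oscillation metrics from the final minute of each recording.

Power spectra are averaged modified periodograms (Welch's method, Hann taper,
2 s windows, 50% overlap, 0.5 Hz resolution).  From each spectrum the gamma
peak frequency and amplitude (20-80 Hz, lower-peak rule), the 15-48 Hz area
power and a clear-gamma inclusion gate are derived.  Traces failing the gate
are excluded from spectral group comparisons at that concentration but still
contribute to event statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .synthetic import LfpTrace

__all__ = [
    "Spectrum",
    "SpectrumMetrics",
    "GAMMA_BAND",
    "AREA_BAND",
    "final_minute",
    "compute_spectrum",
    "gamma_peak",
    "band_area",
    "clear_gamma",
    "trace_metrics",
]

GAMMA_BAND: tuple[float, float] = (20.0, 80.0)
AREA_BAND: tuple[float, float] = (15.0, 48.0)


@dataclass
class Spectrum:
    frequencies: np.ndarray
    power: np.ndarray
    segment_duration_s: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")


@dataclass
class SpectrumMetrics:
    """Gamma-band summary of one trace: peak frequency (Hz), peak amplitude
    (power units at the peak bin), 15-48 Hz area power, inclusion gate."""

    peak_frequency: float
    peak_amplitude: float
    area_power: float
    clear_gamma: bool


def final_minute(trace: LfpTrace) -> LfpTrace:
    """The last exactly 60 s of a trace, metadata preserved."""
    n_needed = int(round(60.0 * trace.sampling_rate))
    if len(trace.samples) < n_needed:
        deficit = (n_needed - len(trace.samples)) / trace.sampling_rate
        raise ValueError(
            f"trace is {deficit:.3f} s short of the 60 s final-minute segment")
    return LfpTrace(samples=trace.samples[-n_needed:], **trace.metadata())


def compute_spectrum(segment: LfpTrace, window_s: float = 2.0,
                     overlap_frac: float = 0.5) -> Spectrum:
    """Welch power spectral density of a segment.

    Frequency resolution is 1/window_s.  Power scales quadratically with
    signal amplitude and sums (x bin width) to the segment variance within
    taper-related error (Parseval).
    """
    x = segment.samples
    if len(x) == 0:
        raise ValueError("empty segment")
    nperseg = int(round(window_s * segment.sampling_rate))
    if nperseg > len(x):
        raise ValueError("window longer than segment")
    freqs, power = _signal.welch(
        x, fs=segment.sampling_rate, window="hann", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap_frac)), detrend="constant",
        scaling="density")
    return Spectrum(frequencies=freqs, power=power,
                    segment_duration_s=segment.duration_s)


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0]) & (freqs <= band[1])


def gamma_peak(spectrum: Spectrum, band: tuple[float, float] = GAMMA_BAND,
               rel_height: float = 0.5,
               lower_peak_rule: bool = True) -> tuple[float, float]:
    """Gamma peak (frequency, power) within ``band``.

    With the lower-peak rule, among in-band local maxima whose power reaches
    ``rel_height`` x the in-band maximum, the lowest-frequency one is
    returned — when a faster secondary rhythm coexists with the gamma peak
    only the lower peak is measured.  With ``lower_peak_rule=False`` the
    global in-band maximum is returned.  A spectrum with no in-band power
    returns ``(nan, nan)`` (peak undefined).
    """
    mask = _band_mask(spectrum.frequencies, band)
    if not mask.any():
        raise ValueError("no spectrum bins inside the requested band")
    f = spectrum.frequencies[mask]
    p = spectrum.power[mask]
    pmax = p.max()
    if pmax <= 0:
        return (math.nan, math.nan)
    if not lower_peak_rule:
        i = int(np.argmax(p))
        return (float(f[i]), float(p[i]))
    padded = np.concatenate([[-np.inf], p, [-np.inf]])
    is_local_max = (p >= padded[:-2]) & (p >= padded[2:])
    qualifying = is_local_max & (p >= rel_height * pmax)
    idx = np.nonzero(qualifying)[0]
    i = int(idx[0]) if len(idx) else int(np.argmax(p))
    return (float(f[i]), float(p[i]))


def band_area(spectrum: Spectrum, lo: float = AREA_BAND[0],
              hi: float = AREA_BAND[1]) -> float:
    """Trapezoidal integral of power over [lo, hi] (area power).

    Band edges off the frequency grid are linearly interpolated, so the
    integral is exactly additive over adjacent sub-bands.
    """
    if lo >= hi:
        raise ValueError("band bounds must satisfy lo < hi")
    f, p = spectrum.frequencies, spectrum.power
    lo = max(lo, f[0])
    hi = min(hi, f[-1])
    inner = (f > lo) & (f < hi)
    grid = np.concatenate([[lo], f[inner], [hi]])
    vals = np.interp(grid, f, p)
    return float(np.trapezoid(vals, grid))


def clear_gamma(spectrum: Spectrum, snr_min: float = 5.0,
                band: tuple[float, float] = GAMMA_BAND,
                noise_range: tuple[float, float] = (1.0, 300.0)) -> bool:
    """Inclusion gate: is there a clear gamma-band oscillation?

    True iff the in-band peak power is at least ``snr_min`` times the median
    power over ``noise_range`` with the gamma band excluded.  Mirrors the
    study practice of omitting a slice from spectral analysis at any
    concentration where no clear oscillation was seen.
    """
    in_band = _band_mask(spectrum.frequencies, band)
    if not in_band.any():
        return False
    peak = spectrum.power[in_band].max()
    if peak <= 0:
        return False
    out = _band_mask(spectrum.frequencies, noise_range) & ~in_band
    if not out.any():
        return True
    floor = float(np.median(spectrum.power[out]))
    if floor == 0:
        return True
    return bool(peak >= snr_min * floor)


def trace_metrics(trace: LfpTrace, window_s: float = 2.0,
                  overlap_frac: float = 0.5,
                  band: tuple[float, float] = GAMMA_BAND,
                  area_band: tuple[float, float] = AREA_BAND,
                  snr_min: float = 5.0) -> SpectrumMetrics:
    """Final-minute spectral metrics for one trace."""
    segment = final_minute(trace)
    spec = compute_spectrum(segment, window_s=window_s, overlap_frac=overlap_frac)
    freq, amp = gamma_peak(spec, band=band)
    return SpectrumMetrics(
        peak_frequency=freq, peak_amplitude=amp,
        area_power=band_area(spec, *area_band),
        clear_gamma=clear_gamma(spec, snr_min=snr_min, band=band))
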