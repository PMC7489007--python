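"""Hann-window power spectral density of EEG segments.

The estimator is the averaged periodogram over non-overlapping Hann-windowed
segments (Welch's method with zero overlap), one-sided, with density
normalization in uV^2/Hz, so that the integral of the PSD over frequency
recovers the signal variance (Parseval consistency). The default 1 s window
gives 1 Hz resolution.

For spike-and-wave discharge (SWD) segments, which are often shorter than
one analysis window, segments are extended by symmetric reflection to one
window length and the result is flagged ``padded``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .eeg_io import EEGRecording
from .swd import SWDEvent


@dataclass
class SpectralParams:
    """Hann/no-overlap PSD settings; ``band`` bounds the peak search (Hz)."""

    window_length: float = 1.0
    detrend: str = "constant"  # none | constant
    band: tuple[float, float] = (1.0, 50.0)
    pad_short_segments: bool = True

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be > 0")
        if not (0 <= self.band[0] < self.band[1]):
            raise ValueError("band must be an increasing pair of frequencies")


@dataclass
class PSDResult:
    frequencies: np.ndarray  # Hz
    power: np.ndarray  # uV^2/Hz
    n_windows: int
    peak_frequency: float  # Hz, within the search band
    padded: bool = False  # True if any segment was reflection-padded

    def band_power(self, lo: float, hi: float) -> float:
        """Integrated power (uV^2) in [lo, hi] Hz."""
        m = (self.frequencies >= lo) & (self.frequencies <= hi)
        return float(np.trapezoid(self.power[m], self.frequencies[m]))


def _peak(freqs: np.ndarray, power: np.ndarray, band: tuple[float, float]) -> float:
    m = (freqs >= band[0]) & (freqs <= band[1])
    if not m.any():
        raise ValueError("peak-search band contains no frequency bins")
    return float(freqs[m][np.argmax(power[m])])


def compute_psd(
    segment: np.ndarray,
    sampling_rate: float,
    params: SpectralParams = SpectralParams(),
) -> PSDResult:
    """Averaged Hann-window periodogram of one segment.

    The segment must be at least one window long; a partial trailing window
    is dropped.
    """
    segment = np.asarray(segment, dtype=float)
    nper = int(round(params.window_length * sampling_rate))
    if len(segment) < nper:
        raise ValueError(
            f"segment of {len(segment)} samples shorter than one "
            f"{params.window_length} s window"
        )
    if params.band[1] > sampling_rate / 2:
        raise ValueError("peak-search band exceeds the Nyquist frequency")
    detrend = False if params.detrend == "none" else "constant"
    freqs, power = sps.welch(
        segment,
        fs=sampling_rate,
        window="hann",
        nperseg=nper,
        noverlap=0,
        detrend=detrend,
        scaling="density",
    )
    band = params.band if detrend else (0.0, params.band[1])
    return PSDResult(
        frequencies=freqs,
        power=power,
        n_windows=len(segment) // nper,
        peak_frequency=_peak(freqs, power, band),
    )


def _reflect_to_length(x: np.ndarray, n: int) -> np.ndarray:
    """Symmetric (mirror) extension of x to n samples, centered."""
    if len(x) >= n:
        return x[:n]
    pad = n - len(x)
    left = pad // 2
    return np.pad(x, (left, pad - left), mode="symmetric")


def swd_psd(
    recording: EEGRecording,
    swds: list[SWDEvent],
    params: SpectralParams = SpectralParams(),
    channel: str | None = None,
) -> PSDResult:
    """PSD averaged across SWD segments of a recording.

    Each event's [start, end) samples are extracted; segments shorter than
    one window are reflection-padded (and the result flagged) unless
    ``pad_short_segments`` is off, in which case they are skipped. Windowed
    periodograms from all segments are averaged with equal window weight.
    """
    if not swds:
        raise ValueError("no segments: empty SWD list")
    x = recording.channel(channel) if channel else recording.samples[0]
    fs = recording.sampling_rate
    nper = int(round(params.window_length * fs))

    acc = None
    n_windows = 0
    padded = False
    for ev in swds:
        i0, i1 = int(np.floor(ev.start * fs)), int(np.ceil(ev.end * fs))
        seg = x[max(i0, 0) : min(i1, len(x))]
        if len(seg) < 2:
            continue
        if len(seg) < nper:
            if not params.pad_short_segments:
                continue
            seg = _reflect_to_length(seg, nper)
            padded = True
        detrend = False if params.detrend == "none" else "constant"
        freqs, power = sps.welch(
            seg,
            fs=fs,
            window="hann",
            nperseg=nper,
            noverlap=0,
            detrend=detrend,
            scaling="density",
        )
        k = len(seg) // nper
        acc = power * k if acc is None else acc + power * k
        n_windows += k
    if acc is None or n_windows == 0:
        raise ValueError("no segments long enough for one analysis window")
    if padded:
        warnings.warn(
            "SWD segments shorter than the analysis window were "
            "reflection-padded",
            stacklevel=2,
        )
    power = acc / n_windows
    return PSDResult(
        frequencies=freqs,
        power=power,
        n_windows=n_windows,
        peak_frequency=_peak(freqs, power, params.band),
        padded=padded,
    )
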