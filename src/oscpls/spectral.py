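"""Time-frequency decomposition and band-power extraction in task windows.

Virtual-channel signals are decomposed with a short-time Fourier transform
using overlapping Hann-tapered windows (default 512 points, 200 windows per
trial epoch). The hop between window onsets is derived from the trial
length and the requested window count, so the windows tile the epoch
uniformly whatever the sampling rate. Per-segment power spectra are
averaged over segments and trials; band power in an analysis window is the
mean over frequency bins inside the band and time bins inside the window,
with bin centres compared against closed intervals.

Power is expressed as one-sided spectral density (signal units squared per
Hz), so a unit-amplitude sinusoid concentrates its power in the bin nearest
its frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal.windows import hann

from .bands import BandDefinition

__all__ = [
    "TimeFrequencyRepresentation",
    "compute_tfr",
    "band_window_power",
    "window_contrast",
]


@dataclass
class TimeFrequencyRepresentation:
    """Trial-averaged power on a channel x frequency x time grid.

    ``times`` are the centres of the analysis windows in seconds relative
    to the first study onset; ``freqs`` in Hz.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    n_trials: int

    def __post_init__(self) -> None:
        if self.power.shape != (self.power.shape[0], len(self.freqs), len(self.times)):
            raise ValueError("power grid does not match axis lengths")
        if np.any(self.power < 0):
            raise ValueError("TFR power must be non-negative")


def _segment_starts(n_samples: int, window_points: int, n_windows: int) -> np.ndarray:
    """Uniform tiling: hop = floor((n_samples - window) / (n_windows - 1))."""
    if n_windows < 2:
        raise ValueError("n_windows must be >= 2")
    if n_samples < window_points:
        raise ValueError(
            f"trial of {n_samples} samples is shorter than one {window_points}-point window"
        )
    hop = (n_samples - window_points) // (n_windows - 1)
    if hop < 1:
        raise ValueError("trial too short for the requested number of windows")
    return np.arange(n_windows) * hop


def compute_tfr(
    signals: np.ndarray,
    fs: float,
    window_points: int = 512,
    n_windows: int = 200,
    t_start: float = -2.5,
) -> TimeFrequencyRepresentation:
    """Trial-averaged STFT power of (trial x channel x sample) signals.

    Each trial is cut into ``n_windows`` overlapping Hann-tapered segments of
    ``window_points`` samples; per-segment one-sided power spectral densities
    are averaged over segments within a trial and then over trials.
    ``t_start`` is the time of the first sample relative to the first study
    onset and anchors the time axis.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 3:
        raise ValueError("signals must be 3-D: trial x channel x sample")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    n_trials, n_channels, n_samples = signals.shape
    starts = _segment_starts(n_samples, window_points, n_windows)

    taper = hann(window_points, sym=False)
    scale = 1.0 / (fs * np.sum(taper**2))
    freqs = np.fft.rfftfreq(window_points, d=1.0 / fs)
    times = t_start + (starts + (window_points - 1) / 2.0) / fs

    # segment view: trial x channel x window x sample
    idx = starts[:, None] + np.arange(window_points)[None, :]
    power = np.zeros((n_channels, len(freqs), n_windows))
    # batch over trials to bound peak memory on long recordings
    batch = max(1, int(2e7 // (n_channels * n_windows * window_points)))
    for lo in range(0, n_trials, batch):
        seg = signals[lo : lo + batch][:, :, idx] * taper
        spec = np.abs(np.fft.rfft(seg, axis=-1)) ** 2 * scale
        spec[..., 1:] *= 2.0
        if window_points % 2 == 0:
            spec[..., -1] /= 2.0
        power += spec.sum(axis=0).transpose(0, 2, 1)
    power /= n_trials
    return TimeFrequencyRepresentation(
        power=power, freqs=freqs, times=times, fs=fs, n_trials=n_trials
    )


def band_window_power(
    tfr: TimeFrequencyRepresentation,
    band: BandDefinition,
    window: tuple[float, float],
    log: bool = False,
) -> np.ndarray:
    """Mean power per channel over a band and a time window.

    Bins are included when their centre lies inside the closed interval, for
    both the frequency band [f_lo, f_hi] and the time window [t0, t1].
    """
    t0, t1 = window
    if not t0 < t1:
        raise ValueError(f"window start must precede end, got [{t0}, {t1}]")
    f_mask = (tfr.freqs >= band.f_lo) & (tfr.freqs <= band.f_hi)
    t_mask = (tfr.times >= t0) & (tfr.times <= t1)
    if not f_mask.any():
        raise ValueError(f"no frequency bins inside band {band.name!r} [{band.f_lo}, {band.f_hi}] Hz")
    if not t_mask.any():
        raise ValueError(f"no time bins inside window [{t0}, {t1}] s")
    mean = tfr.power[:, f_mask][:, :, t_mask].mean(axis=(1, 2))
    if log:
        return np.log(mean)
    return mean


def window_contrast(power_a: np.ndarray, power_b: np.ndarray) -> np.ndarray:
    """Elementwise ``a - b``; positive values mean a power increase in the
    task window relative to the baseline window."""
    a = np.asarray(power_a, dtype=float)
    b = np.asarray(power_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"axis mismatch: {a.shape} vs {b.shape}")
    return a - b


def band_power_table(
    tfr: TimeFrequencyRepresentation,
    bands: Sequence[BandDefinition],
    windows: dict[str, tuple[float, float]],
    log: bool = False,
) -> np.ndarray:
    """window x channel x band power summary of a TFR."""
    out = np.empty((len(windows), tfr.power.shape[0], len(bands)))
    for wi, (name, win) in enumerate(windows.items()):
        for bi, band in enumerate(bands):
            out[wi, :, bi] = band_window_power(tfr, band, win, log=log)
    return out
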