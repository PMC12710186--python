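"""From raw multichannel LFP to annotated beta bursts.

The chain is: short-time Fourier power spectrum -> selection of the beta
channel (the bipolar pair with the largest 13-30 Hz spectral peak) ->
causal Butterworth band-pass of +/-3 Hz around the patient-specific beta
peak -> rectified, peak-interpolated amplitude envelope -> bursts as
maximal runs of the envelope strictly above a percentile threshold
(75th by default).  A causal (forward-only) filter is used throughout so
that no sample after time t can influence values at or before t, which
is what makes the downstream windows usable for prediction.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from .io import LFPRecording

logger = logging.getLogger(__name__)

BETA_BAND = (13.0, 30.0)


@dataclasses.dataclass
class PowerSpectrum:
    """Mean squared STFT magnitude on the 1-100 Hz grid (1 Hz steps)."""

    frequencies: np.ndarray
    power: np.ndarray
    channel_label: str = ""

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclasses.dataclass
class BetaChannelSelection:
    channel_label: str
    beta_peak_frequency: float
    peak_power: float


@dataclasses.dataclass
class EnvelopeSeries:
    """Beta-filtered signal and its amplitude envelope."""

    filtered: np.ndarray
    envelope: np.ndarray
    sampling_rate: float
    threshold: float | None = None


@dataclasses.dataclass
class BurstAnnotation:
    """Burst intervals as half-open [onset, offset) sample ranges."""

    onsets: np.ndarray
    offsets: np.ndarray
    durations: np.ndarray
    burst_rate: float
    threshold: float
    threshold_percentile: float
    sampling_rate: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=int)
        if np.any(self.offsets <= self.onsets):
            raise ValueError("offsets must exceed onsets")
        if np.any(self.onsets[1:] < self.offsets[:-1]):
            raise ValueError("burst intervals must be sorted and non-overlapping")

    @property
    def n_bursts(self) -> int:
        return len(self.onsets)

    @property
    def onset_times(self) -> np.ndarray:
        return self.onsets / self.sampling_rate

    @property
    def offset_times(self) -> np.ndarray:
        return self.offsets / self.sampling_rate


def stft_frame_count(n_samples: int, sampling_rate: float) -> int:
    """Number of averaged STFT windows (1 s length, 0.5 s hop)."""
    nperseg = int(round(sampling_rate))
    if n_samples < nperseg:
        return 0
    return (n_samples - nperseg) // (nperseg // 2) + 1


def compute_power_spectrum(recording: LFPRecording, channel: str) -> PowerSpectrum:
    """Hamming-windowed STFT power, 1 s windows, 50% overlap, averaged
    over windows and reported on the 1-100 Hz grid."""
    x = recording.channel(channel)
    nperseg = int(round(recording.sampling_rate))
    if len(x) < nperseg:
        raise ValueError(
            f"recording too short for spectral estimation: need at least "
            f"1 s ({nperseg} samples), got {len(x)}"
        )
    hop = nperseg // 2
    frames = np.lib.stride_tricks.sliding_window_view(x, nperseg)[::hop]
    window = scipy.signal.get_window("hamming", nperseg)
    spec = np.fft.rfft(frames * window, axis=1)
    power = np.mean(np.abs(spec) ** 2, axis=0)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / recording.sampling_rate)
    grid = np.arange(1, 101, dtype=float)
    idx = np.searchsorted(freqs, grid)
    idx = np.clip(idx, 0, len(freqs) - 1)
    return PowerSpectrum(frequencies=grid, power=power[idx], channel_label=channel)


def _beta_peaks(spectrum: PowerSpectrum) -> list[tuple[float, float]]:
    """(frequency, power) of local maxima of the spectrum inside the beta
    band, using the 1 Hz grid and its immediate neighbors."""
    f = spectrum.frequencies
    p = spectrum.power
    peaks = []
    for i in range(1, len(f) - 1):
        if not BETA_BAND[0] <= f[i] <= BETA_BAND[1]:
            continue
        if p[i] > p[i - 1] and p[i] >= p[i + 1]:
            peaks.append((f[i], p[i]))
    return peaks


def select_beta_channel(
    spectra: dict[str, PowerSpectrum],
) -> BetaChannelSelection | None:
    """Pick the channel with the largest beta-band spectral peak.

    Returns ``None`` when no channel shows a local maximum inside
    13-30 Hz, so the caller can exclude that hemisphere.  Ties in peak
    power are broken toward the lower frequency and then toward the
    lexicographically smaller channel label.
    """
    if not spectra:
        raise ValueError("at least one channel spectrum required")
    best: BetaChannelSelection | None = None
    for label in sorted(spectra):
        for freq, power in _beta_peaks(spectra[label]):
            if best is None or power > best.peak_power:
                best = BetaChannelSelection(label, freq, power)
    return best


def bandpass_beta(
    recording: LFPRecording, channel: str, peak: float
) -> np.ndarray:
    """Causal 6th-order Butterworth band-pass of peak +/- 3 Hz."""
    return bandpass_beta_series(
        recording.channel(channel), recording.sampling_rate, peak
    )


def bandpass_beta_series(x: np.ndarray, fs: float, peak: float) -> np.ndarray:
    lo, hi = peak - 3.0, peak + 3.0
    if lo <= 0 or hi >= fs / 2:
        raise ValueError(
            f"band [{lo:g}, {hi:g}] Hz violates (0, Nyquist={fs / 2:g}) limits"
        )
    sos = scipy.signal.butter(6, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # forward-only filtering: output at t depends only on inputs <= t
    return scipy.signal.sosfilt(sos, x)


def downsample_series(x: np.ndarray, from_fs: float, to_fs: float) -> np.ndarray:
    """Anti-alias protected decimation by an integer factor."""
    ratio = from_fs / to_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"downsampling ratio {from_fs:g}/{to_fs:g} is not an integer"
        )
    q = int(round(ratio))
    if q == 1:
        return np.asarray(x, dtype=float).copy()
    return scipy.signal.decimate(x, q)


def compute_envelope(filtered: np.ndarray, fs: float) -> EnvelopeSeries:
    """Rectify and linearly interpolate between the peaks of the
    rectified signal; edge samples hold the nearest peak value."""
    filtered = np.asarray(filtered, dtype=float)
    if len(filtered) == 0:
        raise ValueError("empty series")
    rect = np.abs(filtered)
    peaks, _ = scipy.signal.find_peaks(rect)
    if len(peaks) == 0:
        logger.warning("no local maxima found; envelope equals rectified signal")
        env = rect.copy()
    else:
        env = np.interp(np.arange(len(rect)), peaks, rect[peaks])
    return EnvelopeSeries(filtered=filtered, envelope=env, sampling_rate=fs)


def annotate_bursts(
    env: EnvelopeSeries,
    percentile: float = 75.0,
    reference: np.ndarray | None = None,
    threshold: float | None = None,
    min_duration_s: float = 0.0,
) -> BurstAnnotation:
    """Bursts = maximal runs of envelope samples strictly above the
    threshold.

    The threshold is the given percentile of ``reference`` (defaults to
    the envelope itself; pass the training portion to avoid leakage into
    validation/test data), unless an explicit ``threshold`` is supplied.
    Samples exactly at the threshold are non-burst, so a constant
    envelope yields zero bursts.
    """
    e = env.envelope
    if len(e) == 0:
        raise ValueError("empty envelope")
    if threshold is None:
        ref = e if reference is None else np.asarray(reference, dtype=float)
        threshold = float(np.percentile(ref, percentile))
    env.threshold = threshold
    above = e > threshold
    edges = np.diff(above.astype(np.int8))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if above[0]:
        onsets = np.r_[0, onsets]
    if above[-1]:
        offsets = np.r_[offsets, len(e)]
    durations = (offsets - onsets) / env.sampling_rate
    if min_duration_s > 0:
        keep = durations >= min_duration_s
        onsets, offsets, durations = onsets[keep], offsets[keep], durations[keep]
    minutes = len(e) / env.sampling_rate / 60.0
    return BurstAnnotation(
        onsets=onsets,
        offsets=offsets,
        durations=durations,
        burst_rate=len(onsets) / minutes,
        threshold=threshold,
        threshold_percentile=percentile,
        sampling_rate=env.sampling_rate,
    )


def burst_statistics(annotation: BurstAnnotation, total_duration: float) -> dict:
    """Count, duration summaries and rate (bursts/min)."""
    if total_duration <= 0:
        raise ValueError("total_duration must be positive")
    n = annotation.n_bursts
    stats = {
        "count": n,
        "rate_per_min": n / (total_duration / 60.0),
        "mean_duration_s": float(np.mean(annotation.durations)) if n else math.nan,
        "median_duration_s": float(np.median(annotation.durations)) if n else math.nan,
        "mean_defined": n > 0,
    }
    return stats


def write_burst_annotation(annotation: BurstAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {
            "onset_s": annotation.onset_times,
            "offset_s": annotation.offset_times,
            "duration_s": annotation.durations,
        }
    ).to_csv(path, sep="\t", index=False)


SLEEP_SCORE_CUTOFF = 80.0
SAMPLES_PER_WINDOW = 5  # five 2-min bradykinesia scores per 10-min window


def classify_vigilance_state(scores: np.ndarray) -> list[str]:
    """Label each 10-min window sleep/awake from 2-min bradykinesia scores.

    Scores must already be sign-transformed to positive.  A window is
    'sleep' when at least 6 of its 10 minutes are immobile, i.e. at
    least 3 of its 5 two-minute scores exceed 80; otherwise 'awake'.
    Windows with missing or incomplete samples are 'unknown'.
    """
    scores = np.asarray(scores, dtype=float)
    labels = []
    n_windows = math.ceil(len(scores) / SAMPLES_PER_WINDOW)
    for w in range(n_windows):
        chunk = scores[w * SAMPLES_PER_WINDOW : (w + 1) * SAMPLES_PER_WINDOW]
        if len(chunk) < SAMPLES_PER_WINDOW or np.any(np.isnan(chunk)):
            labels.append("unknown")
        elif np.sum(chunk > SLEEP_SCORE_CUTOFF) >= 3:
            labels.append("sleep")
        else:
            labels.append("awake")
    return labels
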