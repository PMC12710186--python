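"""Synthetic subthalamic LFP with ground-truth beta bursts.

The generator emulates the statistical structure that the downstream
pipeline exploits: a narrow-band beta carrier (13-30 Hz) whose amplitude
is elevated during burst episodes, an optional pre-burst amplitude dip
accompanied by a phase reset of the carrier (the putative mechanism of
burst initiation), and spectrally shaped 1/f background noise.  Every
draw flows from one seeded generator, so identical seeds give
bit-identical recordings.

Burst onsets/offsets in :class:`GroundTruth` mark the half-amplitude
points of the burst envelope ramps, which is where a percentile
threshold on the amplitude envelope detects them.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .io import LFPRecording

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SimulationParams:
    """Conditions of a synthetic recording.

    sampling_rate : Hz.
    duration : s.
    beta_peak : Hz, patient-specific peak in 13-30 Hz.
    burst_rate : bursts per minute (realized onset rate).
    burst_duration_shape : (gamma shape, gamma scale) in s for burst
        durations measured between half-amplitude points.
    burst_amplitude_gain : burst envelope amplitude as a multiple of the
        baseline beta amplitude.
    dip_depth : fractional amplitude reduction at the dip trough, in [0, 1].
    dip_latency : ms between the dip trough and the following burst onset.
    dip_width : full width of the raised-cosine dip notch, ms.
    noise_exponent : slope of the 1/f^a background noise.
    snr : dB of baseline beta power over background power within the
        beta_peak +/- 3 Hz band; ``None`` or ``inf`` disables noise.
    n_channels : channels; channel 0 carries the beta process at unit
        gain, later channels at ``channel_beta_gains`` (default 0.5**k).
    ramp : full width of the half-cosine burst on/off ramps, ms.
    """

    sampling_rate: float = 600.0
    duration: float = 600.0
    beta_peak: float = 18.0
    burst_rate: float = 30.0
    burst_duration_shape: tuple[float, float] = (9.0, 1.0 / 18.0)
    burst_amplitude_gain: float = 3.0
    dip_depth: float = 0.6
    dip_latency: float = 90.0
    dip_width: float = 100.0
    noise_exponent: float = 1.0
    snr: float | None = 15.0
    n_channels: int = 1
    seed: int = 0
    min_inter_burst_gap: float = 0.5
    ramp: float = 80.0
    channel_beta_gains: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2.0 * (self.beta_peak + 3.0):
            raise ValueError(
                "sampling_rate must exceed twice the upper band edge "
                f"(need > {2 * (self.beta_peak + 3):g} Hz)"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 13.0 <= self.beta_peak <= 30.0:
            raise ValueError("beta_peak must lie in the beta range 13-30 Hz")
        if self.dip_latency < 0:
            raise ValueError("dip_latency must be non-negative")
        if not 0.0 <= self.dip_depth <= 1.0:
            raise ValueError("dip_depth must lie in [0, 1]")
        if self.burst_rate <= 0:
            raise ValueError("burst_rate must be positive")


@dataclasses.dataclass
class GroundTruth:
    """Programmed burst events of a simulation (times in seconds)."""

    true_burst_onsets: np.ndarray
    true_burst_offsets: np.ndarray
    dip_centers: np.ndarray
    # diagnostic: the programmed amplitude-modulation profile, one value
    # per sample of the recording
    amplitude_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        on = np.asarray(self.true_burst_onsets, dtype=float)
        off = np.asarray(self.true_burst_offsets, dtype=float)
        if np.any(np.diff(on) <= 0):
            raise ValueError("burst onsets must be strictly increasing")
        if np.any(off <= on):
            raise ValueError("each offset must exceed its onset")
        if np.any(on[1:] < off[:-1]):
            raise ValueError("burst intervals must not overlap")
        self.true_burst_onsets = on
        self.true_burst_offsets = off
        self.dip_centers = np.asarray(self.dip_centers, dtype=float)

    @property
    def n_bursts(self) -> int:
        return len(self.true_burst_onsets)


def _draw_events(params: SimulationParams, rng: np.random.Generator):
    """Renewal process of burst intervals at the requested onset rate.

    Onset-to-onset interval = previous duration + dead time + gamma wait,
    with the wait mean chosen so the mean interval is 60/burst_rate.
    The dead time guarantees clean pre-burst windows for labeling.
    """
    shape, scale = params.burst_duration_shape
    mean_dur = shape * scale
    mean_interval = 60.0 / params.burst_rate
    mean_wait = mean_interval - mean_dur - params.min_inter_burst_gap
    if mean_wait <= 0:
        raise ValueError(
            "burst_rate too high for the requested durations and the "
            f"{params.min_inter_burst_gap:g} s inter-burst dead time"
        )
    ramp_s = params.ramp / 1000.0
    onsets, offsets = [], []
    t = params.min_inter_burst_gap + rng.gamma(2.0, mean_wait / 2.0)
    while True:
        dur = max(rng.gamma(shape, scale), 0.12)
        if t + dur + ramp_s / 2 >= params.duration:
            break
        onsets.append(t)
        offsets.append(t + dur)
        t = t + dur + params.min_inter_burst_gap + rng.gamma(2.0, mean_wait / 2.0)
    if not onsets:
        raise ValueError(
            "duration too short to contain one burst at the requested rate"
        )
    return np.array(onsets), np.array(offsets)


def _raised_cosine_step(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth 0->1 step of full width `width` centered on `center`."""
    x = np.clip((t - center) / width + 0.5, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * x)


def simulate_recording(params: SimulationParams) -> tuple[LFPRecording, GroundTruth]:
    """Generate a seeded synthetic recording plus its ground truth."""
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs

    onsets, offsets = _draw_events(params, rng)
    ramp_s = params.ramp / 1000.0

    # amplitude profile: baseline 1, bursts raised to the gain with
    # half-cosine ramps whose half-amplitude points sit at onset/offset
    profile = np.ones(n)
    gain = params.burst_amplitude_gain
    for on, off in zip(onsets, offsets):
        rise = _raised_cosine_step(t, on, ramp_s)
        fall = 1.0 - _raised_cosine_step(t, off, ramp_s)
        profile += (gain - 1.0) * rise * fall

    # pre-burst dip: multiplicative raised-cosine notch before each onset
    dip_centers = []
    half_w = params.dip_width / 2000.0
    if params.dip_depth > 0:
        for i, on in enumerate(onsets):
            c = on - params.dip_latency / 1000.0
            prev_end = offsets[i - 1] + ramp_s / 2 if i > 0 else 0.0
            if c - half_w < prev_end:
                logger.warning(
                    "skipping dip before burst %d at %.3f s: would overlap "
                    "the previous burst", i, on,
                )
                continue
            dip_centers.append(c)
            lo = np.searchsorted(t, c - half_w)
            hi = np.searchsorted(t, c + half_w)
            notch = 0.5 + 0.5 * np.cos(np.pi * (t[lo:hi] - c) / half_w)
            profile[lo:hi] *= 1.0 - params.dip_depth * notch
    dip_centers = np.array(dip_centers)

    # carrier with an instantaneous phase reset (to 0) at each dip center
    phase = 2.0 * np.pi * params.beta_peak * t
    if len(dip_centers):
        idx = np.searchsorted(t, dip_centers)
        offset = np.zeros(n)
        for ic in idx:
            offset[ic:] = phase[ic]
        phase = phase - offset
    beta = profile * np.cos(phase)

    gains = params.channel_beta_gains
    if gains is None:
        gains = tuple(0.5 ** k for k in range(params.n_channels))
    if len(gains) != params.n_channels:
        raise ValueError("channel_beta_gains length must equal n_channels")

    noise_scale = None
    channels = np.empty((params.n_channels, n))
    for k in range(params.n_channels):
        channels[k] = gains[k] * beta
        if params.snr is not None and np.isfinite(params.snr):
            noise, noise_scale = _shaped_noise(
                rng, n, fs, params, noise_scale
            )
            channels[k] += noise

    rec = LFPRecording(
        samples=channels,
        sampling_rate=fs,
        channel_labels=[f"ch{k}" for k in range(params.n_channels)],
        session_id=f"sim-seed{params.seed}",
    )
    truth = GroundTruth(onsets, offsets, dip_centers, amplitude_profile=profile)
    return rec, truth


def _shaped_noise(rng, n, fs, params, scale):
    """1/f^a Gaussian noise scaled so baseline beta power over in-band
    noise power equals the requested snr (dB)."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-params.noise_exponent / 2.0)
    x = np.fft.irfft(np.fft.rfft(white) * shaping, n)
    if scale is None:
        spec = np.fft.rfft(x)
        band = (freqs >= params.beta_peak - 3.0) & (freqs <= params.beta_peak + 3.0)
        p_band = 2.0 * np.sum(np.abs(spec[band]) ** 2) / n**2
        p_target = 0.5 * 10.0 ** (-params.snr / 10.0)  # baseline carrier power 0.5
        scale = math.sqrt(p_target / p_band)
    return x * scale, scale


def make_surrogate(recording: LFPRecording, seed: int) -> LFPRecording:
    """Phase-randomized surrogate: per channel, the amplitude spectrum is
    preserved exactly while Fourier phases are drawn uniformly, which
    destroys time-locked features such as the pre-burst dip."""
    if recording.n_samples == 0:
        raise ValueError("recording is empty")
    rng = np.random.default_rng(seed)
    n = recording.n_samples
    out = np.empty_like(recording.samples)
    for k in range(recording.n_channels):
        spec = np.fft.rfft(recording.samples[k])
        mags = np.abs(spec)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(spec))
        new = mags * np.exp(1j * phases)
        new[0] = spec[0]  # DC stays real and untouched
        if n % 2 == 0:
            new[-1] = spec[-1]  # Nyquist bin stays real
        out[k] = np.fft.irfft(new, n)
    return LFPRecording(
        samples=out,
        sampling_rate=recording.sampling_rate,
        channel_labels=list(recording.channel_labels),
        session_id=recording.session_id + "-surrogate",
    )
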