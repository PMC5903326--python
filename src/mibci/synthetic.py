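"""Synthetic Graz-paradigm EEG sessions with a controllable event-related
desynchronization (ERD).

The generator emulates a cue-based motor-imagery session: every trial holds a
rest interval followed by a motor-imagery (MI) interval, recorded from a fixed
montage of 11 scalp electrodes.  Background activity per channel is
1/f-shaped Gaussian noise plus a narrowband sensorimotor oscillation; the ERD
is a multiplicative amplitude attenuation of that oscillation on the target
channels during the MI interval.  Power-line contamination (a 60 Hz sinusoid)
is added so that downstream notch filtering is exercised.

The spectral contract: for an ERD of depth ``d``, the expected band-limited
power of the target band on the target channels during the (post-onset) MI
segment is ``(1 - d)`` times the power during rest.  Channels and bands not
targeted are stationary across the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: Electrode labels of the montage, in canonical order (10-20 system).
CANONICAL_CHANNELS: tuple[str, ...] = (
    "C3", "C4", "Cz", "T3", "T4", "F3", "F4", "Fz", "P3", "P4", "Pz",
)

REST = "REST"
MI = "MI"


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing and montage of one recording session.

    A session holds ``2 * n_trials_per_class`` trials; each trial contributes
    one REST and one MI analysis window downstream, so the number of evaluated
    windows per class equals the total trial count (120 by default).
    """

    sampling_rate: float = 256.0
    rest_duration: float = 3.0
    mi_duration: float = 5.0
    channels: tuple[str, ...] = CANONICAL_CHANNELS
    n_trials_per_class: int = 60

    def __post_init__(self) -> None:
        n = (self.rest_duration + self.mi_duration) * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"trial duration x sampling rate = {n} is not an integer sample count"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")

    @property
    def trial_duration(self) -> float:
        return self.rest_duration + self.mi_duration

    @property
    def n_samples(self) -> int:
        return round(self.trial_duration * self.sampling_rate)

    @property
    def n_trials(self) -> int:
        return 2 * self.n_trials_per_class

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass(frozen=True)
class ErdEffect:
    """Event-related desynchronization injected during the MI interval.

    depth is the relative band-power reduction: 0 = no effect (null data),
    1 = complete suppression of the target-band oscillation.  The attenuation
    starts ``onset_latency`` seconds after the MI cue.
    """

    target_channels: tuple[str, ...] = ("C3", "C4")
    band: tuple[float, float] = (8.0, 12.0)
    depth: float = 0.7
    onset_latency: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError(f"ERD depth must lie in [0, 1], got {self.depth}")
        if not 0.0 < self.band[0] < self.band[1]:
            raise ValueError(f"invalid ERD band {self.band}")
        if self.onset_latency < 0:
            raise ValueError("onset_latency must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Background-activity parameters (amplitudes in microvolts)."""

    background_std: float = 4.0        # broadband 1/f noise RMS
    background_exponent: float = 1.0   # PSD ~ 1/f**exponent
    oscillator_std: float = 8.0        # narrowband sensorimotor rhythm RMS
    line_frequency: float = 60.0
    line_amplitude: float = 2.0


@dataclass
class TrialSet:
    """Labelled epoch array: trials x channels x samples, in microvolts.

    Class labels are positional within each trial (rest segment first, MI
    segment second) and are resolved into per-window REST/MI labels at window
    extraction; ``labels`` stays None until then.
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]
    trial_layout: ParadigmSpec
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("TrialSet data must be trials x channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("TrialSet data contains NaN or Inf")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                      n_samples: int, fs: float, exponent: float,
                      std: float) -> np.ndarray:
    """Gaussian noise with PSD ~ 1/f**exponent, unit-free then scaled to std."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    rms = shaped.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return shaped / rms * std


def _narrowband_noise(rng: np.random.Generator, shape: tuple[int, ...],
                      n_samples: int, fs: float, band: tuple[float, float],
                      std: float) -> np.ndarray:
    """Band-limited Gaussian oscillation with exact per-epoch RMS ``std``."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    white = rng.standard_normal(shape + (n_samples,))
    narrow = signal.sosfiltfilt(sos, white, axis=-1)
    rms = narrow.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return narrow / rms * std


def generate_session(spec: ParadigmSpec = ParadigmSpec(),
                     effect: ErdEffect = ErdEffect(),
                     noise_model: NoiseModel = NoiseModel(),
                     seed: int = 0) -> TrialSet:
    """Generate one synthetic session of ``2 * n_trials_per_class`` trials.

    Identical arguments (including seed) produce bit-identical output.

    Raises
    ------
    ValueError
        If the ERD band reaches the Nyquist frequency or a target channel is
        not in the montage.
    """
    nyquist = spec.sampling_rate / 2.0
    if effect.band[1] >= nyquist:
        raise ValueError(
            f"ERD band {effect.band} exceeds the Nyquist frequency {nyquist} Hz"
        )
    missing = [ch for ch in effect.target_channels if ch not in spec.channels]
    if missing:
        raise ValueError(f"ERD target channels not in montage: {missing}")

    rng = np.random.default_rng(seed)
    n_trials, n_ch, n_samp = spec.n_trials, spec.n_channels, spec.n_samples
    fs = spec.sampling_rate

    background = _one_over_f_noise(
        rng, (n_trials, n_ch), n_samp, fs,
        noise_model.background_exponent, noise_model.background_std)
    oscillation = _narrowband_noise(
        rng, (n_trials, n_ch), n_samp, fs, effect.band,
        noise_model.oscillator_std)

    # ERD envelope: unity during rest and pre-onset MI, sqrt(1 - depth) after,
    # so band POWER drops by the factor (1 - depth).
    envelope = np.ones(n_samp)
    onset = round((spec.rest_duration + effect.onset_latency) * fs)
    envelope[onset:] = np.sqrt(1.0 - effect.depth)
    target_idx = [spec.channels.index(ch) for ch in effect.target_channels]
    modulation = np.ones((n_ch, n_samp))
    modulation[target_idx, :] = envelope
    oscillation *= modulation

    data = background + oscillation
    if noise_model.line_amplitude > 0:
        t = np.arange(n_samp) / fs
        phase = rng.uniform(0, 2 * np.pi, size=(n_trials, n_ch, 1))
        data += noise_model.line_amplitude * np.sin(
            2 * np.pi * noise_model.line_frequency * t + phase)

    return TrialSet(data=data, sampling_rate=fs,
                    channel_names=tuple(spec.channels), trial_layout=spec)


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Welch band power of a 1-D signal; independent check of the ERD contract."""
    x = np.asarray(x, dtype=np.float64)
    nperseg = min(len(x), 256)
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[sel], freqs[sel]))
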