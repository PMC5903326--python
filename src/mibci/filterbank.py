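"""Analysis-window extraction and the temporal filter bank.

Each 8-s trial yields two 1-s analysis windows (one REST, one MI).  Every
window is decomposed into six 4 Hz subbands spanning the mu and beta ranges
(8-32 Hz) with 31-tap linear-phase FIR filters, optionally preceded by a
60 Hz band-stop.  Filtering is causal (plain convolution, no forward-backward
pass) so that the offline path is sample-identical to the online simulator,
which must process windows as they elapse; the constant 15-sample group delay
affects both classes identically.

Filters are least-squares designs (scipy.signal.firls) with 8 Hz transition
bands, normalised to unit gain at the band centre.  At 31 taps this yields
usable stopbands (a 10 Hz tone leaks into the 20-24 Hz band with gain ~0.01),
which a windowed design of the same length does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synthetic import MI, REST, TrialSet

logger = logging.getLogger(__name__)

#: Default subband edges in Hz (contiguous 4 Hz bands covering mu and beta).
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (8.0, 12.0), (12.0, 16.0), (16.0, 20.0),
    (20.0, 24.0), (24.0, 28.0), (28.0, 32.0),
)


@dataclass(frozen=True)
class WindowSpec:
    """Analysis-window placement within a trial, in seconds from trial onset.

    Windows are half-open ``[start, end)`` in samples.  Defaults follow the
    intervals where REST/MI discrimination is strongest: rest 1.5-2.5 s,
    MI 3.5-4.5 s (1-s windows).
    """

    rest_window: tuple[float, float] = (1.5, 2.5)
    mi_window: tuple[float, float] = (3.5, 4.5)

    def __post_init__(self) -> None:
        for name, (a, b) in (("rest_window", self.rest_window),
                             ("mi_window", self.mi_window)):
            if not b > a:
                raise ValueError(f"{name} must have end > start, got ({a}, {b})")
        len_r = self.rest_window[1] - self.rest_window[0]
        len_m = self.mi_window[1] - self.mi_window[0]
        if abs(len_r - len_m) > 1e-9:
            raise ValueError("rest and MI windows must have equal length")


@dataclass(frozen=True)
class FilterBankSpec:
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    filter_order: int = 30
    notch_enabled: bool = True
    notch_band: tuple[float, float] = (59.0, 61.0)
    transition_width: float = 8.0

    def __post_init__(self) -> None:
        if self.filter_order % 2 != 0 or self.filter_order < 2:
            raise ValueError("filter_order must be a positive even integer "
                             "(linear-phase type-I design)")
        prev = 0.0
        for lo, hi in self.bands:
            if not 0.0 < lo < hi:
                raise ValueError(f"invalid band ({lo}, {hi})")
            if lo < prev:
                raise ValueError("bands must be ordered by lower edge")
            prev = lo

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass
class WindowSet:
    """Labelled 1-s windows: windows x channels x samples."""

    data: np.ndarray
    labels: np.ndarray          # "REST" / "MI" per window
    sampling_rate: float
    channel_names: tuple[str, ...]
    trial_index: np.ndarray     # source trial of each window

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(self.data[idx], self.labels[idx], self.sampling_rate,
                         self.channel_names, self.trial_index[idx])


@dataclass
class BandedWindows:
    """Subband-decomposed windows: windows x bands x channels x samples."""

    data: np.ndarray
    labels: np.ndarray
    band_edges: tuple[tuple[float, float], ...]
    sampling_rate: float
    channel_names: tuple[str, ...]
    trial_index: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_bands(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def subset(self, idx: np.ndarray) -> "BandedWindows":
        return BandedWindows(self.data[idx], self.labels[idx], self.band_edges,
                             self.sampling_rate, self.channel_names,
                             self.trial_index[idx])


def extract_windows(trials: TrialSet, spec: WindowSpec = WindowSpec()) -> WindowSet:
    """Cut the REST and MI analysis windows out of every trial.

    Returns 2 windows per trial, interleaved (REST then MI), each exactly
    ``round(window_length * fs)`` samples.
    """
    fs = trials.sampling_rate
    duration = trials.n_samples / fs
    for name, (a, b) in (("rest_window", spec.rest_window),
                         ("mi_window", spec.mi_window)):
        if a < 0 or b > duration + 1e-9:
            raise ValueError(
                f"{name}=({a}, {b}) s lies outside trial 0 "
                f"(all trials span [0, {duration}) s)")
    slices = {}
    for name, (a, b) in (("rest", spec.rest_window), ("mi", spec.mi_window)):
        start, stop = round(a * fs), round(b * fs)
        slices[name] = (start, stop)
    n_win_samples = slices["rest"][1] - slices["rest"][0]

    n = trials.n_trials
    data = np.empty((2 * n, trials.data.shape[1], n_win_samples))
    labels = np.empty(2 * n, dtype=object)
    trial_index = np.repeat(np.arange(n), 2)
    r0, r1 = slices["rest"]
    m0, m1 = slices["mi"]
    data[0::2] = trials.data[:, :, r0:r1]
    data[1::2] = trials.data[:, :, m0:m1]
    labels[0::2] = REST
    labels[1::2] = MI
    return WindowSet(data=data, labels=labels.astype("U4"), sampling_rate=fs,
                     channel_names=trials.channel_names, trial_index=trial_index)


def design_fir_bandpass(low: float, high: float, order: int = 30,
                        fs: float = 256.0, transition_width: float = 8.0,
                        ) -> np.ndarray:
    """Design a linear-phase FIR bandpass (least squares, ``order + 1`` taps).

    Coefficients are symmetric (type-I linear phase, group delay ``order/2``
    samples) and scaled to unit gain at the arithmetic band centre.
    """
    nyq = fs / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) invalid for fs={fs}")
    if order % 2 != 0 or order < 2:
        raise ValueError("order must be a positive even integer")
    lo_stop = max(low - transition_width, 0.1)
    hi_stop = min(high + transition_width, nyq - 0.1)
    taps = signal.firls(order + 1,
                        [0.0, lo_stop, low, high, hi_stop, nyq],
                        [0.0, 0.0, 1.0, 1.0, 0.0, 0.0], fs=fs)
    centre = 0.5 * (low + high)
    _, response = signal.freqz(taps, worN=[centre], fs=fs)
    taps = taps / np.abs(response[0])
    return taps


def design_fir_bandstop(low: float = 59.0, high: float = 61.0, order: int = 30,
                        fs: float = 256.0, transition_width: float = 8.0,
                        ) -> np.ndarray:
    """Linear-phase FIR band-stop (power-line notch), unit passband gain."""
    nyq = fs / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"stop band ({low}, {high}) invalid for fs={fs}")
    lo_pass = max(low - transition_width, 0.1)
    hi_pass = min(high + transition_width, nyq - 0.1)
    taps = signal.firls(order + 1,
                        [0.0, lo_pass, low, high, hi_pass, nyq],
                        [1.0, 1.0, 0.0, 0.0, 1.0, 1.0], fs=fs)
    return taps


def filter_bank_taps(spec: FilterBankSpec, fs: float) -> list[np.ndarray]:
    return [design_fir_bandpass(lo, hi, spec.filter_order, fs,
                                spec.transition_width)
            for lo, hi in spec.bands]


def apply_filter_bank(windows: WindowSet,
                      spec: FilterBankSpec = FilterBankSpec()) -> BandedWindows:
    """Decompose every window into the subbands of ``spec`` (causal FIR).

    The notch, when enabled, is applied before the bandpass bank.  The first
    ``order + 1`` output samples of each window contain the filter transient;
    they are kept (log-variance features are robust to this).
    """
    fs = windows.sampling_rate
    n_taps = spec.filter_order + 1
    if windows.data.shape[-1] < 3 * n_taps:
        logger.warning(
            "windows of %d samples are shorter than 3x the filter length (%d); "
            "edge effects will dominate", windows.data.shape[-1], 3 * n_taps)
    x = windows.data
    if spec.notch_enabled:
        notch = design_fir_bandstop(*spec.notch_band, order=spec.filter_order,
                                    fs=fs, transition_width=spec.transition_width)
        x = signal.lfilter(notch, 1.0, x, axis=-1)
    banded = np.stack(
        [signal.lfilter(taps, 1.0, x, axis=-1)
         for taps in filter_bank_taps(spec, fs)], axis=1)
    return BandedWindows(data=banded, labels=windows.labels,
                         band_edges=tuple(spec.bands), sampling_rate=fs,
                         channel_names=windows.channel_names,
                         trial_index=windows.trial_index)
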