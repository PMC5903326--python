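"""Online-session replay: windowed classification and the orthosis trigger.

A deployed session presents each 8-s trial as six consecutive one-second
windows; the first three fall in the rest interval, the next three in the
motor-imagery interval.  Every window is filtered, featurised and classified
with the frozen offline parameters as soon as it has elapsed.  The robotic
hand orthosis is triggered immediately after the MI interval iff at least 2
of the 3 MI windows were classified as MI; REST windows count toward the
window accuracy (%CA) but never toward the trigger.

%CA is the percentage of correct window classifications over the session;
%CT (percent correct trials) is the percentage of trials whose trigger fired.
After every run, %CT determines a 5-level feedback band (the smiley-face
scale: 90-100 -> happiest, below 60 -> most serious).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import OnlineModel
from .synthetic import MI, REST, TrialSet


@dataclass(frozen=True)
class OnlineProtocol:
    windows_per_trial: int = 6
    n_rest_windows: int = 3
    trials_per_run: int = 20
    runs_per_session: int = 3
    sessions: int = 2
    trigger_min_votes: int = 2

    @property
    def n_mi_windows(self) -> int:
        return self.windows_per_trial - self.n_rest_windows

    def window_truths(self) -> np.ndarray:
        return np.array([REST] * self.n_rest_windows
                        + [MI] * self.n_mi_windows, dtype="U4")


@dataclass
class TrialReplay:
    predictions: np.ndarray
    truths: np.ndarray
    trigger: bool


@dataclass
class SessionResult:
    predictions: np.ndarray      # trials x windows
    truths: np.ndarray
    triggers: np.ndarray         # per-trial bool
    ca: float                    # window-level %CA
    ct: float                    # trial-level trigger rate, %
    per_run_ct: list[float]
    per_run_feedback: list[int]
    mean_processing_time: float  # seconds per window, informational only

    def event_log(self) -> pd.DataFrame:
        rows = []
        n_trials, n_windows = self.predictions.shape
        for t in range(n_trials):
            for w in range(n_windows):
                rows.append((t, w, self.truths[t, w], self.predictions[t, w],
                             bool(self.triggers[t])))
        return pd.DataFrame(rows, columns=["trial", "window", "truth",
                                           "prediction", "trigger"])


def trigger_decision(mi_predictions: np.ndarray,
                     min_votes: int = 2) -> bool:
    """Orthosis rule: fire iff >= min_votes MI-interval windows read MI."""
    return int(np.sum(np.asarray(mi_predictions) == MI)) >= min_votes


def replay_trial(trial: np.ndarray, model: OnlineModel,
                 protocol: OnlineProtocol = OnlineProtocol()) -> TrialReplay:
    """Classify one trial as six consecutive [k, k+1) s windows.

    The featurisation path is identical to the offline one (same causal
    filters and projections), so predictions are reproducible offline.
    """
    trial = np.asarray(trial, dtype=np.float64)
    fs = round(model.sampling_rate)
    needed = protocol.windows_per_trial * fs
    if trial.shape[-1] < needed:
        raise ValueError(
            f"trial has {trial.shape[-1]} samples; replay needs >= {needed} "
            f"({protocol.windows_per_trial} windows of {fs} samples)")
    windows = np.stack([trial[:, k * fs:(k + 1) * fs]
                        for k in range(protocol.windows_per_trial)])
    predictions = model.predict_windows(windows)
    truths = protocol.window_truths()
    fire = trigger_decision(predictions[protocol.n_rest_windows:],
                            protocol.trigger_min_votes)
    return TrialReplay(predictions=predictions, truths=truths, trigger=fire)


def run_session(trials: TrialSet | np.ndarray, model: OnlineModel,
                protocol: OnlineProtocol = OnlineProtocol(),
                trigger_callback: Callable[[int], None] | None = None,
                ) -> SessionResult:
    """Replay every trial in order; aggregate %CA, %CT and per-run feedback.

    ``trigger_callback(trial_index)`` stands in for the orthosis actuation
    (hardware I/O is out of scope).
    """
    data = trials.data if isinstance(trials, TrialSet) else np.asarray(trials)
    n_trials = data.shape[0]
    predictions = np.empty((n_trials, protocol.windows_per_trial), dtype="U4")
    triggers = np.zeros(n_trials, dtype=bool)
    elapsed = 0.0
    for t in range(n_trials):
        tic = time.perf_counter()
        replay = replay_trial(data[t], model, protocol)
        elapsed += time.perf_counter() - tic
        predictions[t] = replay.predictions
        triggers[t] = replay.trigger
        if replay.trigger and trigger_callback is not None:
            trigger_callback(t)
    truths = np.tile(protocol.window_truths(), (n_trials, 1))
    ca = 100.0 * float(np.mean(predictions == truths))
    ct = 100.0 * float(np.mean(triggers))
    per_run_ct, per_run_feedback = [], []
    for start in range(0, n_trials, protocol.trials_per_run):
        run = triggers[start:start + protocol.trials_per_run]
        run_ct = 100.0 * float(np.mean(run))
        per_run_ct.append(run_ct)
        per_run_feedback.append(feedback_band(run_ct))
    return SessionResult(
        predictions=predictions, truths=truths, triggers=triggers,
        ca=ca, ct=ct, per_run_ct=per_run_ct, per_run_feedback=per_run_feedback,
        mean_processing_time=elapsed / (n_trials * protocol.windows_per_trial))


def feedback_band(ct_percent: float) -> int:
    """Smiley-scale index: 0 (happiest, %CT in 90-100) .. 4 (below 60)."""
    for band, threshold in enumerate((90.0, 80.0, 70.0, 60.0)):
        if ct_percent >= threshold:
            return band
    return 4


def correlate_ca_ct(ca: np.ndarray, ct: np.ndarray) -> tuple[float, float]:
    """Pearson r between per-subject %CA and %CT, and the r^2 of the OLS line.

    Returns (nan, nan) when either variable is constant (the correlation is
    undefined then).
    """
    ca = np.asarray(ca, dtype=np.float64)
    ct = np.asarray(ct, dtype=np.float64)
    if ca.size != ct.size or ca.size < 3:
        raise ValueError("need >= 3 paired (%CA, %CT) observations")
    if np.ptp(ca) == 0 or np.ptp(ct) == 0:
        return float("nan"), float("nan")
    r = float(sps.pearsonr(ca, ct).statistic)
    fit = sps.linregress(ca, ct)
    return r, float(fit.rvalue ** 2)
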