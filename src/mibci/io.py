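"""Readers, writers and the run configuration.

Two interchange formats are supported for trial data:

* a compressed NumPy archive (``.npz``) with a JSON sidecar holding labels
  and the paradigm layout — lossless, the native round-trip format;
* EDF+ (``.edf``) — the clinical EEG interchange standard.  Reading goes
  through :mod:`mne`.  Writing is a minimal EDF+C writer implemented here
  (16-bit samples, one annotation channel carrying the cue times); mne's
  independent reader is the round-trip check in the test suite.

Epoching on read cuts one trial per ``trial`` annotation; trials running past
the end of the recording are dropped (logged), and files missing any of the
required channels or recorded at an unexpected rate are refused — this
package never resamples silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .filterbank import FilterBankSpec, WindowSpec
from .online import OnlineProtocol
from .pipeline import CvScheme
from .pso import PsoConfig
from .synthetic import (CANONICAL_CHANNELS, ErdEffect, NoiseModel,
                        ParadigmSpec, TrialSet)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# npz archive + JSON sidecar

def save_trialset(path: str | Path, trials: TrialSet) -> Path:
    """Write trials to ``<path>.npz`` plus ``<path>.json`` sidecar."""
    path = Path(path)
    if path.suffix == ".npz":
        path = path.with_suffix("")
    np.savez_compressed(path.with_suffix(".npz"), data=trials.data)
    layout = dataclasses.asdict(trials.trial_layout)
    layout["channels"] = list(layout["channels"])
    sidecar = {
        "sampling_rate": trials.sampling_rate,
        "channel_names": list(trials.channel_names),
        "trial_layout": layout,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_trialset(path: str | Path) -> TrialSet:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as archive:
        data = archive["data"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    layout = sidecar["trial_layout"]
    spec = ParadigmSpec(sampling_rate=layout["sampling_rate"],
                        rest_duration=layout["rest_duration"],
                        mi_duration=layout["mi_duration"],
                        channels=tuple(layout["channels"]),
                        n_trials_per_class=layout["n_trials_per_class"])
    return TrialSet(data=data, sampling_rate=sidecar["sampling_rate"],
                    channel_names=tuple(sidecar["channel_names"]),
                    trial_layout=spec)


# ---------------------------------------------------------------------------
# EDF+ writing (16-bit; header layout per the EDF specification)

def _ascii(value, width: int) -> bytes:
    text = str(value)[:width]
    return text.ljust(width).encode("ascii")


def write_edf_continuous(path: str | Path, data: np.ndarray, fs: float,
                         channel_names: tuple[str, ...],
                         annotations: list[tuple[float, str]],
                         physical_dim: str = "uV") -> Path:
    """Write a continuous multichannel record as EDF+C.

    ``data`` is channels x samples in physical units; the sample count is
    truncated to whole 1-s data records.  ``annotations`` are (onset_s, text)
    events stored in an 'EDF Annotations' signal.
    """
    path = Path(path)
    data = np.asarray(data, dtype=np.float64)
    fs_int = round(fs)
    if abs(fs - fs_int) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = data.shape[0]
    n_records = data.shape[1] // fs_int
    data = data[:, :n_records * fs_int]

    # symmetric physical range; one digital step of headroom
    span = max(1.0, float(np.max(np.abs(data))))
    pmin, pmax = -span, span
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin) / gain).astype(np.int64) + dmin
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    ann_samples = 40  # 80 bytes per record for timestamp + event TALs
    record_ann = [b"" for _ in range(n_records)]
    for rec in range(n_records):
        record_ann[rec] = f"+{rec}\x14\x14\x00".encode("ascii")
    for onset, text in sorted(annotations):
        rec = min(int(onset), n_records - 1)
        tal = f"+{onset:g}\x14{text}\x14\x00".encode("ascii")
        record_ann[rec] += tal
    for rec, payload in enumerate(record_ann):
        if len(payload) > 2 * ann_samples:
            raise ValueError(f"annotation payload overflows record {rec}")
        record_ann[rec] = payload.ljust(2 * ann_samples, b"\x00")

    n_signals = n_ch + 1
    header = b"".join([
        _ascii("0", 8), _ascii("X X X X", 80), _ascii("Startdate X X X X", 80),
        _ascii("01.01.01", 8), _ascii("00.00.00", 8),
        _ascii(256 * (n_signals + 1), 8), _ascii("EDF+C", 44),
        _ascii(n_records, 8), _ascii(1, 8), _ascii(n_signals, 4),
    ])
    labels = [ch for ch in channel_names] + ["EDF Annotations"]
    fields = [
        (16, labels),
        (80, [""] * n_signals),
        (8, [physical_dim] * n_ch + [""]),
        (8, [f"{pmin:g}"] * n_ch + ["-1"]),
        (8, [f"{pmax:g}"] * n_ch + ["1"]),
        (8, [str(dmin)] * n_signals),
        (8, [str(dmax)] * n_signals),
        (80, [""] * n_signals),
        (8, [str(fs_int)] * n_ch + [str(ann_samples)]),
        (32, [""] * n_signals),
    ]
    signal_header = b"".join(
        b"".join(_ascii(v, width) for v in values) for width, values in fields)

    with open(path, "wb") as fh:
        fh.write(header + signal_header)
        for rec in range(n_records):
            chunk = digital[:, rec * fs_int:(rec + 1) * fs_int]
            fh.write(chunk.tobytes())
            fh.write(record_ann[rec])
    return path


def write_edf(path: str | Path, trials: TrialSet,
              trial_annotation: str = "trial",
              mi_annotation: str = "mi") -> Path:
    """Write a TrialSet as one continuous EDF+ file with cue annotations."""
    layout = trials.trial_layout
    duration = trials.n_samples / trials.sampling_rate
    continuous = np.concatenate(list(trials.data), axis=-1)
    annotations = []
    for i in range(trials.n_trials):
        onset = i * duration
        annotations.append((onset, trial_annotation))
        annotations.append((onset + layout.rest_duration, mi_annotation))
    return write_edf_continuous(path, continuous, trials.sampling_rate,
                                trials.channel_names, annotations)


# ---------------------------------------------------------------------------
# reading

def read_eeg(path: str | Path,
             channels: tuple[str, ...] = CANONICAL_CHANNELS,
             expected_sfreq: float | None = None,
             trial_duration: float = 8.0,
             rest_duration: float = 3.0,
             trial_annotation: str = "trial") -> TrialSet:
    """Load trials from an ``.npz`` archive or an EDF/BDF recording.

    EDF recordings are epoched at the ``trial`` annotations into fixed-length
    trials; channel order is normalised to ``channels``.
    """
    path = Path(path)
    if path.suffix in (".npz", ".json", ""):
        return load_trialset(path)
    if path.suffix.lower() in (".edf", ".bdf"):
        return _read_edf(path, channels, expected_sfreq, trial_duration,
                         rest_duration, trial_annotation)
    raise ValueError(f"unsupported input format {path.suffix!r}")


def _read_edf(path: Path, channels: tuple[str, ...],
              expected_sfreq: float | None, trial_duration: float,
              rest_duration: float, trial_annotation: str) -> TrialSet:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    missing = [ch for ch in channels if ch not in raw.ch_names]
    if missing:
        raise ValueError(f"recording is missing required channels: {missing}")
    sfreq = float(raw.info["sfreq"])
    if expected_sfreq is not None and abs(sfreq - expected_sfreq) > 1e-6:
        raise ValueError(
            f"recording sampled at {sfreq} Hz but {expected_sfreq} Hz was "
            "expected; resampling is refused — convert the file explicitly")
    data = raw.get_data(picks=list(channels)) * 1e6  # volts -> microvolts
    n_samples_trial = round(trial_duration * sfreq)
    onsets = [float(a["onset"]) for a in raw.annotations
              if a["description"] == trial_annotation]
    trials, dropped = [], 0
    for onset in onsets:
        start = round(onset * sfreq)
        stop = start + n_samples_trial
        if stop > data.shape[1]:
            dropped += 1
            continue
        trials.append(data[:, start:stop])
    if dropped:
        logger.info("dropped %d trial(s) extending past the end of %s",
                    dropped, path.name)
    if not trials:
        raise ValueError(f"no complete trials found in {path}")
    stack = np.stack(trials)
    layout = ParadigmSpec(sampling_rate=sfreq, rest_duration=rest_duration,
                          mi_duration=trial_duration - rest_duration,
                          channels=tuple(channels),
                          n_trials_per_class=max(1, len(trials) // 2))
    return TrialSet(data=stack, sampling_rate=sfreq,
                    channel_names=tuple(channels), trial_layout=layout)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Aggregated configuration of every pipeline stage; YAML round-trips
    losslessly."""

    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    effect: ErdEffect = field(default_factory=ErdEffect)
    noise: NoiseModel = field(default_factory=NoiseModel)
    window: WindowSpec = field(default_factory=WindowSpec)
    filterbank: FilterBankSpec = field(default_factory=FilterBankSpec)
    pso: PsoConfig = field(default_factory=PsoConfig)
    cv: CvScheme = field(default_factory=CvScheme)
    protocol: OnlineProtocol = field(default_factory=OnlineProtocol)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            if isinstance(obj, list):
                return [plain(v) for v in obj]
            return obj
        return plain(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        def tup(seq):
            return tuple(tuple(v) if isinstance(v, list) else v for v in seq)
        p = payload.get("paradigm", {})
        e = payload.get("effect", {})
        w = payload.get("window", {})
        f = payload.get("filterbank", {})
        pso = payload.get("pso", {})
        return cls(
            paradigm=ParadigmSpec(
                **{**p, "channels": tuple(p.get("channels", CANONICAL_CHANNELS))}),
            effect=ErdEffect(**{
                **e,
                "target_channels": tuple(e.get("target_channels", ("C3", "C4"))),
                "band": tuple(e.get("band", (8.0, 12.0)))}),
            noise=NoiseModel(**payload.get("noise", {})),
            window=WindowSpec(**{
                **w,
                "rest_window": tuple(w.get("rest_window", (1.5, 2.5))),
                "mi_window": tuple(w.get("mi_window", (3.5, 4.5)))}),
            filterbank=FilterBankSpec(**{
                **f,
                "bands": tup(f.get("bands",
                                   [list(b) for b in FilterBankSpec().bands])),
                "notch_band": tuple(f.get("notch_band", (59.0, 61.0)))}),
            pso=PsoConfig(**{
                **pso,
                "position_bounds": tuple(pso.get("position_bounds", (0.0, 1.0)))}),
            cv=CvScheme(**payload.get("cv", {})),
            protocol=OnlineProtocol(**payload.get("protocol", {})),
            seed=payload.get("seed", 0),
            log_level=payload.get("log_level", "INFO"),
        )

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the configuration (manifest provenance)."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
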