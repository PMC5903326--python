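"""Frozen deployment model: everything the online stage needs, as JSON.

The offline stage produces per-subband spatial filters, a pair-closed feature
mask and LDA coefficients; the online stage loads them and classifies 1-s
windows as they elapse.  The featurisation path here is the same code the
offline evaluator uses (same causal filters, same projections, same feature
formula), so replaying an offline window online reproduces the offline
prediction bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .csp import SpatialFilterBank, extract_features
from .filterbank import FilterBankSpec, WindowSet, apply_filter_bank
from .lda import LdaModel


@dataclass
class OnlineModel:
    sampling_rate: float
    channel_names: tuple[str, ...]
    filter_bank_spec: FilterBankSpec
    spatial_filters: SpatialFilterBank
    feature_mask: np.ndarray
    lda_model: LdaModel

    def featurize(self, windows: np.ndarray) -> np.ndarray:
        """Masked feature matrix for raw windows (n x channels x samples)."""
        windows = np.asarray(windows, dtype=np.float64)
        if windows.ndim == 2:
            windows = windows[None]
        n = windows.shape[0]
        ws = WindowSet(data=windows,
                       labels=np.array(["?"] * n, dtype="U4"),
                       sampling_rate=self.sampling_rate,
                       channel_names=self.channel_names,
                       trial_index=np.arange(n))
        banded = apply_filter_bank(ws, self.filter_bank_spec)
        table = extract_features(banded, self.spatial_filters)
        return table.X[:, self.feature_mask]

    def predict_windows(self, windows: np.ndarray) -> np.ndarray:
        return self.lda_model.predict(self.featurize(windows))

    def to_dict(self) -> dict:
        return {
            "sampling_rate": self.sampling_rate,
            "channel_names": list(self.channel_names),
            "filter_bank": {
                "bands": [list(b) for b in self.filter_bank_spec.bands],
                "filter_order": self.filter_bank_spec.filter_order,
                "notch_enabled": self.filter_bank_spec.notch_enabled,
                "notch_band": list(self.filter_bank_spec.notch_band),
                "transition_width": self.filter_bank_spec.transition_width,
            },
            "spatial_filters": [w.tolist() for w in self.spatial_filters.filters],
            "eigenvalues": [e.tolist() for e in self.spatial_filters.eigenvalues],
            "band_edges": [list(b) for b in self.spatial_filters.band_edges],
            "feature_mask": self.feature_mask.astype(int).tolist(),
            "lda": self.lda_model.to_dict(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, payload: dict) -> "OnlineModel":
        fb = payload["filter_bank"]
        spec = FilterBankSpec(
            bands=tuple(tuple(b) for b in fb["bands"]),
            filter_order=int(fb["filter_order"]),
            notch_enabled=bool(fb["notch_enabled"]),
            notch_band=tuple(fb.get("notch_band", (59.0, 61.0))),
            transition_width=float(fb.get("transition_width", 8.0)))
        filters = [np.asarray(w, dtype=np.float64)
                   for w in payload["spatial_filters"]]
        eigenvalues = [np.asarray(e, dtype=np.float64)
                       for e in payload["eigenvalues"]]
        sfb = SpatialFilterBank(
            filters=filters, eigenvalues=eigenvalues,
            s1=[np.empty(0)] * len(filters), s2=[np.empty(0)] * len(filters),
            band_edges=tuple(tuple(b) for b in payload["band_edges"]))
        return cls(sampling_rate=float(payload["sampling_rate"]),
                   channel_names=tuple(payload["channel_names"]),
                   filter_bank_spec=spec, spatial_filters=sfb,
                   feature_mask=np.asarray(payload["feature_mask"], dtype=bool),
                   lda_model=LdaModel.from_dict(payload["lda"]))

    @classmethod
    def load(cls, path: str | Path) -> "OnlineModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
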