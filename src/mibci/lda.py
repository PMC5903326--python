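"""Two-class linear discriminant analysis.

Fisher/Gaussian LDA with equal priors and pooled covariance: the weight
vector is w = Sigma_pooled^-1 (mu_MI - mu_REST) and the bias places the
decision boundary at the midpoint of the projected class means.  The classes
are balanced by construction throughout the pipeline (one REST and one MI
window per trial), so equal priors are exact, not an approximation.

A decision score of exactly zero resolves to REST: for an orthosis-triggering
system the conservative tie-break is "no movement intent".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import MI, REST

logger = logging.getLogger(__name__)

#: Relative ridge applied to the pooled covariance when it is singular.
SHRINKAGE = 1e-6


@dataclass
class LdaModel:
    weights: np.ndarray
    bias: float
    classes: tuple[str, str] = (REST, MI)   # (negative, positive)
    condition_number: float = 0.0
    shrinkage_used: bool = False

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"dimension {self.weights.shape[0]}")
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        out = np.where(scores > 0, self.classes[1], self.classes[0])
        return out.astype("U4")

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "bias": float(self.bias),
                "classes": list(self.classes),
                "shrinkage_used": self.shrinkage_used}

    @classmethod
    def from_dict(cls, payload: dict) -> "LdaModel":
        return cls(weights=np.asarray(payload["weights"], dtype=np.float64),
                   bias=float(payload["bias"]),
                   classes=tuple(payload["classes"]),
                   shrinkage_used=bool(payload.get("shrinkage_used", False)))


def fit(X: np.ndarray, y: np.ndarray, shrinkage: float = SHRINKAGE) -> LdaModel:
    """Fit the closed-form two-class LDA.

    Parameters
    ----------
    X : windows x features matrix (already restricted to the feature mask).
    y : per-window labels, both REST and MI must be present with >= 2 samples.
    shrinkage : relative diagonal ridge engaged only when the pooled
        covariance cannot be inverted reliably.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    idx_mi = y == MI
    idx_rest = y == REST
    n_mi, n_rest = int(idx_mi.sum()), int(idx_rest.sum())
    if n_mi < 2 or n_rest < 2:
        raise ValueError(
            f"both classes need >= 2 samples (MI={n_mi}, REST={n_rest})")

    mu_mi = X[idx_mi].mean(axis=0)
    mu_rest = X[idx_rest].mean(axis=0)
    centred_mi = X[idx_mi] - mu_mi
    centred_rest = X[idx_rest] - mu_rest
    pooled = (centred_mi.T @ centred_mi + centred_rest.T @ centred_rest) \
        / (n_mi + n_rest - 2)

    delta = mu_mi - mu_rest
    shrinkage_used = False
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e12:
        ridge = shrinkage * max(np.mean(np.diag(pooled)), np.finfo(float).tiny)
        pooled = pooled + ridge * np.eye(pooled.shape[0])
        shrinkage_used = True
        cond = np.linalg.cond(pooled)
        logger.debug("singular pooled covariance; ridge %.3e engaged", ridge)
    weights = np.linalg.solve(pooled, delta)
    bias = -float(weights @ (mu_mi + mu_rest) / 2.0)
    return LdaModel(weights=weights, bias=bias, classes=(REST, MI),
                    condition_number=float(cond), shrinkage_used=shrinkage_used)


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Percentage of correct classifications (%CA)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size == 0:
        raise ValueError("cannot compute accuracy of an empty prediction set")
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth have different lengths")
    return 100.0 * float(np.mean(predicted == truth))
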