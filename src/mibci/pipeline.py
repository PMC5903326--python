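"""Offline evaluation: repeated stratified cross-validation of the
filter-bank-CSP + swarm-selection classifier against the single-band CSP
baseline.

The fold unit is the trial: a trial's REST and MI windows always travel
together, which removes sibling-window leakage between partitions.  Because
every trial contributes exactly one window per class, any partition of trials
is perfectly stratified at the window level.  Spatial filters, the feature
mask and the LDA are all refit on each fold's training trials only; the
temporal filter bank is unsupervised and per-window, so it is applied once
up front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import KFold

from . import lda
from .csp import (FeatureTable, extract_csp_pair_features, extract_features,
                  fit_spatial_filters)
from .filterbank import (BandedWindows, FilterBankSpec, WindowSpec,
                         apply_filter_bank, extract_windows)
from .model import OnlineModel
from .pso import FeatureLayout, PsoConfig, select_features
from .stats import compare_methods, practical_chance_level
from .synthetic import TrialSet

logger = logging.getLogger(__name__)

#: Baseline band for the original-CSP comparison (Hz).
BASELINE_BAND = (8.0, 32.0)


@dataclass(frozen=True)
class CvScheme:
    n_folds: int = 10
    n_repetitions: int = 10
    stratified: bool = True
    seed: int = 0


@dataclass
class FoldRecord:
    repetition: int
    fold: int
    train_trials: np.ndarray
    test_trials: np.ndarray
    accuracy: float
    mask: np.ndarray | None = None
    n_selected: int | None = None


@dataclass
class CvResult:
    method: str
    accuracies: np.ndarray            # n_folds * n_repetitions %CA values
    folds: list[FoldRecord]

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.accuracies, ddof=1))


def make_folds(n_trials: int, scheme: CvScheme,
               ) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
    """Deterministic fold partitions; repetition r reshuffles with seed+r.

    Trials carry one window of each class, so trial-level folds are exactly
    stratified at the window level.
    """
    folds = []
    for rep in range(scheme.n_repetitions):
        splitter = KFold(n_splits=scheme.n_folds, shuffle=True,
                         random_state=(scheme.seed + rep) % (2 ** 31))
        for fold, (train, test) in enumerate(splitter.split(np.arange(n_trials))):
            folds.append((rep, fold, train, test))
    return folds


def _window_subsets(banded: BandedWindows, trial_idx: np.ndarray,
                    ) -> BandedWindows:
    return banded.subset(np.isin(banded.trial_index, trial_idx))


def run_fbcsp_pso_cv(trials: TrialSet,
                     window_spec: WindowSpec = WindowSpec(),
                     fb_spec: FilterBankSpec = FilterBankSpec(),
                     pso_config: PsoConfig = PsoConfig(),
                     scheme: CvScheme = CvScheme()) -> CvResult:
    """10 x 10-fold CV of the full chain; returns the 100 held-out %CAs.

    Per fold: CSP filters, the swarm-selected feature mask and the LDA are
    fit on the training trials; %CA is measured on the held-out trials'
    windows with the training-stage mask.
    """
    windows = extract_windows(trials, window_spec)
    banded = apply_filter_bank(windows, fb_spec)
    records: list[FoldRecord] = []
    for rep, fold, train_idx, test_idx in make_folds(trials.n_trials, scheme):
        train = _window_subsets(banded, train_idx)
        test = _window_subsets(banded, test_idx)
        sfb = fit_spatial_filters(train)
        f_train = extract_features(train, sfb)
        f_test = extract_features(test, sfb)
        fold_cfg = replace(
            pso_config,
            seed=(pso_config.seed + 100003 * rep + 1009 * fold) % (2 ** 31))
        mask, _ = select_features(f_train, fold_cfg)
        model = lda.fit(f_train.X[:, mask], f_train.labels)
        acc = lda.accuracy(model.predict(f_test.X[:, mask]), f_test.labels)
        records.append(FoldRecord(rep, fold, train_idx, test_idx, acc,
                                  mask=mask, n_selected=int(mask.sum())))
        logger.debug("rep %d fold %d: %%CA=%.1f nselec=%d",
                     rep, fold, acc, int(mask.sum()))
    return CvResult(method="fbcsp_pso",
                    accuracies=np.array([r.accuracy for r in records]),
                    folds=records)


def run_csp_baseline_cv(trials: TrialSet,
                        window_spec: WindowSpec = WindowSpec(),
                        fb_spec: FilterBankSpec = FilterBankSpec(),
                        scheme: CvScheme = CvScheme(),
                        m: int = 2) -> CvResult:
    """Original-CSP baseline: one 8-32 Hz band, first/last m filters (2m=4
    features), LDA; identical fold partitions to the proposed method."""
    baseline_spec = FilterBankSpec(bands=(BASELINE_BAND,),
                                   filter_order=fb_spec.filter_order,
                                   notch_enabled=fb_spec.notch_enabled,
                                   notch_band=fb_spec.notch_band,
                                   transition_width=fb_spec.transition_width)
    windows = extract_windows(trials, window_spec)
    banded = apply_filter_bank(windows, baseline_spec)
    records: list[FoldRecord] = []
    for rep, fold, train_idx, test_idx in make_folds(trials.n_trials, scheme):
        train = _window_subsets(banded, train_idx)
        test = _window_subsets(banded, test_idx)
        sfb = fit_spatial_filters(train)
        f_train = extract_csp_pair_features(train, sfb, m=m)
        f_test = extract_csp_pair_features(test, sfb, m=m)
        model = lda.fit(f_train.X, f_train.labels)
        acc = lda.accuracy(model.predict(f_test.X), f_test.labels)
        records.append(FoldRecord(rep, fold, train_idx, test_idx, acc))
    return CvResult(method="csp",
                    accuracies=np.array([r.accuracy for r in records]),
                    folds=records)


def fit_online_model(trials: TrialSet,
                     window_spec: WindowSpec = WindowSpec(),
                     fb_spec: FilterBankSpec = FilterBankSpec(),
                     pso_config: PsoConfig = PsoConfig()) -> OnlineModel:
    """Refit the whole chain once on all offline data; this is the parameter
    set the online stage loads (spatial filters, mask, LDA coefficients)."""
    windows = extract_windows(trials, window_spec)
    banded = apply_filter_bank(windows, fb_spec)
    sfb = fit_spatial_filters(banded)
    table = extract_features(banded, sfb)
    mask, _ = select_features(table, pso_config)
    model = lda.fit(table.X[:, mask], table.labels)
    return OnlineModel(sampling_rate=trials.sampling_rate,
                       channel_names=trials.channel_names,
                       filter_bank_spec=fb_spec, spatial_filters=sfb,
                       feature_mask=mask, lda_model=model)


def summarize_subject(results: dict[str, CvResult], n_decisions: int,
                      alpha: float = 0.05) -> dict:
    """Per-method mean +/- SD, the practical chance line, and the
    nonparametric method comparison when both methods are present."""
    if not results:
        raise ValueError("no results to summarize")
    chance = practical_chance_level(n_decisions, alpha=alpha)
    report: dict = {
        "chance_level_percent": chance,
        "n_decisions": n_decisions,
        "methods": {},
    }
    for name, res in results.items():
        report["methods"][name] = {
            "mean_ca": res.mean,
            "sd_ca": res.std,
            "n_values": int(res.accuracies.size),
            "above_chance": bool(res.mean > chance),
        }
    if "fbcsp_pso" in results and "csp" in results:
        u, p, sig = compare_methods(results["fbcsp_pso"].accuracies,
                                    results["csp"].accuracies, alpha=alpha)
        report["comparison"] = {"test": "mann-whitney-u", "U": u, "p": p,
                                "significant": sig}
    return report
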