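"""Chance-level and hypothesis-testing utilities.

The practical level of chance is the upper confidence bound of a random
classifier's accuracy over a finite number of decisions, from the adjusted
(Agresti-Coull-style) binomial proportion

    p~ = (k + 2) / (n + 4)
    level = p~ + z_{1 - alpha/2} * sqrt( p~ (1 - p~) / (n + 4) )

with k the expected number of correct decisions under random classification
(n/2 by default).  A measured %CA is "above chance" iff it exceeds this
bound.  The z quantile comes from the standard-normal inverse CDF, so any
significance level works.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ChanceSpec:
    n_trials: int
    alpha: float = 0.05
    k: int | None = None   # expected correct count; defaults to n/2

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def expected_correct(self) -> float:
        return self.n_trials / 2.0 if self.k is None else float(self.k)


def practical_chance_level(n: int | ChanceSpec, k: float | None = None,
                           alpha: float = 0.05) -> float:
    """Upper confidence bound of a random classifier's accuracy, in percent."""
    if isinstance(n, ChanceSpec):
        spec = n
    else:
        spec = ChanceSpec(n_trials=int(n), alpha=alpha,
                          k=None if k is None else int(k))
    n_adj = spec.n_trials + 4
    p = (spec.expected_correct + 2.0) / n_adj
    z = sps.norm.ppf(1.0 - spec.alpha / 2.0)
    return 100.0 * (p + z * np.sqrt(p * (1.0 - p) / n_adj))


def above_chance(ca_percent: float, n_decisions: int,
                 alpha: float = 0.05) -> bool:
    """Repo-wide criterion: %CA strictly above the practical chance level."""
    return ca_percent > practical_chance_level(n_decisions, alpha=alpha)


def compare_methods(ca_a: np.ndarray, ca_b: np.ndarray, alpha: float = 0.05,
                    ) -> tuple[float, float, bool]:
    """Two-sided Mann-Whitney U comparison of two %CA samples.

    Returns (U statistic for the first sample, p value, p < alpha).
    """
    ca_a = np.asarray(ca_a, dtype=np.float64)
    ca_b = np.asarray(ca_b, dtype=np.float64)
    if ca_a.size == 0 or ca_b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(ca_a, ca_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def normality_check(sample: np.ndarray) -> tuple[float, float]:
    """Lilliefors-corrected Kolmogorov-Smirnov test for normality.

    Returns (KS statistic, p value).  A constant sample has no distributional
    shape to test; this degenerate case raises.
    """
    from statsmodels.stats.diagnostic import lilliefors

    sample = np.asarray(sample, dtype=np.float64)
    if sample.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(sample) == 0:
        raise ValueError("sample is constant; normality test is degenerate")
    stat, p = lilliefors(sample, dist="norm")
    return float(stat), float(p)


def paired_comparison(a: np.ndarray, b: np.ndarray, alpha: float = 0.05,
                      ) -> tuple[float, float, bool]:
    """Paired t-test (e.g. per-subject offline vs online %CA)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must share a length of >= 2")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)
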