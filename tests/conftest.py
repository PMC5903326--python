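"""Shared fixtures: synthetic sessions at the scales the tests need.

Session-scoped so the expensive generations and model fits run once.
"""

import numpy as np
import pytest

import mibci


@pytest.fixture(scope="session")
def small_trials():
    """30 trials (15 per class-count), strong ERD — fast smoke-scale data."""
    spec = mibci.ParadigmSpec(n_trials_per_class=15)
    return mibci.generate_session(spec, mibci.ErdEffect(depth=0.7), seed=7)


@pytest.fixture(scope="session")
def erd_session():
    """Full-scale session: 120 trials, ERD depth 0.7 on C3/C4."""
    spec = mibci.ParadigmSpec(n_trials_per_class=60)
    return mibci.generate_session(spec, mibci.ErdEffect(depth=0.7), seed=11)


@pytest.fixture(scope="session")
def sibling_session():
    """Independent session from the same generative conditions as erd_session."""
    spec = mibci.ParadigmSpec(n_trials_per_class=60)
    return mibci.generate_session(spec, mibci.ErdEffect(depth=0.7), seed=12)


@pytest.fixture(scope="session")
def deployment_model(erd_session):
    """Whole chain refit once on erd_session (the frozen online parameters)."""
    return mibci.fit_online_model(erd_session)


@pytest.fixture(scope="session")
def small_features(small_trials):
    windows = mibci.extract_windows(small_trials)
    banded = mibci.apply_filter_bank(windows)
    filters = mibci.fit_spatial_filters(banded)
    return mibci.extract_features(banded, filters)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
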