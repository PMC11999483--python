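import numpy as np
import pytest

from circavol import FilterConfig, TrialDesign, simulate_trial


def coarse_filter_config(n: int = 16, cands: int = 2) -> FilterConfig:
    """Small grid for fast tests; bounds match the defaults."""
    return FilterConfig(
        n_mu=n,
        n_logvmu=n,
        n_logsd=n,
        kmu_candidates=tuple(np.logspace(-3, -1, cands)),
        vsd_candidates=tuple(np.logspace(-3, -1, cands)),
    )


def null_design(**kw) -> TrialDesign:
    """Trial design with every treatment effect switched off."""
    base = dict(
        effect_m10_by_week={},
        effect_onset_by_week={},
        effect_volatility_by_week={},
        effect_is_by_week={},
    )
    base.update(kw)
    return TrialDesign(**base)


@pytest.fixture(scope="session")
def small_trial():
    """A complete (no missing days) 6-per-arm null trial."""
    return simulate_trial(null_design(n_per_arm=6, missing_day_rate=0.0, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
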