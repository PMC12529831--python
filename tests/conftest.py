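import numpy as np
import pytest

from cbctqa.config import AnalysisOptions, CohortSpec, Config, PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_phantom():
    """A coarse phantom grid that still holds the 25 mm protocol ROI."""
    return PhantomSpec(shape=(64, 64, 12), spacing_mm=(2.0, 2.0, 2.0))


@pytest.fixture
def small_cohort():
    """Reduced-grid cohort: full anatomy, few patients, fast to render."""
    return CohortSpec(n_patients=4, shape=(48, 48, 24), spacing_mm=(4.0, 4.0, 4.0))


@pytest.fixture
def small_config(small_phantom, small_cohort):
    return Config(phantom=small_phantom, cohort=small_cohort, analysis=AnalysisOptions(), seed=7)


def quiet_cohort(**overrides) -> CohortSpec:
    """A deterministic cohort: no noise, no jitter, no drift fluctuation."""
    base = dict(
        n_patients=2,
        shape=(48, 48, 24),
        spacing_mm=(4.0, 4.0, 4.0),
        noise_sd_hu={"planning-CT": 0.0, "CBCT": 0.0},
        drift={"slope_hu_per_fraction": 0.0, "shell_sigma_hu": 0.0},
    )
    base.update(overrides)
    spec = CohortSpec(**base)
    for comp in spec.compartments.values():
        comp.jitter_sd_hu = 0.0
    return spec
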