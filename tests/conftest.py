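import numpy as np
import pytest
from skimage import draw as skdraw

import gazegrade as gg


def disc_mask(radius: int, pad: int = 4) -> np.ndarray:
    n = 2 * radius + 2 * pad + 1
    m = np.zeros((n, n), bool)
    rr, cc = skdraw.disk((n // 2, n // 2), radius + 0.5, shape=m.shape)
    m[rr, cc] = True
    return m


def ellipse_mask(a: int, b: int, pad: int = 4) -> np.ndarray:
    n = 2 * max(a, b) + 2 * pad + 1
    m = np.zeros((n, n), bool)
    rr, cc = skdraw.ellipse(n // 2, n // 2, b + 0.5, a + 0.5, shape=m.shape)
    m[rr, cc] = True
    return m


@pytest.fixture(scope="session")
def small_tabular_cohort():
    """3 raters x 4 cases, feature-level generation (no rasters)."""
    cfg = gg.default_config(n_cases=4, n_raters=3)
    return gg.simulate_cohort(cfg, seed=123, render=False)


@pytest.fixture(scope="session")
def small_rendered_cohort():
    """3 raters x 4 cases with full rasters and gaze streams."""
    cfg = gg.default_config(n_cases=4, n_raters=3)
    return gg.simulate_cohort(cfg, seed=123, render=True)
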