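import numpy as np
import pytest

import functree as ft


@pytest.fixture
def fine_grid():
    return np.linspace(0.0, 1.0, 1001)


@pytest.fixture
def rank1_sine(fine_grid):
    """Four curves a_i * sin(2πt): rank-1 sample with known eigenstructure.

    The sole eigenfunction is ±√2 sin(2πt) (unit L2 norm) and the scores are
    a_i/√2.
    """
    a = np.array([-3.0, -1.0, 1.0, 3.0])
    values = a[:, None] * np.sin(2 * np.pi * fine_grid)
    return ft.CurveSet(fine_grid, values), a


@pytest.fixture(scope="session")
def separable():
    """The default two-class study conditions with the class difference on
    the second smooth component (seeded once per session)."""
    curves, truth = ft.generate(ft.separable_spec(), seed=42)
    return curves, truth


@pytest.fixture(scope="session")
def separable_features(separable):
    curves, _ = separable
    model, scores = ft.fit_fpca(curves, n_components=5)
    return model, ft.FeatureMatrix.from_scores(scores)
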