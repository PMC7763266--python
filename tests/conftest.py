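"""Shared fixtures: seeded RNGs and small panels of each flavor."""

import numpy as np
import pytest

from mmlgranger import TimeSeriesPanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gaussian_panel(rng, p=3, n=120, parent=None, target=None,
                        strength=0.9, d=2):
    """White-noise gaussian panel, optionally with one planted edge
    parent -> target of the given per-lag strength."""
    x = rng.normal(size=(p, n))
    if parent is not None:
        for t in range(d, n):
            x[target, t] = sum(strength / d * x[parent, t - l]
                               for l in range(1, d + 1)) + rng.normal()
    return TimeSeriesPanel(x, ["gaussian"] * p)


@pytest.fixture
def gaussian_panel(rng):
    return make_gaussian_panel(rng)


@pytest.fixture
def planted_panel(rng):
    """Gaussian panel with a single strong edge x1 -> x3 (0 -> 2)."""
    return make_gaussian_panel(rng, p=3, n=400, parent=0, target=2)
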