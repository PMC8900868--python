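"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from tomocor import make_reflection_pair, reflection_sum, shepp_logan_2d


@pytest.fixture(scope="session")
def shepp_pair_factory():
    """Noiseless low-contrast head-phantom reflection pairs at a given COR
    offset (256 detector columns, phantom shrunk to leave room for +-16 px)."""

    def make(cor_offset: float, **kwargs):
        spec = shepp_logan_2d(grid=256, cor_offset=cor_offset, fill=0.8)
        return make_reflection_pair(spec, **kwargs)

    return make


def brute_force_symmetry_center(profile: np.ndarray, halfwidth: float = 18.0,
                                step: float = 0.01) -> float:
    """Independent COR oracle: direct search for the even-symmetry center.

    Scans candidate centers ``c`` on a ``step``-pixel grid around the array
    center and minimizes ``sum_u |S(c+u) - S(c-u)|^2`` on a cubic-spline
    interpolant of the profile.  Slow and model-free; used only to
    cross-check the Fourier-phase estimator.
    """
    n = profile.size
    center = (n - 1) / 2.0
    spline = CubicSpline(np.arange(n), profile)
    candidates = center + np.arange(-halfwidth, halfwidth + step / 2, step)
    u = np.arange(0.25, n / 2 - halfwidth - 1, 0.25)
    plus = spline(candidates[:, None] + u[None, :])
    minus = spline(candidates[:, None] - u[None, :])
    cost = ((plus - minus) ** 2).sum(axis=1)
    return float(candidates[np.argmin(cost)] - center)


def pair_symmetry_center(pair) -> float:
    """Brute-force oracle applied to a reflection pair's summed profile."""
    profile, _ = reflection_sum(pair, collapse="rows_collapsed")
    return brute_force_symmetry_center(profile)
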