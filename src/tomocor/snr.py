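"""Two-image SNR estimation and photon-budget bookkeeping.

The signal-to-noise ratio of a projection is estimated from two images of
the same scene carrying independent noise instances: the Pearson
correlation ``r`` between them splits the per-pixel variance into a shared
(signal) part and an independent (noise) part, ``r = s^2 / (s^2 + n^2)``,
giving the amplitude SNR ``s/n = sqrt(r / (1 - r))``.  The amplitude
convention is used (not the power ratio ``r/(1-r)``) because for Poisson
counting statistics it scales as the square root of the fluence, matching
how projection SNR grows with dose.

The module also carries the small dose-budget identities used when planning
a dose-fractionated acquisition: the object contrast parameter, the fluence
needed to see that contrast at a target SNR, the per-projection fluence
after fractionation, and the Crowther angular-sampling count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InvalidInputError

__all__ = [
    "SnrEstimate",
    "estimate_snr",
    "contrast_parameter",
    "fluence_for_contrast",
    "fractionate",
    "crowther_angle_count",
]


@dataclass(frozen=True)
class SnrEstimate:
    """Amplitude SNR inferred from the correlation of two noisy images.

    ``saturated`` flags ``r == 1`` (identical inputs), where the estimator
    diverges and ``snr`` is reported as ``inf``.
    """

    snr: float
    r: float
    n_pixels: int
    saturated: bool = False


def estimate_snr(i1: np.ndarray, i2: np.ndarray) -> SnrEstimate:
    """SNR from two independently noised instances of the same image.

    Correlates over all pixels without masking, so featureless background
    legitimately depresses the estimate — it is the SNR of the frame, not
    of the object.  Negative correlations are clipped to SNR 0.
    """
    a = np.asarray(i1, dtype=float).ravel()
    b = np.asarray(i2, dtype=float).ravel()
    if a.shape != b.shape:
        raise InvalidInputError("images must have the same shape")
    if a.size < 100:
        raise InvalidInputError("need at least 100 pixels for a stable estimate")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant image: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    if r >= 1.0 - 1e-12:
        return SnrEstimate(snr=math.inf, r=1.0, n_pixels=a.size, saturated=True)
    snr = math.sqrt(r / (1.0 - r)) if r > 0.0 else 0.0
    return SnrEstimate(snr=snr, r=r, n_pixels=a.size)


def contrast_parameter(i_max: float, i_min: float) -> float:
    """Object contrast parameter ``|i_max - i_min| / sqrt(i_max + i_min)``.

    For intensities in photon-count units this compares the signal
    difference to the Poisson noise of the summed counts; it is the
    per-photon detectability of the feature.
    """
    if i_min < 0 or i_max < i_min:
        raise InvalidInputError("require i_max >= i_min >= 0")
    if i_max == 0 and i_min == 0:
        raise InvalidInputError("both intensities are zero")
    return abs(i_max - i_min) / math.sqrt(i_max + i_min)


def fluence_for_contrast(theta: float, snr_target: float = 5.0) -> float:
    """Photons/pixel needed to detect contrast ``theta`` at ``snr_target``.

    The feature SNR grows as ``theta * sqrt(fluence)``, so the budget is
    ``(snr_target / theta)**2``.
    """
    if theta <= 0:
        raise InvalidInputError("contrast parameter must be positive")
    return (snr_target / theta) ** 2


def fractionate(total_fluence: float, n_angles: int) -> float:
    """Per-projection fluence when a total budget is split over angles."""
    if total_fluence <= 0 or n_angles <= 0:
        raise InvalidInputError("total fluence and angle count must be positive")
    return total_fluence / n_angles


def crowther_angle_count(width_pixels: float) -> float:
    """Minimum projection count ``(pi/2) * D`` for full angular sampling of
    an object ``D`` pixels wide."""
    if width_pixels <= 0:
        raise InvalidInputError("object width must be positive")
    return math.pi / 2.0 * width_pixels
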