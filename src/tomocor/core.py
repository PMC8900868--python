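"""Domain types and the phase-symmetry center-of-rotation estimator.

In parallel-beam, single-tilt-axis tomography every point of the object
traces a sinusoid in the sinogram ``p(t, theta)``.  Summed over a full
rotation, a point contributes an arcsine-shaped density that is even-symmetric
about the column where the rotation axis projects onto the detector (the
center of rotation, COR).  The same symmetry already holds for the plain sum
of any two projections taken 180 degrees apart (a *reflection pair*): they
sample opposite ends of each point's trajectory.  A continuous object is an
ensemble of points, so its reflection sum is a superposition of even profiles
and remains even about the COR.

If the rotation axis is displaced by ``t'`` pixels from the detector-array
center, the reflection sum is even about ``center + t'`` instead.  By the
Fourier shift theorem this displacement appears as a phase ramp, and the ramp
is read off most reliably at the lowest non-zero spatial frequency, where
object power dominates photon noise.  The estimator here therefore takes a
single 1-D FFT of the reflection sum, extracts the phase ``phi = arctan(I/R)``
at that frequency, and converts it to a pixel shift.  Using ``arctan`` on the
principal branch (rather than ``arctan2``) makes the result independent of
the sign of the signal, i.e. of whether the data are transmission
(bright background, dark object) or emission (dark background, bright
object) images.

The estimator is linear-time, needs only two projections, and is robust at
photon fluences where correlation-based registration starts to fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .exceptions import DegenerateInputError, InvalidInputError

Modality = Literal["transmission", "emission"]

__all__ = [
    "ProjectionImage",
    "Sinogram",
    "ReflectionPair",
    "ThetaSum",
    "CenterEstimate",
    "array_center",
    "theta_sum",
    "reflection_sum",
    "phase_at_fmin",
    "phase_to_shift",
    "find_center_phase_symmetry",
    "normalize_background_edges",
]


def array_center(n_t: int) -> float:
    """Detector-array center in 0-based pixel coordinates: ``(n_t - 1) / 2``.

    All signed COR shifts ``t'`` in this package are measured from this
    point, and all absolute COR columns are ``array_center(n_t) + t'``.
    """
    return (n_t - 1) / 2.0


@dataclass(frozen=True)
class ProjectionImage:
    """A single 2-D detector frame.

    Rows (axis 0) run along the rotation axis (the ``y``/``z`` direction);
    columns (axis 1) run perpendicular to it (the ``t`` direction the COR
    shift lives in).  A 2-D phantom produces single-row frames.
    """

    data: np.ndarray
    theta_deg: float = 0.0
    modality: Modality = "transmission"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise InvalidInputError(f"projection must be 2-D, got ndim={data.ndim}")
        if data.shape[1] < 4:
            raise InvalidInputError("projection needs at least 4 detector columns")
        if not np.all(np.isfinite(data)):
            raise InvalidInputError("projection contains non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def n_y(self) -> int:
        return self.data.shape[0]

    @property
    def n_t(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class Sinogram:
    """Stack of 1-D projections of one slice: rows are angles, columns ``t``."""

    data: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        angles = np.asarray(self.angles_deg, dtype=float)
        if data.ndim != 2:
            raise InvalidInputError("sinogram data must be 2-D")
        if angles.ndim != 1 or len(angles) != data.shape[0]:
            raise InvalidInputError(
                f"angle list length {angles.shape} does not match "
                f"{data.shape[0]} sinogram rows"
            )
        if len(angles) > 1 and not np.all(np.diff(angles) > 0):
            raise InvalidInputError("angles must be strictly increasing")
        if len(angles) > 1 and angles[-1] - angles[0] > 360.0 + 1e-9:
            raise InvalidInputError("angular span exceeds 360 degrees")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "angles_deg", angles)

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    @property
    def n_t(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ReflectionPair:
    """Two projections nominally 180 degrees apart.

    ``delta_theta_deg`` records the departure ``theta2 - theta1 - 180`` from
    a perfect pair.  Non-zero departures are accepted silently: tolerance to
    them is a feature of the estimator, not an error condition.
    """

    p1: ProjectionImage
    p2: ProjectionImage
    delta_theta_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.p1.data.shape != self.p2.data.shape:
            raise InvalidInputError(
                f"pair shapes differ: {self.p1.data.shape} vs {self.p2.data.shape}"
            )
        if self.p1.modality != self.p2.modality:
            raise InvalidInputError("pair members have different modalities")

    @property
    def n_t(self) -> int:
        return self.p1.n_t


@dataclass(frozen=True)
class ThetaSum:
    """Sum of a sinogram (or projection set) over the angle axis."""

    profile: np.ndarray
    n_projections_summed: int
    modality: Modality = "transmission"


@dataclass(frozen=True)
class CenterEstimate:
    """Result of a COR search.

    ``t_prime`` is the signed shift of the rotation axis from the array
    center ``(n_t - 1)/2``; positive means the axis sits at larger ``t``.
    ``cor_absolute`` is the corresponding 0-based detector column.
    """

    t_prime: float
    cor_absolute: float
    method: str
    diagnostics: dict = field(default_factory=dict)


def theta_sum(sinogram: Sinogram) -> ThetaSum:
    """Sum a sinogram over its angle axis.

    For a point object observed over 360 degrees the result approaches the
    arcsine density of its sinusoidal trajectory, even-symmetric about the
    rotation axis.
    """
    if sinogram.data.size == 0:
        raise InvalidInputError("cannot theta-sum an empty sinogram")
    return ThetaSum(
        profile=sinogram.data.sum(axis=0),
        n_projections_summed=sinogram.n_angles,
    )


def reflection_sum(
    pair: ReflectionPair,
    collapse: Literal["rows_collapsed", "flattened"] = "flattened",
) -> tuple[np.ndarray, int]:
    """Element-wise sum of a reflection pair, arranged for the 1-D FFT.

    No mirroring is applied: the raw sum is already even about the COR.
    Two equivalent layouts are offered:

    ``rows_collapsed``
        Detector rows are summed first, giving a length ``n_t`` profile; the
        symmetry phase is then read at FFT bin 1.
    ``flattened``
        The ``(n_y, n_t)`` sum is unravelled row-major into a length
        ``n_y * n_t`` array; the bin with one cycle per detector row is
        ``k = n_y``.  By linearity of the DFT this bin equals bin 1 of the
        collapsed profile exactly, so both modes give identical phases.

    Returns the 1-D array and the frequency-bin index ``k`` at which
    :func:`phase_at_fmin` should be evaluated.
    """
    summed = pair.p1.data + pair.p2.data
    if collapse == "rows_collapsed":
        return summed.sum(axis=0), 1
    if collapse == "flattened":
        return summed.ravel(order="C"), summed.shape[0]
    raise InvalidInputError(f"unknown collapse mode {collapse!r}")


def phase_at_fmin(signal: np.ndarray, k_index: int) -> tuple[float, float, float]:
    """Phase of the DFT of ``signal`` at bin ``k_index``, referenced to the
    array center.

    The DFT coefficient is rotated so that a signal even-symmetric about the
    detector-array center ``(n - 1)/2`` (per period of ``n = len/k`` samples)
    has exactly zero phase.  ``phi`` is then ``arctan(I/R)`` on the principal
    branch ``(-pi/2, pi/2)``: negating the signal negates both ``R`` and
    ``I`` and leaves ``phi`` unchanged, which is what makes the estimator
    polarity-blind (transmission vs emission).

    Returns ``(phi, R, I)`` with ``R``/``I`` the real/imaginary parts of the
    re-centered coefficient.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n <= 2 * k_index or k_index < 1:
        raise InvalidInputError(
            f"signal of length {n} cannot resolve frequency bin {k_index}"
        )
    if np.ptp(signal) == 0:
        raise DegenerateInputError("constant signal has no phase at non-zero bins")
    coeff = complex(np.fft.rfft(signal)[k_index])
    # One period of bin k spans n/k samples; re-reference the phase origin to
    # the center (n/k - 1)/2 of that period, i.e. the detector-array center.
    n_period = n / k_index
    coeff *= np.exp(2j * np.pi * ((n_period - 1) / 2.0) / n_period)
    r, i = float(coeff.real), float(coeff.imag)
    if r == 0.0 and i == 0.0:
        raise DegenerateInputError(
            f"zero spectral magnitude at bin {k_index}: no symmetry signal"
        )
    return float(np.arctan(i / r)) if r != 0.0 else float(np.pi / 2), r, i


def phase_to_shift(phi: float, k_index: int, length: int) -> float:
    """Convert the symmetry phase to a pixel shift ``t'`` of the COR.

    Linear by the shift theorem: ``t' = -phi * length / (2 pi k)``.  The
    global sign is fixed so that positive ``t'`` means the rotation axis lies
    at larger ``t`` than the array center (pinned against shift-recovery
    simulations and frozen in the test suite).  With ``phi`` restricted to
    the principal branch, recoverable shifts satisfy ``|t'| < length/(4 k)``
    (one quarter period); larger offsets wrap.
    """
    if length <= 0 or k_index < 1:
        raise InvalidInputError("length and k_index must be positive")
    return -phi * length / (2.0 * np.pi * k_index)


def find_center_phase_symmetry(
    pair: ReflectionPair,
    collapse: Literal["rows_collapsed", "flattened"] = "flattened",
    k_index: int | None = None,
) -> CenterEstimate:
    """Estimate the COR of a reflection pair from its symmetry phase.

    Composes :func:`reflection_sum`, :func:`phase_at_fmin` and
    :func:`phase_to_shift`.  The caller is responsible for the object being
    fully inside the field of view in both frames; a truncated object breaks
    the even-symmetry argument.

    ``k_index`` overrides the default frequency bin (one cycle per detector
    row) for fidelity experiments; the default realizes the per-row DFT
    average and is degenerate-safe.
    """
    signal, k_default = reflection_sum(pair, collapse=collapse)
    k = k_default if k_index is None else k_index
    phi, r, i = phase_at_fmin(signal, k)
    t_prime = phase_to_shift(phi, k, signal.size)
    n_t = pair.n_t
    return CenterEstimate(
        t_prime=t_prime,
        cor_absolute=array_center(n_t) + t_prime,
        method="phase_symmetry",
        diagnostics={
            "R": r,
            "I": i,
            "phi": phi,
            "k_index": k,
            "f_min": k / signal.size,
        },
    )


def normalize_background_edges(
    p: ProjectionImage, margin: int | None = None
) -> ProjectionImage:
    """Remove a linear illumination ramp so both edge backgrounds match.

    The phase of the lowest spatial frequency is sensitive to illumination
    gradients along ``t``; flat/dark normalization removes most of them, and
    this removes the remainder.  Illumination multiplies the transmitted
    intensity, so the correction is multiplicative: a straight line is fit
    through the mean of the left ``margin`` columns and the mean of the
    right ``margin`` columns (assumed background-only, caller's
    responsibility), the image is divided by it, and the result is rescaled
    to preserve the overall mean.  After correction both edge-background
    means are equal, and a pure linear illumination gradient is removed
    exactly.  An image whose edge means already match is returned
    unchanged.

    ``margin`` defaults to 5% of ``n_t`` (at least 2 columns).
    """
    n_t = p.n_t
    if margin is None:
        margin = max(2, round(0.05 * n_t))
    if 2 * margin >= n_t:
        raise InvalidInputError(f"margin {margin} too wide for {n_t} columns")
    left = float(p.data[:, :margin].mean())
    right = float(p.data[:, -margin:].mean())
    t_left = (margin - 1) / 2.0
    t_right = (n_t - 1) - t_left
    line = left + (right - left) * (np.arange(n_t) - t_left) / (t_right - t_left)
    if np.any(line <= 0):
        raise DegenerateInputError(
            "fitted illumination line is not positive across the frame"
        )
    corrected = p.data / line[np.newaxis, :]
    mean = corrected.mean()
    scale = p.data.mean() / mean if mean != 0 else 1.0
    return ProjectionImage(
        data=corrected * scale,
        theta_deg=p.theta_deg,
        modality=p.modality,
    )
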