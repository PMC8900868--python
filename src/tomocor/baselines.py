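"""Reference COR estimators: sub-pixel phase correlation and the
mirrored-sinogram double-wedge (sinogram FFT) method.

Both are well-established comparison points for the phase-symmetry
estimator in :mod:`tomocor.core`:

* *Phase correlation*: a projection and the t-mirrored copy of its 180°
  counterpart are translated copies of each other, displaced by twice the
  COR error.  The displacement is found from the normalized cross-power
  spectrum, refined to sub-pixel precision with the windowed
  matrix-multiplication DFT (upsampled around the coarse peak rather than
  zero-padding the whole array).
* *Sinogram FFT*: a correctly centered 360° sinogram has its 2-D Fourier
  energy confined to a bow-tie ("double wedge") region whose slope is set
  by the object radius.  A 180° sinogram is mirrored into a 360° one, the
  mirrored half is slid along t, and the shift minimizing the out-of-wedge
  energy locates the axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .core import CenterEstimate, ProjectionImage, ReflectionPair, Sinogram, array_center
from .exceptions import DegenerateInputError, InvalidInputError, ScanBoundaryError

__all__ = [
    "SubpixelConfig",
    "WedgeMask",
    "mirror_t",
    "find_center_phase_correlation",
    "build_mirrored_360",
    "make_wedge_mask",
    "double_wedge_metric",
    "find_center_sinogram_fft",
]


@dataclass(frozen=True)
class SubpixelConfig:
    """Sub-pixel refinement settings for phase correlation.

    ``upsample_factor`` m gives 1/m-pixel resolution.  The refinement
    window half-width is tied to the upsampled-DFT region actually
    evaluated around the coarse peak, ``ceil(1.5 m) / m`` pixels.
    """

    upsample_factor: int = 10

    def __post_init__(self) -> None:
        if self.upsample_factor < 1:
            raise InvalidInputError("upsample factor must be >= 1")

    @property
    def window_halfwidth(self) -> float:
        return math.ceil(1.5 * self.upsample_factor) / self.upsample_factor


def mirror_t(p: ProjectionImage) -> ProjectionImage:
    """Reverse the detector columns (mirror about column ``(n_t - 1)/2``)."""
    return ProjectionImage(
        data=p.data[:, ::-1].copy(), theta_deg=p.theta_deg, modality=p.modality
    )


def find_center_phase_correlation(
    pair: ReflectionPair, cfg: SubpixelConfig | None = None
) -> CenterEstimate:
    """COR from sub-pixel phase correlation of a mirrored reflection pair.

    The second projection is mirrored about the t axis, then registered
    against the first using only the phase of the cross-power spectrum.
    The registered translation along t is twice the COR error; half of it
    is reported as ``t_prime``.  The translation along the row axis is a
    sample-drift diagnostic and is reported but never applied.
    """
    cfg = cfg or SubpixelConfig()
    ref = pair.p1.data
    mov = mirror_t(pair.p2).data
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise DegenerateInputError("constant image: no correlation peak")
    shift, error, _ = phase_cross_correlation(
        ref, mov, upsample_factor=cfg.upsample_factor, normalization="phase"
    )
    t_prime = float(shift[1]) / 2.0
    return CenterEstimate(
        t_prime=t_prime,
        cor_absolute=array_center(pair.n_t) + t_prime,
        method="phase_correlation",
        diagnostics={
            "y_drift": float(shift[0]),
            "upsample_factor": cfg.upsample_factor,
            "registration_error": float(error),
        },
    )


def build_mirrored_360(s: Sinogram) -> Sinogram:
    """Extend a 180° sinogram to 360° by appending its t-mirrored copy.

    A projection at ``theta + 180`` equals the ``theta`` projection mirrored
    about the rotation axis; mirroring about the *array* center instead
    leaves a residual shift of twice the COR error, which is what
    :func:`find_center_sinogram_fft` exploits.
    """
    n = s.n_angles
    span = float(s.angles_deg[-1] - s.angles_deg[0]) if n > 1 else 0.0
    step = span / (n - 1) if n > 1 else 180.0
    if n > 1 and not (180.0 - 1.5 * step) <= span <= 180.0 + 0.5 * step:
        raise InvalidInputError(
            f"sinogram spans {span:.2f} degrees; need ~180 (within one step)"
        )
    data = np.vstack([s.data, s.data[:, ::-1]])
    angles = np.concatenate([s.angles_deg, s.angles_deg + 180.0])
    return Sinogram(data=data, angles_deg=angles)


@dataclass(frozen=True)
class WedgeMask:
    """Out-of-wedge selector in the 2-D Fourier plane of a 360° sinogram.

    ``mask[n, q]`` is True where angular harmonic ``n`` (cycles per turn)
    exceeds ``slope * |q| + pad`` for t-frequency bin ``q`` — i.e. outside
    the bow-tie support a centered sinogram should occupy.  Symmetric under
    negating both frequency axes by construction.
    """

    mask: np.ndarray
    slope: float

    def __post_init__(self) -> None:
        if self.mask.dtype != bool or self.mask.ndim != 2:
            raise InvalidInputError("wedge mask must be a boolean 2-D array")


def make_wedge_mask(
    n_angles: int,
    n_t: int,
    object_radius: float | None = None,
    pad: float = 2.0,
) -> WedgeMask:
    """Double-wedge mask for an ``(n_angles, n_t)`` sinogram spectrum.

    A point at radius r contributes angular harmonics up to about
    ``r * omega`` at t-frequency ``omega`` (rad/px), so the wedge slope in
    (harmonic, bin) units is ``2 pi r / n_t``.  ``object_radius`` defaults
    to ``n_t / 2`` (object filling the field of view); ``pad`` keeps a few
    harmonics around DC out of the metric.
    """
    radius = n_t / 2.0 if object_radius is None else object_radius
    slope = 2.0 * math.pi * radius / n_t
    n = np.fft.fftfreq(n_angles) * n_angles  # signed harmonic index
    q = np.fft.fftfreq(n_t) * n_t  # signed t-frequency bin
    mask = np.abs(n)[:, None] > slope * np.abs(q)[None, :] + pad
    return WedgeMask(mask=mask, slope=slope)


def double_wedge_metric(s360: Sinogram, mask: WedgeMask) -> float:
    """Mean spectral magnitude outside the double wedge.

    Low values mean the sinogram is consistent with a centered rotation
    axis; the metric is insensitive to the sign and scale of the data
    (magnitudes only).
    """
    if mask.mask.shape != s360.data.shape:
        raise InvalidInputError(
            f"mask shape {mask.mask.shape} does not match sinogram "
            f"{s360.data.shape}"
        )
    if not mask.mask.any():
        raise InvalidInputError("mask selects no bins")
    spectrum = np.abs(np.fft.fft2(s360.data))
    return float(spectrum[mask.mask].mean())


def find_center_sinogram_fft(
    s: Sinogram,
    search_halfwidth: int = 20,
    object_radius: float | None = None,
) -> CenterEstimate:
    """COR from the double-wedge energy of a mirrored 360° sinogram.

    The mirrored half is cyclically shifted along t by every integer in
    ``[-search_halfwidth, search_halfwidth]``; the shift minimizing the
    out-of-wedge energy is refined by a parabola through the three metric
    values around the minimum.  The optimal mirrored-half shift is twice
    the COR error.  Cyclic (Fourier) shifting keeps the metric smooth in
    the shift but assumes the object does not touch the frame edges.
    """
    if search_halfwidth < 1 or search_halfwidth >= s.n_t // 4:
        raise InvalidInputError("search halfwidth must be in [1, n_t/4)")
    top = s.data
    mirrored = s.data[:, ::-1]
    mask = make_wedge_mask(2 * s.n_angles, s.n_t, object_radius=object_radius)
    angles360 = np.concatenate([s.angles_deg, s.angles_deg + 180.0])
    shifts = np.arange(-search_halfwidth, search_halfwidth + 1)
    metrics = np.empty(shifts.size)
    for j, u in enumerate(shifts):
        s360 = Sinogram(
            data=np.vstack([top, np.roll(mirrored, int(u), axis=1)]),
            angles_deg=angles360,
        )
        metrics[j] = double_wedge_metric(s360, mask)
    best = int(np.argmin(metrics))
    if best == 0 or best == shifts.size - 1:
        raise ScanBoundaryError(
            f"metric minimum at scan edge (shift {shifts[best]}); "
            "increase search_halfwidth"
        )
    # Parabolic vertex through the three best integer shifts.
    y0, y1, y2 = metrics[best - 1 : best + 2]
    denom = y0 - 2.0 * y1 + y2
    frac = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    u_star = shifts[best] + frac
    t_prime = u_star / 2.0
    return CenterEstimate(
        t_prime=float(t_prime),
        cor_absolute=array_center(s.n_t) + float(t_prime),
        method="sinogram_fft",
        diagnostics={
            "best_integer_shift": int(shifts[best]),
            "metric_min": float(metrics[best]),
            "wedge_slope": mask.slope,
        },
    )
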