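"""Quantifying radiation-induced structural change across a dose series.

A dose series is a list of reconstructions of the same object at strictly
increasing cumulative doses, registered to a common frame. The quantities of
interest are the total electron count inside the object (its integral over
the support), fractional electron loss per step, mean-density trajectories of
fixed rectangular regions, and vertically averaged lateral density profiles.
All fractional quantities are independent of the electrons-per-intensity-unit
calibration, which cancels in the ratios.

Negative pixel values that survive reconstruction are kept in every sum (not
clipped), so totals are unbiased; the non-negativity constraint mode of the
phasing engine makes them rare.
"""

from __future__ import annotations

import numpy as np

from .clustering import align_to_reference
from .types import DoseSeries, Reconstruction, RegionSpec

__all__ = [
    "total_electrons",
    "electron_loss_series",
    "region_density_series",
    "lateral_profile",
    "register_series",
    "calibration_from_dc",
]


def _real(image: np.ndarray) -> np.ndarray:
    return np.abs(image) if np.iscomplexobj(image) else np.asarray(image, dtype=float)


def total_electrons(
    reconstruction: Reconstruction | np.ndarray,
    support: np.ndarray | None = None,
    calibration: float = 1.0,
) -> float:
    """Electron count: ``calibration x sum(image)`` over the support."""
    if calibration <= 0:
        raise ValueError("calibration must be positive")
    if isinstance(reconstruction, Reconstruction):
        image = reconstruction.image
        if support is None:
            support = reconstruction.support
    else:
        image = reconstruction
    img = _real(image)
    if support is None:
        support = np.ones(img.shape, dtype=bool)
    return float(calibration * img[support].sum())


def calibration_from_dc(dc_intensity: float, image_sum: float) -> float:
    """Electrons per image unit from the measured zero-frequency intensity.

    The DC Fourier amplitude of the electron-density map equals the total
    electron count, so ``sqrt(I(0)) / sum(image)`` calibrates image units.
    Usable only when the DC pixel was actually measured.
    """
    if dc_intensity < 0 or image_sum <= 0:
        raise ValueError("need non-negative DC intensity and positive image sum")
    return float(np.sqrt(dc_intensity) / image_sum)


def electron_loss_series(series: DoseSeries) -> np.ndarray:
    """Fractional electron change per step, ``(E_t - E_0) / E_0``.

    Step 0 is 0 by construction; calibration cancels.
    """
    if len(series) < 2:
        raise ValueError("series needs at least two members")
    support = series.reconstructions[0].support
    totals = np.array(
        [total_electrons(r, support, series.calibration) for r in series.reconstructions]
    )
    if totals[0] == 0:
        raise ZeroDivisionError("step 0 has zero electrons")
    return (totals - totals[0]) / totals[0]


def region_density_series(series: DoseSeries, region: RegionSpec) -> np.ndarray:
    """Mean calibrated density of a fixed rectangle at every step."""
    shape = series.reconstructions[0].shape
    region.check_bounds(shape)
    sl = region.slices()
    return np.array(
        [series.calibration * _real(r.image)[sl].mean() for r in series.reconstructions]
    )


def lateral_profile(
    reconstruction: Reconstruction | np.ndarray, region: RegionSpec
) -> np.ndarray:
    """Column-wise mean density across a region's rows (length = width)."""
    image = (
        reconstruction.image
        if isinstance(reconstruction, Reconstruction)
        else reconstruction
    )
    img = _real(image)
    region.check_bounds(img.shape)
    return img[region.slices()].mean(axis=0)


def register_series(series: DoseSeries, reference: np.ndarray | None = None) -> DoseSeries:
    """Align every member to a common frame by integer-shift/twin registration.

    Member 0 is the reference unless an explicit ``reference`` image is given
    (e.g. a ground-truth phantom in simulation studies), in which case member
    0 is aligned too.
    """
    if len(series) < 2:
        raise ValueError("series needs at least two members")
    recons = series.reconstructions
    out = []
    if reference is None:
        ref = recons[0].image
        out.append(recons[0].copy())
        rest = recons[1:]
    else:
        ref = reference
        rest = recons
    for r in rest:
        aligned = align_to_reference(r.image, ref)
        out.append(Reconstruction(aligned, r.support, r.error_history, r.seed))
    return DoseSeries(
        reconstructions=out, doses=list(series.doses), calibration=series.calibration
    )
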