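"""Synthetic speckle experiment.

Emulates a plane-wave CDI measurement of a weakly scattering organelle:
an oversampled compact phantom with internal high- and low-density regions,
far-field diffraction, Poisson photon noise, a (possibly off-centre) beamstop
whose shadow is partially refilled by Friedel centrosymmetry, and detector
binning followed by contrast-restoring deconvolution.

The dose-degradation series reproduces the qualitative radiation-damage
phenomenology of soft biomaterials: dense regions lose electron density
monotonically, while sparse regions transiently gain density (radiation-driven
aggregation) before collapsing.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import ndimage

from ._fft import fft2c, ifft2c, friedel_partner
from .types import DiffractionPattern, DoseParams, ExposureSchedule, Phantom

__all__ = [
    "make_phantom",
    "simulate_damage_series",
    "diffract",
    "diffract_series",
    "add_poisson_noise",
    "apply_beamstop_and_symmetrize",
    "bin_and_deconvolve",
    "deconvolve_box",
    "total_exposure",
    "absorbed_dose",
    "DEFAULT_PIXEL_NM",
    "DEFAULT_PHOTON_BUDGET",
]

#: Real-space sampling matched to a 5.5 keV / 1.496 m / 60 um (3x3-binned)
#: detector geometry at a 411-pixel grid: lambda * z / (N * p) ~ 13.7 nm.
DEFAULT_PIXEL_NM = 13.7

#: Photons per simulated pattern. Low-count regime: speckle visible, shot
#: noise clearly dominant at high frequency.
DEFAULT_PHOTON_BUDGET = 1.0e6

_KEV_TO_J = 1.602176634e-16


def make_phantom(
    seed: int,
    grid_size: int = 128,
    object_fraction: float = 0.08,
    n_blobs: int = 6,
    density_range: tuple[float, float] = (0.3, 1.0),
    pixel_nm: float = DEFAULT_PIXEL_NM,
    aspect: float = 1.8,
) -> Phantom:
    """Generate a compact elongated phantom with internal density structure.

    The envelope is a randomly oriented, boundary-perturbed ellipse whose area
    is ``object_fraction`` of the grid; its interior holds ``n_blobs`` smooth
    Gaussian blobs affinely mapped onto ``density_range``, giving distinct
    high- and low-density areas. With ``n_blobs=0`` the interior is uniform at
    the midpoint of ``density_range``.

    Raises
    ------
    ValueError
        If the envelope cannot fit inside half the grid extent per axis
        (oversampling would be violated).
    """
    if grid_size < 64:
        raise ValueError("grid_size must be >= 64")
    if not 0 < object_fraction <= 0.25:
        raise ValueError("object_fraction must lie in (0, 0.25]")
    d_lo, d_hi = density_range
    if not 0 <= d_lo < d_hi:
        raise ValueError("density_range must be increasing and non-negative")

    rng = np.random.default_rng(seed)
    n = grid_size
    # semi-axes for an ellipse of the requested area with the given aspect
    b_ax = math.sqrt(object_fraction * n * n / (math.pi * aspect))
    a_ax = aspect * b_ax
    if 2.0 * a_ax > n / 2.0:
        raise ValueError(
            "object_fraction too large for 2x linear oversampling at this aspect"
        )

    theta = rng.uniform(0, math.pi)
    ct, st = math.cos(theta), math.sin(theta)
    yy, xx = np.mgrid[0:n, 0:n]
    yc = yy - n / 2 + rng.uniform(-2, 2)
    xc = xx - n / 2 + rng.uniform(-2, 2)
    u = ct * xc + st * yc
    v = -st * xc + ct * yc
    r_ell = np.hypot(u / a_ax, v / b_ax)

    # low-order angular wobble of the boundary (keeps area within a few %)
    phi = np.arctan2(v, u)
    wob = np.zeros_like(phi)
    for m in (2, 3, 5):
        wob += rng.uniform(-0.04, 0.04) * np.cos(m * phi + rng.uniform(0, 2 * math.pi))
    support = r_ell <= 1.0 + wob

    if n_blobs == 0:
        density = np.where(support, 0.5 * (d_lo + d_hi), 0.0)
        return Phantom(density, pixel_nm, support)

    field = np.zeros((n, n))
    inside = np.argwhere(support)
    for k in range(n_blobs):
        cy, cx = inside[rng.integers(len(inside))]
        sig = rng.uniform(0.15, 0.4) * b_ax
        amp = rng.uniform(0.5, 1.0) * (1 if k % 2 == 0 else -1)
        field += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2)))
    field = ndimage.gaussian_filter(field, sigma=1.0)

    vals = field[support]
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-12:
        density = np.where(support, 0.5 * (d_lo + d_hi), 0.0)
    else:
        density = np.zeros((n, n))
        density[support] = d_lo + (d_hi - d_lo) * (vals - lo) / (hi - lo)
    return Phantom(density, pixel_nm, support)


def simulate_damage_series(
    phantom: Phantom,
    n_steps: int = 4,
    high_decay: float = 0.08,
    low_swell: float = 0.35,
    swell_peak_step: int = 2,
    seed: int = 0,
) -> list[Phantom]:
    """Dose-degradation series of ``n_steps`` phantoms (step 0 = input).

    Damage is cumulative: every step applies fresh change on top of the
    previous step, never undoing earlier change, so the object moves
    monotonically away from step 0 (the behaviour behind steadily decreasing
    pattern cross-correlations). Pixels above the support's 75th density
    percentile decay multiplicatively by a mean factor ``(1 - high_decay)``
    per step, with a fresh, spatially uneven profile each step (different
    parts of the dense material degrade at different rates).
    Pixels below the 25th percentile gain a fresh additive blob field
    (aggregation) each step up to ``swell_peak_step``, raising the region
    mean linearly to ``1 + low_swell`` times its start; after the peak the
    whole non-high interior collapses instead — a multiplicative loss whose
    spatial profile is part uniform, part fresh random blobs — bringing the
    low-region mean back down. Region masks are frozen
    at step 0, so the contracts (high mean non-increasing, low mean unimodal
    with peak at ``swell_peak_step``) hold exactly; the support never changes.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if not (0 <= high_decay < 1 and 0 <= low_swell < 1):
        raise ValueError("high_decay and low_swell must lie in [0, 1)")
    swell_peak_step = int(np.clip(swell_peak_step, 1, n_steps - 1))

    rng = np.random.default_rng(seed)
    dens0 = phantom.density
    sup = phantom.support
    vals = dens0[sup]
    hi_thr = np.percentile(vals, 75)
    lo_thr = np.percentile(vals, 25)
    high_mask = sup & (dens0 >= hi_thr)
    low_mask = sup & (dens0 <= lo_thr) & ~high_mask

    soft_mask = sup & ~high_mask  # everything that may collapse post-peak

    yy, xx = np.mgrid[0 : phantom.shape[0], 0 : phantom.shape[1]]

    def _blob_profile(
        region: np.ndarray, n_blobs: int = 3, sig_range: tuple = (2.0, 5.0)
    ) -> np.ndarray:
        """Fresh smooth non-negative blob profile confined to ``region``."""
        pts = np.argwhere(region)
        field = np.zeros(phantom.shape)
        for _ in range(n_blobs):
            cy, cx = pts[rng.integers(len(pts))]
            sig = rng.uniform(*sig_range)
            field += np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2)))
        field *= region
        peak = field[region].max()
        return field / peak if peak > 0 else field

    base_low = dens0[low_mask].mean() if low_mask.any() else 0.0
    per_step_gain = (
        low_swell * base_low / swell_peak_step if low_swell > 0 else 0.0
    )
    tail = max(1, n_steps - 1 - swell_peak_step)
    collapse_rate = min(0.9, 1.5 * low_swell / tail)

    series = [phantom.copy()]
    dens = dens0.copy()
    for t in range(1, n_steps):
        dens = dens.copy()
        if high_mask.any() and high_decay > 0:
            hprofile = np.where(high_mask, 0.5, 0.0) + _blob_profile(high_mask)
            hscale = high_decay / max(hprofile[high_mask].mean(), 1e-12)
            dens[high_mask] *= np.clip(1.0 - hscale * hprofile[high_mask], 0.0, 1.0)
        if low_mask.any() and low_swell > 0:
            if t <= swell_peak_step:
                blobs = _blob_profile(low_mask)
                mean = blobs[low_mask].mean()
                if mean > 0:
                    dens[low_mask] += per_step_gain * blobs[low_mask] / mean
            else:
                # part uniform, part fresh blobs, part rim erosion, over the
                # soft interior: the uniform floor guarantees a strict
                # low-mean decrease, the blobs keep the structural change
                # moving in new directions, and the rim term thins the
                # envelope (the strongest low-frequency signature of
                # late-stage damage)
                rim = sup & ~ndimage.binary_erosion(sup, np.ones((5, 5)))
                profile = (
                    np.where(soft_mask, 0.5, 0.0)
                    + _blob_profile(soft_mask)
                    + np.where(rim & soft_mask, 1.0, 0.0)
                )
                scale = collapse_rate / max(profile[low_mask].mean(), 1e-12)
                dens[soft_mask] *= np.clip(1.0 - scale * profile[soft_mask], 0.0, 1.0)
                # near-zero-mean redistribution of the mid-density interior:
                # large structural change, little electron change, and no
                # effect on the high/low region-mean contracts
                mid_mask = soft_mask & ~low_mask
                if mid_mask.any():
                    shake = _blob_profile(mid_mask, sig_range=(3.0, 8.0)) - _blob_profile(
                        mid_mask, sig_range=(3.0, 8.0)
                    )
                    shake[mid_mask] -= shake[mid_mask].mean()
                    sd = shake[mid_mask].std()
                    if sd > 0:
                        amp = 0.5 * low_swell * dens[mid_mask].mean() / sd
                        dens[mid_mask] = np.clip(
                            dens[mid_mask] + amp * shake[mid_mask], 0.0, None
                        )
        series.append(Phantom(dens, phantom.pixel_nm, sup.copy()))
    return series


def diffract(phantom: Phantom) -> DiffractionPattern:
    """Noiseless far-field diffraction intensity of a phantom.

    Intensity is the squared magnitude of the centred 2-D DFT of the density;
    every pixel is valid. Parseval: ``sum(I) == n_pixels * sum(density**2)``.
    The frequency increment is the full-period frequency step
    ``1 / (N * pixel)`` expressed in inverse micrometres.
    """
    n = phantom.shape[0]
    if phantom.oversampling_ratio < 4:  # 2x per axis
        raise ValueError("phantom violates the oversampling invariant")
    amp = fft2c(phantom.density)
    intensity = np.abs(amp) ** 2
    freq_per_pixel = 1.0 / (n * phantom.pixel_nm * 1e-3)  # um^-1
    return DiffractionPattern(
        intensity=intensity,
        valid=np.ones(phantom.shape, dtype=bool),
        freq_per_pixel=freq_per_pixel,
    )


def diffract_series(
    series: list[Phantom],
    photon_budget: float = DEFAULT_PHOTON_BUDGET,
    seed: int = 0,
    stop_halfwidth: int | tuple[int, int] | None = None,
    stop_offset: tuple[int, int] = (0, 0),
    bin_factor: int = 1,
) -> list[DiffractionPattern]:
    """Noisy patterns for a dose series under equal-exposure acquisition.

    ``photon_budget`` is the expected total count for step 0; later steps
    receive budgets scaled by their relative total scattering power, the way
    equal exposures of a fading sample do. Keeping this relative scale is
    what lets electron totals and region densities be compared across the
    series after reconstruction. An optional beamstop (with Friedel refill)
    and detector binning are applied per pattern.
    """
    clean = [diffract(ph) for ph in series]
    total0 = clean[0].intensity.sum()
    out = []
    for i, pat in enumerate(clean):
        budget = photon_budget * pat.intensity.sum() / total0
        noisy = add_poisson_noise(pat, budget, seed=seed + i)
        if stop_halfwidth:
            noisy = apply_beamstop_and_symmetrize(noisy, stop_halfwidth, stop_offset)
        if bin_factor > 1:
            noisy = bin_and_deconvolve(noisy, bin_factor)
        out.append(noisy)
    return out


def add_poisson_noise(
    pattern: DiffractionPattern,
    photon_budget: float = DEFAULT_PHOTON_BUDGET,
    seed: int = 0,
) -> DiffractionPattern:
    """Rescale total intensity to ``photon_budget`` and draw Poisson counts."""
    if photon_budget <= 0:
        raise ValueError("photon_budget must be positive")
    total = pattern.intensity.sum()
    if total <= 0:
        raise ValueError("pattern has no intensity to scale")
    lam = pattern.intensity * (photon_budget / total)
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(lam).astype(float)
    out = pattern.copy()
    out.intensity = noisy
    return out


def apply_beamstop_and_symmetrize(
    pattern: DiffractionPattern,
    stop_halfwidth: int | tuple[int, int],
    stop_offset: tuple[int, int] = (0, 0),
) -> DiffractionPattern:
    """Block a rectangular beamstop region, then refill by Friedel symmetry.

    Pixels under the stop are invalidated; each invalid pixel whose Friedel
    partner is valid takes the partner's intensity and becomes valid again.
    The remaining invalid set is centrosymmetric by construction.
    """
    n, m = pattern.shape
    if np.isscalar(stop_halfwidth):
        hr = hc = int(stop_halfwidth)
    else:
        hr, hc = (int(v) for v in stop_halfwidth)
    ci, cj = n // 2 + int(stop_offset[0]), m // 2 + int(stop_offset[1])
    if 2 * hr + 1 >= n or 2 * hc + 1 >= m:
        raise ValueError("beamstop must be smaller than the grid")

    stop = np.zeros((n, m), dtype=bool)
    stop[max(0, ci - hr) : ci + hr + 1, max(0, cj - hc) : cj + hc + 1] = True

    out = pattern.copy()
    out.valid &= ~stop
    part = friedel_partner(pattern.shape)
    partner_valid = out.valid[part]
    partner_intensity = out.intensity[part]
    recover = ~out.valid & partner_valid
    out.intensity[recover] = partner_intensity[recover]
    out.valid |= recover
    return out


def bin_and_deconvolve(
    pattern: DiffractionPattern,
    b: int = 3,
    deconvolve: bool = True,
    deconv_threshold: float = 0.1,
    crop: int | None = None,
) -> DiffractionPattern:
    """Sum ``b x b`` detector blocks, then undo the contrast loss.

    Binning sums blocks (a block is valid only if every member is); this is a
    box convolution of the intensity followed by subsampling, which damps the
    speckle contrast. The deconvolution divides the binned pattern, in its
    conjugate (autocorrelation) domain, by the box transfer function wherever
    its magnitude exceeds ``deconv_threshold``, leaving it untouched at the
    transfer-function zeros to avoid noise blow-up.

    ``crop`` optionally fixes the binned grid size per axis (which otherwise
    defaults to the largest even size that fits); the crop is centred on the
    DC pixel so the centred-spectrum convention survives binning.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if b == 1:
        return pattern.copy()
    n, m = pattern.shape
    if b > min(n, m):
        raise ValueError("bin factor exceeds grid size")

    def _sizes(N: int) -> int:
        M = N // b
        if M % 2 == 1:
            M -= 1
        return M

    mr, mc = _sizes(n), _sizes(m)
    if crop is not None:
        if crop > min(mr, mc) or crop < 2 or crop % 2:
            raise ValueError("crop must be an even size within the binned grid")
        mr = mc = int(crop)
    r0 = n // 2 - b * (mr // 2)
    c0 = m // 2 - b * (mc // 2)
    sub_i = pattern.intensity[r0 : r0 + b * mr, c0 : c0 + b * mc]
    sub_v = pattern.valid[r0 : r0 + b * mr, c0 : c0 + b * mc]
    binned = sub_i.reshape(mr, b, mc, b).sum(axis=(1, 3))
    valid = sub_v.reshape(mr, b, mc, b).all(axis=(1, 3))

    intensity = binned
    if deconvolve:
        # small negative excursions from the regularized division are clipped
        # to keep intensities physical
        intensity = np.maximum(
            deconvolve_box(binned, valid, b, deconv_threshold), 0.0
        )

    return DiffractionPattern(
        intensity=intensity,
        valid=valid,
        freq_per_pixel=pattern.freq_per_pixel * b,
        photon_energy_kev=pattern.photon_energy_kev,
        detector_distance_m=pattern.detector_distance_m,
        detector_pixel_um=pattern.detector_pixel_um,
        binning=pattern.binning * b,
    )


def deconvolve_box(
    binned: np.ndarray, valid: np.ndarray, b: int, threshold: float = 0.1
) -> np.ndarray:
    """Undo the contrast loss of ``b x b`` binning (no clipping).

    Divides the binned pattern, in its conjugate (autocorrelation) domain, by
    the box transfer function wherever its magnitude exceeds ``threshold``;
    frequencies at the transfer-function zeros are left unchanged. Exact
    inverse of the box convolution on the retained frequencies: multiplying
    the result's conjugate spectrum back by the transfer function recovers
    the binned spectrum there.
    """
    mr, mc = binned.shape
    t2 = np.outer(_box_transfer(mr, b), _box_transfer(mc, b))
    conj = fft2c(np.where(valid, binned, 0.0))
    safe = np.abs(t2) > threshold
    conj = np.where(safe, conj / np.where(safe, t2, 1.0), conj)
    return ifft2c(conj).real


def _box_transfer(M: int, b: int) -> np.ndarray:
    """Normalized transfer function of a length-``b`` box, sampled on the
    centred conjugate grid of a length-``M`` binned axis."""
    u = np.arange(M) - M // 2
    nu = u / (M * b)  # cycles per fine-grid sample
    out = np.ones(M)
    nz = u != 0
    out[nz] = np.sin(np.pi * b * nu[nz]) / (b * np.sin(np.pi * nu[nz]))
    return out


def total_exposure(schedule: ExposureSchedule | Sequence[tuple[float, int]]) -> float:
    """Total exposure time in seconds: sum of (seconds x count) entries."""
    if not isinstance(schedule, ExposureSchedule):
        schedule = ExposureSchedule(list(schedule))
    return float(sum(sec * count for sec, count in schedule.entries))


def absorbed_dose(
    params: DoseParams, exposure_seconds: float, flux_density: float
) -> float:
    """Absorbed dose in grays from a uniform-illumination estimate.

    ``flux_density`` is in photons um^-2 s^-1. The dose is
    ``fluence x photon energy x mass-attenuation coefficient`` with fluence
    ``flux_density * exposure_seconds``; it is therefore additive over
    consecutive exposures.
    """
    if exposure_seconds < 0 or flux_density < 0:
        raise ValueError("exposure and flux must be non-negative")
    fluence_m2 = flux_density * exposure_seconds * 1e12  # photons / m^2
    energy_j = params.photon_energy_kev * _KEV_TO_J
    mu_m2_kg = params.mass_attenuation_cm2_g * 0.1
    return fluence_m2 * energy_j * mu_m2_kg
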