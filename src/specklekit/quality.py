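"""Resolution and consistency metrics for CDI reconstructions.

The central quantity is the phase-retrieval transfer function (PRTF): per
resolution shell, the ratio of the Fourier amplitude of the *average* of
independent reconstructions to the measured amplitude. Where the retrieved
phases are reproducible the ratio stays near 1; where they are random the
average destructively interferes and the ratio falls to the ``1/sqrt(N)``
floor (~0.2 for N = 24). Because shot noise makes the raw PRTF rise
spuriously at high frequency, it is damped by a Wiener weight
``W = S/(S+N)`` built from the pattern's power spectral density and a
constant noise floor; the resolution is read where the weighted curve (wPRTF)
first drops below 1/e.

Shell statistics always exclude invalid (missing) pixels rather than imputing
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._fft import fft2c, radius_grid
from .types import Curve, DiffractionPattern, ReconstructionSet, ShellMap

__all__ = [
    "build_shells",
    "prtf",
    "prtf_random_floor",
    "power_spectral_density",
    "estimate_noise_floor",
    "wiener_weight",
    "wprtf",
    "resolution_from_curve",
    "ResolutionResult",
    "amplitude_variance",
    "shell_cc",
    "global_cc",
    "band_scale",
]

ONE_OVER_E = 1.0 / math.e


def build_shells(
    shape: tuple[int, int], freq_per_pixel: float, shell_width: int = 1
) -> ShellMap:
    """Concentric annuli about the DC pixel, up to the Nyquist radius.

    Shell ``j`` collects pixels with radius in ``[j*w, (j+1)*w)`` pixels; its
    centre frequency is ``(j + 1/2) * w * freq_per_pixel``. Pixels beyond the
    Nyquist radius (``min(shape)//2``) carry index -1.
    """
    if shell_width < 1:
        raise ValueError("shell_width must be >= 1 pixel")
    r = radius_grid(shape)
    nyq = min(shape) // 2
    index = np.where(r < nyq, (r / shell_width).astype(int), -1)
    n_shells = int(index.max()) + 1
    counts = np.bincount(index[index >= 0].ravel(), minlength=n_shells)
    centre = (np.arange(n_shells) + 0.5) * shell_width * freq_per_pixel
    return ShellMap(
        index=index,
        centre_freq=centre,
        counts=counts,
        freq_per_pixel=freq_per_pixel,
        shell_width=shell_width,
    )


def _shell_reduce(
    values: np.ndarray, include: np.ndarray, shells: ShellMap, statistic: str = "mean"
) -> np.ndarray:
    """Per-shell mean (or RMS) of ``values`` over the ``include`` pixels;
    shells with no included pixels come back NaN."""
    idx = shells.index[include]
    vals = values[include]
    n = np.bincount(idx, minlength=shells.n_shells).astype(float)
    if statistic == "rms":
        s = np.bincount(idx, weights=vals**2, minlength=shells.n_shells)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.sqrt(s / n)
    elif statistic == "mean":
        s = np.bincount(idx, weights=vals, minlength=shells.n_shells)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = s / n
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    out[n == 0] = np.nan
    return out


def prtf(
    average_image: np.ndarray,
    pattern: DiffractionPattern,
    shells: ShellMap | None = None,
    statistic: str = "mean",
    amp_floor_frac: float = 1e-6,
) -> Curve:
    """Phase-retrieval transfer function of an averaged reconstruction.

    Per shell: the ``statistic`` ("mean" or "rms") of the per-pixel ratios
    ``|F(average_image)| / sqrt(I)`` over valid pixels. Pixels whose measured
    amplitude falls below ``amp_floor_frac`` of the maximum are excluded to
    avoid division blow-up. Shells without usable pixels are NaN (flagged in
    ``meta``), and values above 1 (possible through noise) are reported, not
    clipped.
    """
    if average_image.shape != pattern.shape:
        raise ValueError("image and pattern shapes differ")
    if shells is None:
        shells = build_shells(pattern.shape, pattern.freq_per_pixel)
    amp = np.sqrt(np.where(pattern.valid, pattern.intensity, 0.0))
    floor = amp_floor_frac * amp.max()
    include = pattern.valid & (amp > floor) & (shells.index >= 0)
    model = np.abs(fft2c(average_image))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(include, model / np.where(include, amp, 1.0), 0.0)
    y = _shell_reduce(ratio, include, shells, statistic=statistic)
    return Curve(
        f=shells.centre_freq,
        y=y,
        kind="PRTF",
        meta={
            "statistic": statistic,
            "n_empty_shells": int(np.isnan(y).sum()),
            "n_shells_above_1": int(np.nansum(y > 1)),
        },
    )


def prtf_random_floor(n_members: int = 24, n_bins: int = 10000, seed: int = 0) -> float:
    """Expected PRTF floor for fully unconverged phases, by Monte Carlo.

    For each frequency bin, ``n_members`` unit-amplitude phasors with i.i.d.
    uniform phases are averaged; the RMS magnitude of the per-bin averages is
    returned. Analytically this tends to ``1/sqrt(n_members)`` (~0.204 for
    24), the floor quoted for PRTF curves of N averaged reconstructions.
    """
    if n_members < 2 or n_bins < 1:
        raise ValueError("need n_members >= 2 and n_bins >= 1")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=(n_members, n_bins))
    mean_phasor = np.exp(1j * phases).mean(axis=0)
    return float(np.sqrt(np.mean(np.abs(mean_phasor) ** 2)))


def power_spectral_density(
    pattern: DiffractionPattern, shells: ShellMap | None = None
) -> Curve:
    """Shell-averaged intensity (the pattern's radial power spectrum)."""
    if shells is None:
        shells = build_shells(pattern.shape, pattern.freq_per_pixel)
    include = pattern.valid & (shells.index >= 0)
    y = _shell_reduce(pattern.intensity, include, shells)
    return Curve(f=shells.centre_freq, y=y, kind="psd")


def estimate_noise_floor(
    pattern: DiffractionPattern,
    shells: ShellMap | None = None,
    tail_fraction: float = 0.1,
) -> float:
    """Constant noise level: median shell-mean intensity over the outermost
    ``tail_fraction`` of shells, where the PSD of a shot-noise-limited
    pattern flattens."""
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must lie in (0, 0.5)")
    psd = power_spectral_density(pattern, shells)
    defined = ~np.isnan(psd.y)
    tail = max(1, int(round(tail_fraction * defined.sum())))
    vals = psd.y[defined][-tail:]
    return float(np.median(vals))


def wiener_weight(
    pattern: DiffractionPattern,
    shells: ShellMap | None = None,
    noise_floor: float | None = None,
) -> Curve:
    """Wiener weight ``W = S / (S + N)`` per shell.

    ``S`` is the shell PSD minus the constant noise floor (clipped at zero);
    ``W`` is 0 where both vanish and lies in [0, 1] everywhere.
    """
    if shells is None:
        shells = build_shells(pattern.shape, pattern.freq_per_pixel)
    if noise_floor is None:
        noise_floor = estimate_noise_floor(pattern, shells)
    if noise_floor < 0:
        raise ValueError("noise_floor must be non-negative")
    psd = power_spectral_density(pattern, shells)
    S = np.clip(psd.y - noise_floor, 0.0, None)
    denom = S + noise_floor
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(denom > 0, S / np.where(denom > 0, denom, 1.0), 0.0)
    W = np.where(np.isnan(psd.y), np.nan, W)
    return Curve(
        f=psd.f, y=W, kind="wiener", meta={"noise_floor": float(noise_floor)}
    )


def wprtf(prtf_curve: Curve, wiener_curve: Curve) -> Curve:
    """Wiener-weighted PRTF: the pointwise product of the two curves."""
    if len(prtf_curve) != len(wiener_curve) or not np.allclose(
        prtf_curve.f, wiener_curve.f
    ):
        raise ValueError("curves are binned on different shells")
    meta = {**wiener_curve.meta, **prtf_curve.meta}
    return Curve(f=prtf_curve.f, y=prtf_curve.y * wiener_curve.y, kind="wPRTF", meta=meta)


@dataclass
class ResolutionResult:
    """Resolution estimate from a threshold crossing of a quality curve."""

    d_nm: float
    f_star: float  # um^-1
    limit_reached: bool
    threshold: float

    def __float__(self) -> float:
        return self.d_nm


def resolution_from_curve(curve: Curve, threshold: float = ONE_OVER_E) -> ResolutionResult:
    """Full-period resolution at the first crossing below ``threshold``.

    The crossing frequency is linearly interpolated between the bracketing
    shells and converted to ``d = 1/f`` in nanometres (``f`` in inverse
    micrometres). If the curve never crosses, the Nyquist-limit resolution is
    returned with ``limit_reached=True``.
    """
    defined = ~np.isnan(curve.y)
    f = curve.f[defined]
    y = curve.y[defined]
    if len(f) == 0:
        raise ValueError("curve has no defined values")
    if y[0] < threshold:
        raise ValueError("curve starts below the threshold")
    below = np.flatnonzero(y < threshold)
    if below.size == 0:
        f_star = float(f[-1])
        return ResolutionResult(1000.0 / f_star, f_star, True, threshold)
    i = int(below[0])
    f_star = float(
        f[i - 1] + (y[i - 1] - threshold) / (y[i - 1] - y[i]) * (f[i] - f[i - 1])
    )
    return ResolutionResult(1000.0 / f_star, f_star, False, threshold)


def amplitude_variance(
    rset: ReconstructionSet | np.ndarray,
    shells: ShellMap,
    log: bool = True,
) -> Curve:
    """Shell-averaged per-pixel variance of member Fourier amplitudes.

    Measures how much the independent reconstructions disagree at each
    frequency; averaging-friendly ensembles have uniformly low variance. With
    ``log=True`` (the reporting convention) the natural log is returned, with
    ``-inf`` flagging exactly-zero shells.
    """
    images = rset.images() if isinstance(rset, ReconstructionSet) else np.asarray(rset)
    if images.shape[0] < 2:
        raise ValueError("variance needs at least two members")
    amps = np.stack([np.abs(fft2c(img)) for img in images])
    pixel_var = amps.var(axis=0)
    include = shells.index >= 0
    y = _shell_reduce(pixel_var, include, shells)
    meta = {"n_members": int(images.shape[0]), "scale": "ln" if log else "linear"}
    if log:
        with np.errstate(divide="ignore"):
            y = np.log(y)
    return Curve(f=shells.centre_freq, y=y, kind="variance", meta=meta)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def shell_cc(
    patternA: DiffractionPattern,
    patternB: DiffractionPattern,
    shells: ShellMap | None = None,
    min_pixels: int = 3,
) -> Curve:
    """Pearson cross-correlation of two patterns, per resolution shell.

    Computed over mutually valid pixels; shells with fewer than
    ``min_pixels`` usable pixels, or with constant values, come back NaN.
    """
    if patternA.shape != patternB.shape:
        raise ValueError("patterns must share geometry")
    if shells is None:
        shells = build_shells(patternA.shape, patternA.freq_per_pixel)
    both = patternA.valid & patternB.valid
    y = np.full(shells.n_shells, np.nan)
    for j in range(shells.n_shells):
        sel = both & (shells.index == j)
        if sel.sum() < min_pixels:
            continue
        y[j] = _pearson(patternA.intensity[sel], patternB.intensity[sel])
    return Curve(f=shells.centre_freq, y=y, kind="shell_cc")


def global_cc(patterns: list[DiffractionPattern]) -> np.ndarray:
    """Symmetric matrix of whole-pattern Pearson correlations.

    Entry (i, j) is computed over the pixels valid in *both* patterns; the
    diagonal is exactly 1.
    """
    n = len(patterns)
    if n < 2:
        raise ValueError("need at least two patterns")
    shapes = {p.shape for p in patterns}
    if len(shapes) > 1:
        raise ValueError("patterns must share geometry")
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            both = patterns[i].valid & patterns[j].valid
            out[i, j] = out[j, i] = _pearson(
                patterns[i].intensity[both], patterns[j].intensity[both]
            )
    return out


def band_scale(f_lo: float, f_hi: float) -> float:
    """Length scale (nm) probed by a frequency band, ``1 / f_mid``.

    Frequencies are full-period, in inverse micrometres: the 16.5-18.9 um^-1
    band maps to ~56 nm.
    """
    if not 0 < f_lo < f_hi:
        raise ValueError("need 0 < f_lo < f_hi")
    return 1000.0 / ((f_lo + f_hi) / 2.0)
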