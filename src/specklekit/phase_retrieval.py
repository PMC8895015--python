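"""Iterative phase retrieval with the oversampling-smoothness (OSS) algorithm.

OSS is a hybrid input-output (HIO) variant suited to noisy data: at every
iteration the region *outside* the support is replaced by a Gaussian-low-pass
filtered copy of itself, with the filter width shrinking stage by stage.
Wide early filters suppress the high-frequency noise that HIO feedback
otherwise amplifies outside the object; narrow late filters let fine detail
converge. With all filter widths infinite the update degenerates exactly to
plain HIO.

The measured Fourier magnitudes are enforced on valid pixels only; pixels
missing after Friedel symmetrization (the beamstop residue) keep the
iterate's own modelled value, the standard treatment for beamstop gaps.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from ._fft import fft2c, ifft2c, radius_grid
from .types import DiffractionPattern, OssSchedule, Reconstruction, ReconstructionSet

__all__ = [
    "OssReconstructor",
    "oss_reconstruct",
    "run_ensemble",
    "fourier_rfactor",
    "make_support",
]


def fourier_rfactor(
    reconstruction: Reconstruction | np.ndarray, pattern: DiffractionPattern
) -> float:
    """Fourier R-factor of an image against measured magnitudes.

    ``R = sum_valid | |F(image)| - sqrt(I) | / sum_valid sqrt(I)``. Zero for
    an exact solution; 1 for an image whose spectrum is twice the data.
    Invariant under real-space translation of the image.
    """
    image = reconstruction.image if isinstance(reconstruction, Reconstruction) else reconstruction
    if image.shape != pattern.shape:
        raise ValueError("image and pattern shapes differ")
    amp = np.sqrt(pattern.intensity[pattern.valid])
    denom = amp.sum()
    if denom <= 0:
        raise ZeroDivisionError("pattern has zero total amplitude on valid pixels")
    model = np.abs(fft2c(image))[pattern.valid]
    return float(np.abs(model - amp).sum() / denom)


def make_support(
    pattern: DiffractionPattern,
    method: str = "autocorrelation",
    threshold: float = 0.1,
) -> np.ndarray:
    """Estimate a loose support from the pattern's autocorrelation.

    The inverse transform of the intensity is the object's autocorrelation,
    whose extent is twice the object's; thresholding it at
    ``threshold x maximum`` and closing/filling the result yields a mask
    guaranteed (for clean data) to contain the centred object.
    """
    if method != "autocorrelation":
        raise ValueError(f"unknown support method: {method!r}")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    intensity = pattern.intensity
    if not pattern.valid.all():
        # a zeroed beamstop residue removes most of the pattern's energy and
        # floods the autocorrelation; fill gaps with the nearest valid value
        idx = ndimage.distance_transform_edt(
            ~pattern.valid, return_distances=False, return_indices=True
        )
        intensity = intensity[tuple(idx)]
    ac = np.abs(ifft2c(intensity))
    mask = ac > threshold * ac.max()
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3)), iterations=2)
    mask = ndimage.binary_fill_holes(mask)
    if mask.sum() >= mask.size / 2:
        raise ValueError("autocorrelation support covers half the grid; raise threshold")
    return mask


class OssReconstructor(BaseEstimator):
    """OSS phase retrieval as a fit-shaped estimator.

    Parameters
    ----------
    n_iterations, n_stages, beta, filter_sigmas
        See :class:`~specklekit.types.OssSchedule`. ``filter_sigmas=None``
        resolves to ten widths decreasing linearly from N to N/10 frequency
        pixels at fit time.
    constraint : {"real_nonneg", "real", "complex"}
        Real-space constraint. The default models electron density: the
        object is real and non-negative, and HIO feedback is applied both
        outside the support and at negative pixels inside it.
    support_threshold : float
        Autocorrelation threshold used when no support is passed to ``fit``.
    random_state : int
        Seed for the uniform random starting phases.

    Attributes
    ----------
    image_ : ndarray
        Best (lowest R-factor) support-masked object estimate.
    support_ : ndarray of bool
    error_history_ : ndarray
        Fourier R-factor at every iteration.
    rfactor_ : float
        Error of ``image_``.
    """

    def __init__(
        self,
        n_iterations: int = 2000,
        n_stages: int = 10,
        beta: float = 0.9,
        filter_sigmas=None,
        constraint: str = "real_nonneg",
        support_threshold: float = 0.1,
        random_state: int = 0,
    ):
        self.n_iterations = n_iterations
        self.n_stages = n_stages
        self.beta = beta
        self.filter_sigmas = filter_sigmas
        self.constraint = constraint
        self.support_threshold = support_threshold
        self.random_state = random_state

    def _schedule(self) -> OssSchedule:
        return OssSchedule(
            n_iterations=self.n_iterations,
            n_stages=self.n_stages,
            beta=self.beta,
            filter_sigmas=self.filter_sigmas,
        )

    def fit(
        self,
        pattern: DiffractionPattern,
        support: np.ndarray | None = None,
        return_iterates: bool = False,
    ) -> "OssReconstructor":
        """Run the OSS iteration on one diffraction pattern."""
        if self.constraint not in ("real_nonneg", "real", "complex"):
            raise ValueError(f"unknown constraint mode: {self.constraint!r}")
        schedule = self._schedule()
        if not pattern.valid.any():
            raise ValueError("pattern has no valid pixels")
        if support is None:
            support = make_support(pattern, threshold=self.support_threshold)
        support = np.asarray(support, dtype=bool)
        if not support.any():
            raise ValueError("support is empty")
        if support.shape != pattern.shape:
            raise ValueError("support and pattern shapes differ")

        n, m = pattern.shape
        valid = pattern.valid
        meas = np.sqrt(np.where(valid, pattern.intensity, 0.0))
        denom = meas[valid].sum()
        if denom <= 0:
            raise ValueError("pattern has zero amplitude on valid pixels")
        real_mode = self.constraint != "complex"
        beta = self.beta

        rng = np.random.default_rng(self.random_state)
        phases = rng.uniform(0.0, 2.0 * math.pi, size=(n, m))
        x = ifft2c(np.where(valid, meas, 0.0) * np.exp(1j * phases))
        if real_mode:
            x = x.real

        rr = radius_grid(pattern.shape)
        sigmas = schedule.resolve_sigmas(max(n, m))
        per_stage = schedule.n_iterations // schedule.n_stages

        errors = np.empty(schedule.n_iterations)
        best_img = None
        best_err = np.inf
        iterates = [] if return_iterates else None

        k = 0
        for sigma in sigmas:
            gauss = None
            if sigma is not None and np.isfinite(sigma):
                gauss = np.exp(-0.5 * (rr / float(sigma)) ** 2)
            stage_best_img = None
            stage_best_err = np.inf
            for _ in range(per_stage):
                F = fft2c(x)
                Fp = np.where(valid, meas * np.exp(1j * np.angle(F)), F)
                xp = ifft2c(Fp)
                if real_mode:
                    xp = xp.real
                cand = np.where(support, xp, 0.0)
                err = float(
                    np.abs(np.abs(fft2c(cand))[valid] - meas[valid]).sum() / denom
                )
                errors[k] = err
                if err < stage_best_err:
                    stage_best_err, stage_best_img = err, cand
                if err < best_err:
                    best_err, best_img = err, cand
                if self.constraint == "real_nonneg":
                    good = support & (xp >= 0)
                else:
                    good = support
                x = np.where(good, xp, x - beta * xp)
                if gauss is not None:
                    # filter the outside-support region alone: at wide sigma
                    # this is the identity (HIO limit); at narrow sigma the
                    # region decays toward its own (near-zero) mean
                    xs = ifft2c(fft2c(np.where(support, 0.0, x)) * gauss)
                    if real_mode:
                        xs = xs.real
                    x = np.where(support, x, xs)
                if iterates is not None:
                    iterates.append(x.copy())
                k += 1
            # stage hand-off: restart from the best object seen in this stage
            x = stage_best_img.astype(x.dtype)

        self.image_ = best_img
        self.support_ = support
        self.error_history_ = errors
        self.rfactor_ = best_err
        if iterates is not None:
            self.iterates_ = iterates
        return self

    def score(self, pattern: DiffractionPattern) -> float:
        """Negative Fourier R-factor of the fitted image (higher is better)."""
        return -fourier_rfactor(self.image_, pattern)

    def to_reconstruction(self) -> Reconstruction:
        return Reconstruction(
            image=self.image_,
            support=self.support_,
            error_history=self.error_history_,
            seed=self.random_state,
        )


def oss_reconstruct(
    pattern: DiffractionPattern,
    support: np.ndarray | None = None,
    schedule: OssSchedule | None = None,
    constraint_mode: str = "real_nonneg",
    seed: int = 0,
) -> Reconstruction:
    """Functional wrapper over :class:`OssReconstructor`."""
    schedule = schedule or OssSchedule()
    est = OssReconstructor(
        n_iterations=schedule.n_iterations,
        n_stages=schedule.n_stages,
        beta=schedule.beta,
        filter_sigmas=schedule.filter_sigmas,
        constraint=constraint_mode,
        random_state=seed,
    )
    est.fit(pattern, support=support)
    return est.to_reconstruction()


def run_ensemble(
    pattern: DiffractionPattern,
    support: np.ndarray | None = None,
    schedule: OssSchedule | None = None,
    n_runs: int = 24,
    base_seed: int = 0,
    constraint_mode: str = "real_nonneg",
) -> ReconstructionSet:
    """Independent OSS runs with seeds ``base_seed .. base_seed + n_runs - 1``."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if support is None:
        support = make_support(pattern)
    members = [
        oss_reconstruct(
            pattern,
            support=support,
            schedule=schedule,
            constraint_mode=constraint_mode,
            seed=base_seed + i,
        )
        for i in range(n_runs)
    ]
    return ReconstructionSet(members=members, pattern=pattern)
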