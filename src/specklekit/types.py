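"""Core containers shared across the toolkit.

Conventions
-----------
All grids are row-major 2-D :class:`numpy.ndarray`. Diffraction-space arrays
place the zero-frequency (DC) pixel at the grid centre, i.e. index
``(N // 2, M // 2)``; on even-size grids this is the pixel just below/right of
the geometric centre. Spatial frequency ``f`` is the *full-period* frequency,
so the corresponding length scale is ``d = 1 / f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Phantom",
    "DiffractionPattern",
    "ExposureSchedule",
    "DoseParams",
    "OssSchedule",
    "Reconstruction",
    "ReconstructionSet",
    "FeatureMatrix",
    "ClusterResult",
    "ShellMap",
    "Curve",
    "RegionSpec",
    "DoseSeries",
    "dc_index",
]


def dc_index(shape: tuple[int, int]) -> tuple[int, int]:
    """Index of the zero-frequency pixel for a centred spectrum."""
    return shape[0] // 2, shape[1] // 2


@dataclass
class Phantom:
    """Ground-truth 2-D electron-density map.

    Attributes
    ----------
    density : ndarray
        Non-negative electron density, electrons per pixel. Zero outside
        ``support``.
    pixel_nm : float
        Real-space sampling interval in nanometres.
    support : ndarray of bool
        Object extent. Must occupy a minority of the grid so that the
        diffraction pattern is oversampled (linear oversampling > 2).
    """

    density: np.ndarray
    pixel_nm: float
    support: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.support = np.asarray(self.support, dtype=bool)
        if self.density.ndim != 2 or self.density.shape != self.support.shape:
            raise ValueError("density and support must be 2-D arrays of equal shape")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if np.any(self.density[~self.support] != 0):
            raise ValueError("density must vanish outside the support")

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape

    @property
    def oversampling_ratio(self) -> float:
        """Grid area divided by support area (sigma in the CDI literature)."""
        n_support = int(self.support.sum())
        if n_support == 0:
            return float("inf")
        return self.density.size / n_support

    def copy(self) -> "Phantom":
        return Phantom(self.density.copy(), self.pixel_nm, self.support.copy())


@dataclass
class DiffractionPattern:
    """Far-field diffraction intensities with a validity mask.

    ``valid`` is False where the measurement is missing (beamstop shadow that
    centrosymmetry could not refill). ``freq_per_pixel`` is the full-period
    spatial-frequency increment per pixel in inverse micrometres.
    """

    intensity: np.ndarray
    valid: np.ndarray
    freq_per_pixel: float
    photon_energy_kev: float = 5.5
    detector_distance_m: float = 1.496
    detector_pixel_um: float = 20.0
    binning: int = 1

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.intensity.shape != self.valid.shape:
            raise ValueError("intensity and valid must share a shape")
        if self.freq_per_pixel <= 0:
            raise ValueError("freq_per_pixel must be positive")
        if np.any(self.intensity[self.valid] < 0):
            raise ValueError("intensity must be non-negative on valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def copy(self) -> "DiffractionPattern":
        return replace(self, intensity=self.intensity.copy(), valid=self.valid.copy())


@dataclass
class ExposureSchedule:
    """Acquisition plan: list of (seconds per exposure, number of exposures)."""

    entries: Sequence[tuple[float, int]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("schedule must be non-empty")
        for sec, count in self.entries:
            if sec <= 0 or count <= 0:
                raise ValueError("exposure time and count must be strictly positive")


@dataclass
class DoseParams:
    """Inputs for the absorbed-dose estimate.

    fluence_per_um2 : photons per square micrometre (per full acquisition);
    photon_energy_kev : photon energy in keV;
    mass_attenuation_cm2_g : mass energy-absorption coefficient, cm^2/g;
    sample_density_g_cm3 : sample mass density, g/cm^3 (kept for derived
    quantities such as absorption length; the per-mass dose itself does not
    need it).
    """

    fluence_per_um2: float = 1.0
    photon_energy_kev: float = 5.5
    mass_attenuation_cm2_g: float = 30.0
    sample_density_g_cm3: float = 1.35

    def __post_init__(self) -> None:
        for name in (
            "fluence_per_um2",
            "photon_energy_kev",
            "mass_attenuation_cm2_g",
            "sample_density_g_cm3",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class OssSchedule:
    """Iteration plan for the OSS engine.

    ``filter_sigmas`` are per-stage Gaussian widths in frequency pixels applied
    to the region outside the support; they must decrease strictly across
    stages. ``None`` entries (or ``math.inf``) disable filtering for that
    stage, which degenerates to plain HIO.
    """

    n_iterations: int = 2000
    n_stages: int = 10
    beta: float = 0.9
    filter_sigmas: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_iterations <= 0 or self.n_stages <= 0:
            raise ValueError("iteration and stage counts must be positive")
        if self.n_iterations % self.n_stages != 0:
            raise ValueError("n_stages must divide n_iterations")
        if self.filter_sigmas is not None:
            sig = list(self.filter_sigmas)
            if len(sig) != self.n_stages:
                raise ValueError("one filter width per stage required")
            finite = [s for s in sig if np.isfinite(s)]
            if any(s <= 0 for s in finite):
                raise ValueError("filter widths must be positive")
            if any(b >= a for a, b in zip(sig, sig[1:])):
                raise ValueError("filter widths must decrease strictly")

    def resolve_sigmas(self, grid_size: int) -> list[float]:
        """Concrete per-stage widths; default is linear from N down to N/10."""
        if self.filter_sigmas is not None:
            return list(self.filter_sigmas)
        return list(
            np.linspace(float(grid_size), float(grid_size) / 10.0, self.n_stages)
        )


@dataclass
class Reconstruction:
    """A single phase-retrieval result."""

    image: np.ndarray
    support: np.ndarray
    error_history: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.support = np.asarray(self.support, dtype=bool)
        self.error_history = np.asarray(self.error_history, dtype=float)
        if self.error_history.size == 0 or not np.all(np.isfinite(self.error_history)):
            raise ValueError("error_history must be non-empty and finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    @property
    def final_error(self) -> float:
        return float(self.error_history.min())

    def copy(self) -> "Reconstruction":
        return Reconstruction(
            self.image.copy(), self.support.copy(), self.error_history.copy(), self.seed
        )


@dataclass
class ReconstructionSet:
    """Independent reconstructions of one diffraction pattern."""

    members: list[Reconstruction]
    pattern: DiffractionPattern | None = None

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.members}
        if len(shapes) > 1:
            raise ValueError("all members must share a grid shape")

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, i: int) -> Reconstruction:
        return self.members[i]

    def images(self) -> np.ndarray:
        return np.stack([m.image for m in self.members])

    def rfactors(self) -> np.ndarray:
        return np.array([m.final_error for m in self.members])


@dataclass
class FeatureMatrix:
    """One feature vector per reconstruction plus provenance."""

    vectors: np.ndarray
    backbone: str
    reduced_dim: int | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D (members x features) array")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature vectors must be finite")


@dataclass
class ClusterResult:
    """Partition of a reconstruction set and the cluster chosen for averaging."""

    labels: np.ndarray
    selected: int
    chosen_members: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.chosen_members = np.asarray(self.chosen_members, dtype=int)
        if self.chosen_members.size == 0:
            raise ValueError("chosen cluster must be non-empty")
        if np.any(self.labels[self.chosen_members] != self.selected):
            raise ValueError("chosen members must carry the selected label")


@dataclass
class ShellMap:
    """Assignment of diffraction pixels to concentric resolution shells.

    ``index`` is -1 beyond the Nyquist radius, otherwise the shell number.
    """

    index: np.ndarray
    centre_freq: np.ndarray
    counts: np.ndarray
    freq_per_pixel: float
    shell_width: int

    @property
    def n_shells(self) -> int:
        return len(self.centre_freq)


@dataclass
class Curve:
    """A radially binned quantity versus full-period spatial frequency."""

    f: np.ndarray
    y: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.f.shape != self.y.shape:
            raise ValueError("f and y must have equal length")

    def __len__(self) -> int:
        return len(self.f)


@dataclass
class RegionSpec:
    """Axis-aligned rectangle in reconstruction pixels."""

    row0: int
    col0: int
    height: int
    width: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("region extent must be positive")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("region origin must be non-negative")

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    def check_bounds(self, shape: tuple[int, int]) -> None:
        if self.row0 + self.height > shape[0] or self.col0 + self.width > shape[1]:
            raise ValueError(f"region {self.label!r} exceeds image bounds {shape}")


@dataclass
class DoseSeries:
    """Reconstructions of one sample at strictly increasing cumulative doses."""

    reconstructions: list[Reconstruction]
    doses: Sequence[float]
    calibration: float = 1.0

    def __post_init__(self) -> None:
        if len(self.reconstructions) != len(self.doses):
            raise ValueError("one dose label per reconstruction required")
        shapes = {r.shape for r in self.reconstructions}
        if len(shapes) > 1:
            raise ValueError("all reconstructions must share a shape")
        d = np.asarray(self.doses, dtype=float)
        if d.size >= 2 and np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.calibration <= 0:
            raise ValueError("calibration must be positive")

    def __len__(self) -> int:
        return len(self.reconstructions)
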