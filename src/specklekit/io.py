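"""File formats: CXI-style HDF5 containers, TIFF interchange, reports.

The HDF5 layout follows the CXI convention used by the coherent-imaging
community: intensities at ``entry_1/data_1/data``, the validity mask at
``entry_1/data_1/mask`` (1 = valid), and instrument metadata under
``entry_1/instrument_1``. Curves are exported as tidy CSV
(``f_um_inv,value,kind``) and reports as schema-versioned JSON.

Coordinate convention (recorded in the files): row-major, 0-based, zero
frequency at the centre pixel ``(N//2, M//2)``.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import tifffile

from .types import Curve, DiffractionPattern, Phantom, Reconstruction, ReconstructionSet

__all__ = [
    "write_pattern",
    "read_pattern",
    "write_phantom",
    "read_phantom",
    "write_reconstruction_set",
    "read_reconstruction_set",
    "write_curves_csv",
    "read_curves_csv",
    "write_report",
    "read_report",
    "plot_curves",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"
logger = logging.getLogger("specklekit")


def _require(group: h5py.Group, name: str, path) -> h5py.Dataset:
    if name not in group:
        raise IOError(f"malformed file {path}: missing dataset {name!r}")
    return group[name]


def write_pattern(path, pattern: DiffractionPattern) -> None:
    """Write a pattern to CXI-style HDF5 (.cxi/.h5) or 32-bit TIFF (.tif)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pattern.intensity.astype(np.float32))
        tifffile.imwrite(
            path.with_suffix(path.suffix + ".mask.tif"),
            pattern.valid.astype(np.uint8),
        )
        return
    with h5py.File(path, "w") as fh:
        data = fh.create_group("entry_1/data_1")
        data.create_dataset("data", data=pattern.intensity)
        data.create_dataset("mask", data=pattern.valid.astype(np.uint8))
        det = fh.create_group("entry_1/instrument_1/detector_1")
        det.create_dataset("distance", data=pattern.detector_distance_m)
        det.create_dataset("x_pixel_size", data=pattern.detector_pixel_um * 1e-6)
        det.create_dataset("binning", data=pattern.binning)
        src = fh.create_group("entry_1/instrument_1/source_1")
        src.create_dataset("energy", data=pattern.photon_energy_kev * 1.602176634e-16)
        fh.attrs["freq_per_pixel_um_inv"] = pattern.freq_per_pixel
        fh.attrs["photon_energy_kev"] = pattern.photon_energy_kev
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["convention"] = "row-major, 0-based, DC at (N//2, M//2)"


def read_pattern(path, freq_per_pixel: float | None = None) -> DiffractionPattern:
    """Read a pattern written by :func:`write_pattern`.

    For TIFF inputs without a sidecar mask an all-valid mask is assumed (a
    warning is logged); ``freq_per_pixel`` must then be supplied or defaults
    to 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        intensity = np.asarray(tifffile.imread(path), dtype=float)
        if np.any(intensity < 0):
            raise IOError(f"malformed file {path}: negative intensities")
        mask_path = path.with_suffix(path.suffix + ".mask.tif")
        if mask_path.exists():
            valid = np.asarray(tifffile.imread(mask_path)).astype(bool)
        else:
            logger.warning("no sidecar mask next to %s; assuming all pixels valid", path)
            valid = np.ones(intensity.shape, dtype=bool)
        return DiffractionPattern(
            intensity=intensity, valid=valid, freq_per_pixel=freq_per_pixel or 1.0
        )
    with h5py.File(path, "r") as fh:
        if "entry_1" not in fh or "data_1" not in fh["entry_1"]:
            raise IOError(f"malformed file {path}: missing group 'entry_1/data_1'")
        data = fh["entry_1/data_1"]
        intensity = np.asarray(_require(data, "data", path), dtype=float)
        valid = np.asarray(_require(data, "mask", path)).astype(bool)
        if np.any(intensity[valid] < 0):
            raise IOError(f"malformed file {path}: negative intensities")
        fpp = float(fh.attrs.get("freq_per_pixel_um_inv", freq_per_pixel or 1.0))
        kw = {}
        det = fh.get("entry_1/instrument_1/detector_1")
        if det is not None:
            kw["detector_distance_m"] = float(det["distance"][()])
            kw["detector_pixel_um"] = float(det["x_pixel_size"][()]) * 1e6
            kw["binning"] = int(det["binning"][()])
        if "photon_energy_kev" in fh.attrs:
            kw["photon_energy_kev"] = float(fh.attrs["photon_energy_kev"])
        return DiffractionPattern(
            intensity=intensity, valid=valid, freq_per_pixel=fpp, **kw
        )


def write_phantom(path, phantom: Phantom) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("phantom")
        grp.create_dataset("density", data=phantom.density)
        grp.create_dataset("support", data=phantom.support.astype(np.uint8))
        grp.attrs["pixel_nm"] = phantom.pixel_nm
        fh.attrs["schema_version"] = SCHEMA_VERSION


def read_phantom(path) -> Phantom:
    with h5py.File(path, "r") as fh:
        if "phantom" not in fh:
            raise IOError(f"malformed file {path}: missing group 'phantom'")
        grp = fh["phantom"]
        return Phantom(
            density=np.asarray(_require(grp, "density", path)),
            pixel_nm=float(grp.attrs["pixel_nm"]),
            support=np.asarray(_require(grp, "support", path)).astype(bool),
        )


def write_reconstruction_set(path, rset: ReconstructionSet) -> None:
    """Reconstruction stack + per-member error histories and seeds."""
    with h5py.File(path, "w") as fh:
        images = rset.images()
        if np.iscomplexobj(images):
            fh.create_dataset("reconstructions/real", data=images.real)
            fh.create_dataset("reconstructions/imag", data=images.imag)
        else:
            fh.create_dataset("reconstructions/real", data=images)
        fh.create_dataset(
            "reconstructions/support",
            data=np.stack([m.support for m in rset.members]).astype(np.uint8),
        )
        fh.create_dataset(
            "reconstructions/error_history",
            data=np.stack([m.error_history for m in rset.members]),
        )
        fh.create_dataset(
            "reconstructions/seeds", data=np.array([m.seed for m in rset.members])
        )
        fh.attrs["schema_version"] = SCHEMA_VERSION


def read_reconstruction_set(path) -> ReconstructionSet:
    with h5py.File(path, "r") as fh:
        if "reconstructions" not in fh:
            raise IOError(f"malformed file {path}: missing group 'reconstructions'")
        grp = fh["reconstructions"]
        images = np.asarray(_require(grp, "real", path), dtype=float)
        if "imag" in grp:
            images = images + 1j * np.asarray(grp["imag"])
        supports = np.asarray(_require(grp, "support", path)).astype(bool)
        errors = np.asarray(_require(grp, "error_history", path), dtype=float)
        seeds = np.asarray(_require(grp, "seeds", path), dtype=int)
        members = [
            Reconstruction(images[i], supports[i], errors[i], int(seeds[i]))
            for i in range(images.shape[0])
        ]
        return ReconstructionSet(members=members)


def write_curves_csv(curves: Sequence[Curve], path) -> None:
    """Tidy CSV with one row per (shell, curve): f_um_inv, value, kind."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["f_um_inv", "value", "kind"])
        for curve in curves:
            for f, y in zip(curve.f, curve.y):
                w.writerow([repr(float(f)), repr(float(y)), curve.kind])


def read_curves_csv(path) -> list[Curve]:
    rows: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.setdefault(rec["kind"], []).append(
                (float(rec["f_um_inv"]), float(rec["value"]))
            )
    return [
        Curve(f=np.array([r[0] for r in pts]), y=np.array([r[1] for r in pts]), kind=kind)
        for kind, pts in rows.items()
    ]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(results: dict, path) -> None:
    """Schema-versioned JSON report; numeric fields survive a round trip."""
    payload = {"schema_version": SCHEMA_VERSION, **_jsonable(results)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def plot_curves(curves: Sequence[Curve], path, logy: bool = False) -> None:
    """PNG preview of one or more curves vs spatial frequency."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for curve in curves:
        ax.plot(curve.f, curve.y, label=curve.kind)
    ax.set_xlabel("spatial frequency (1/um)")
    ax.set_ylabel("value")
    if logy:
        ax.set_yscale("log")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
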