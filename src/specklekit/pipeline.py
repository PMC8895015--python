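"""End-to-end run: simulate -> phase -> cluster -> metrics -> damage.

Glues the stages together for the CLI and for reproducibility studies: one
configuration plus one seed produces byte-identical curves and reports.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import clustering, damage, io, quality, simulate
from .config import resolve_config
from .phase_retrieval import make_support, run_ensemble
from .types import DoseParams, DoseSeries, OssSchedule, Reconstruction, RegionSpec

__all__ = ["run_pipeline", "simulate_patterns", "auto_regions"]


def simulate_patterns(cfg: dict) -> tuple[list, list]:
    """Phantom dose series and the matching noisy, masked, binned patterns."""
    sim = cfg["simulate"]
    seed = cfg["stage_seeds"]["simulate"]
    phantom = simulate.make_phantom(
        seed=seed,
        grid_size=sim["grid_size"],
        object_fraction=sim["object_fraction"],
        n_blobs=sim["n_blobs"],
        density_range=tuple(sim["density_range"]),
        pixel_nm=sim["pixel_nm"],
    )
    series = simulate.simulate_damage_series(
        phantom,
        n_steps=sim["n_steps"],
        high_decay=sim["high_decay"],
        low_swell=sim["low_swell"],
        swell_peak_step=sim["swell_peak_step"],
        seed=seed + 1,
    )
    patterns = simulate.diffract_series(
        series,
        photon_budget=sim["photon_budget"],
        seed=seed + 10,
        stop_halfwidth=sim["stop_halfwidth"],
        stop_offset=tuple(sim["stop_offset"]),
        bin_factor=sim["bin_factor"],
    )
    return series, patterns


def auto_regions(phantom, size: int = 8) -> list[RegionSpec]:
    """High- and low-density probe rectangles centred on the density
    extremes inside the support (used when no regions are configured)."""
    from scipy import ndimage

    dens = phantom.density
    sup = phantom.support
    # keep rectangles fully inside the grid
    def _clamp(c, n):
        return int(np.clip(c - size // 2, 0, n - size))

    # windowed means so the rectangle, not a single pixel, is extreme;
    # candidate centres must have their whole window inside the support
    win_mean = ndimage.uniform_filter(dens, size=size)
    interior = ndimage.binary_erosion(sup, np.ones((size, size)))
    if not interior.any():
        interior = sup
    hi = np.unravel_index(np.argmax(np.where(interior, win_mean, -np.inf)), dens.shape)
    lo = np.unravel_index(np.argmin(np.where(interior, win_mean, np.inf)), dens.shape)
    return [
        RegionSpec(_clamp(hi[0], dens.shape[0]), _clamp(hi[1], dens.shape[1]), size, size, "high"),
        RegionSpec(_clamp(lo[0], dens.shape[0]), _clamp(lo[1], dens.shape[1]), size, size, "low"),
    ]


def run_pipeline(cfg: dict | None = None, seed: int | None = None, out_dir=None) -> dict:
    """Run every stage; write patterns, stacks, curves, previews, report."""
    if cfg is None or "stage_seeds" not in cfg:
        cfg = resolve_config(cfg, seed=seed)
    elif seed is not None:
        sections = {k: v for k, v in cfg.items() if isinstance(v, dict) and k != "stage_seeds"}
        cfg = resolve_config(sections, seed=seed)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    series, patterns = simulate_patterns(cfg)
    for i, pat in enumerate(patterns):
        io.write_pattern(out / f"pattern_{i}.cxi", pat)

    rec_cfg = cfg["reconstruct"]
    schedule = OssSchedule(
        n_iterations=rec_cfg["n_iterations"],
        n_stages=rec_cfg["n_stages"],
        beta=rec_cfg["beta"],
    )
    support = make_support(patterns[0], threshold=rec_cfg["support_threshold"])
    base = cfg["stage_seeds"]["reconstruct"]
    clu_cfg = cfg["cluster"]
    averages, cluster_reports = [], []
    for i, pat in enumerate(patterns):
        rset = run_ensemble(
            pat,
            support=support,
            schedule=schedule,
            n_runs=rec_cfg["n_runs"],
            base_seed=base + 100 * i,
            constraint_mode=rec_cfg["constraint"],
        )
        io.write_reconstruction_set(out / f"stack_{i}.h5", rset)
        clusterer = clustering.ReconstructionClusterer(
            backbone=clu_cfg["backbone"],
            n_components=clu_cfg["n_components"],
            k=min(clu_cfg["k"], len(rset)),
            n_best=clu_cfg["n_best"],
            random_state=cfg["stage_seeds"]["cluster"] + i,
        ).fit(rset)
        averages.append(clusterer.average_image_)
        cluster_reports.append(clusterer.report_)

    met = cfg["metrics"]
    shells = quality.build_shells(
        patterns[0].shape, patterns[0].freq_per_pixel, met["shell_width"]
    )
    curves, resolutions = [], []
    for i, (pat, avg) in enumerate(zip(patterns, averages)):
        p = quality.prtf(avg, pat, shells)
        w = quality.wiener_weight(pat, shells)
        wp = quality.wprtf(p, w)
        res = quality.resolution_from_curve(wp, met["resolution_threshold"])
        resolutions.append(
            {"step": i, "d_nm": res.d_nm, "limit_reached": res.limit_reached}
        )
        for c, suffix in ((p, "prtf"), (w, "wiener"), (wp, "wprtf")):
            c.kind = f"{suffix}_step{i}"
            curves.append(c)
    cc_curves = [
        quality.shell_cc(patterns[0], patterns[j], shells) for j in range(1, len(patterns))
    ]
    for j, c in enumerate(cc_curves, start=1):
        c.kind = f"cc_1_{j + 1}"
        curves.append(c)
    cc_matrix = quality.global_cc(patterns)

    dmg = cfg["damage"]
    sim = cfg["simulate"]
    fluence = sim["photon_budget"] / (sim["grid_size"] * sim["pixel_nm"] * 1e-3) ** 2
    dose_step = simulate.absorbed_dose(DoseParams(), 1.0, fluence)
    doses = [dose_step * (i + 1) for i in range(len(averages))]
    recs = [
        Reconstruction(avg, support, np.array([rep["mean_rfactor"]]), i)
        for i, (avg, rep) in enumerate(zip(averages, cluster_reports))
    ]
    dseries = damage.register_series(
        DoseSeries(recs, doses, dmg["calibration"]), reference=series[0].density
    )
    regions = (
        [RegionSpec(**r) for r in dmg["regions"]]
        if dmg["regions"]
        else auto_regions(series[0])
    )
    region_out = {
        r.label or f"region_{k}": damage.region_density_series(dseries, r).tolist()
        for k, r in enumerate(regions)
    }
    loss = damage.electron_loss_series(dseries)

    io.write_curves_csv(curves, out / "curves.csv")
    io.plot_curves([c for c in curves if c.kind.startswith("wprtf")], out / "wprtf.png")
    report = {
        "seed": cfg["seed"],
        "resolutions": resolutions,
        "cluster": cluster_reports,
        "cc_matrix": cc_matrix,
        "doses_gy": doses,
        "electron_loss": loss,
        "region_density": region_out,
    }
    io.write_report(report, out / "report.json")
    return report
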