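"""End-to-end analysis pipeline: clustering, metrics, FEL, pore geometry.

Runs every stage that applies to a peptide trajectory in order and writes
tidy CSV outputs plus one JSON run summary.  Stages that need solvent
(axial density, PMF, permeation) run only when the trajectory contains the
requested species.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .core_io import AnalysisConfig, Trajectory
from .aggregation import cluster_count_series
from .conformation import conformation_series, order_parameter_series
from .free_energy import barrier_height, find_basins, landscape_from_series
from .pore_permeation import (axial_density, count_permeation_events,
                              density_pmf, pore_radius)

logger = logging.getLogger("poreform")


def run_pipeline(traj: Trajectory, config: AnalysisConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run all applicable analysis stages and return a summary dict."""
    cfg = config or AnalysisConfig()
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"n_frames": traj.n_frames,
                     "n_particles": traj.topology.n_particles}

    # 1. clustering kinetics
    series = cluster_count_series(traj, cfg.cluster_cutoff, cfg)
    counts = series.counts
    summary["cluster_counts"] = {
        "initial": int(counts[0]), "final": int(counts[-1]),
        "non_increasing": bool(np.all(np.diff(counts) <= 0)),
    }
    if out:
        series.to_frame().to_csv(out / "clusters.csv", index=False)

    # 2. conformation metrics
    conf = conformation_series(traj, cfg)
    order = order_parameter_series(traj, cfg.cluster_cutoff, cfg)
    summary["conformation"] = {
        "mean_sasa_nm2": float(conf.sasa.mean()),
        "mean_rg_nm": float(conf.rg.mean()),
        "final_order_parameter": (None if np.isnan(order.s[-1])
                                  else float(order.s[-1])),
    }
    if out:
        df = conf.to_frame()
        df["S_largest_cluster"] = order.s
        df.to_csv(out / "metrics.csv", index=False)

    # 3. free-energy landscape over (SASA, Rg)
    landscape = landscape_from_series(conf, cfg.temperature, cfg.fel_bins)
    basins = find_basins(landscape, connectivity=cfg.connectivity)
    fel_summary = {
        "min_w": float(landscape.w[landscape.occupied].min()),
        "n_occupied_bins": int(landscape.occupied.sum()),
        "basins": [{"sasa_nm2": b.x, "rg_nm": b.y, "w_kcal_mol": b.w}
                   for b in basins[:5]],
    }
    if len(basins) >= 2:
        barrier = barrier_height(landscape, basins[0], basins[1],
                                 cfg.connectivity)
        fel_summary["barrier_kcal_mol"] = {"forward": barrier.forward,
                                           "backward": barrier.backward}
    summary["free_energy"] = fel_summary
    if out:
        landscape.to_frame().to_csv(out / "fel.csv", index=False)

    # 4. pore geometry of the final largest cluster
    final = series.assignments[-1]
    big = final.largest_cluster
    if len(big) >= 3:
        pr = pore_radius(traj.frames[-1], traj.topology, big,
                         cfg.pore_grid_spacing, cfg.channel_z_lo,
                         cfg.channel_z_hi)
        summary["pore_radius"] = {"radius_nm": pr.radius,
                                  "diagnostic": pr.diagnostic}
        if out:
            (out / "pore_radius.json").write_text(json.dumps(asdict(pr)))

    # 5. solvent stages, when solvent is present
    for species in ("water", "ion"):
        if traj.topology.select(species).size == 0 or traj.n_frames < 2:
            continue
        try:
            profile = axial_density(traj, species, cfg.channel_z_lo,
                                    cfg.channel_z_hi,
                                    cylinder_radius=cfg.cylinder_radius,
                                    bulk_margin=cfg.bulk_margin,
                                    bulk_cross_section=cfg.bulk_cross_section)
            pmf = density_pmf(profile, cfg.temperature)
            summary[f"{species}_pmf_barrier_kcal_mol"] = pmf.barrier
            if out:
                df = profile.to_frame()
                df["dG_kcal_mol"] = pmf.dg
                df.to_csv(out / f"density_pmf_{species}.csv", index=False)
        except ValueError as exc:
            logger.warning("%s density stage skipped: %s", species, exc)
        events = count_permeation_events(traj, species, cfg.channel_z_lo,
                                         cfg.channel_z_hi,
                                         cfg.cylinder_radius)
        summary[f"{species}_permeation_events"] = len(events)

    if out:
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("pipeline outputs written to %s", out)
    return summary
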