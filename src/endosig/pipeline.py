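"""End-to-end runs: simulate fixtures, imaging quantification, SILAC stage.

Every run is deterministic given its configuration and seed, logs its key
intermediate numbers (nucleus counts, QC drop counts, background modes,
centering constants, flagged counts) and writes the resolved configuration
next to its outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import imaging, silac, stats, synth
from .config import RunConfig

log = logging.getLogger("endosig")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible per-task seeds below 2**31 from one run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % 2**31 for s in ss.generate_state(n, dtype=np.uint64)]


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def run_simulate(cfg: RunConfig) -> dict[str, list[str]]:
    """Write a synthetic fixture bundle (scenes and/or SILAC tables)."""
    sim = cfg.simulate
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {"images": [], "tables": [], "truth": []}
    log.info("simulate: seed=%d outdir=%s", cfg.seed, outdir)

    n_scene_seeds = sum(s.n_fields for s in sim.scenes)
    seeds = _child_seeds(cfg.seed, n_scene_seeds + 1)
    i = 0
    for scene_cfg in sim.scenes:
        for f in range(scene_cfg.n_fields):
            spec = scene_cfg.to_spec(seeds[i])
            i += 1
            dapi, marker, truth = synth.generate_scene(spec)
            prefix = f"{scene_cfg.group}_field{f}"
            paths = synth.write_scene(outdir / "images", prefix, dapi, marker, truth)
            manifest["images"] += [str(paths["dapi"]), str(paths["marker"])]
            manifest["truth"].append(str(paths["truth"]))
            log.info("simulate: wrote %s (%d cells)", prefix, len(truth.cells))
    if sim.table is not None:
        spec = sim.table.to_spec(seeds[-1])
        fwd, rev, truth = synth.generate_silac_tables(spec)
        paths = synth.write_silac_tables(outdir / "tables", fwd, rev, truth)
        manifest["tables"] += [str(paths["forward"]), str(paths["reverse"])]
        manifest["truth"].append(str(paths["truth"]))
        log.info("simulate: wrote SILAC tables (%d rows each)", len(fwd))

    cfg.write_resolved(outdir)
    pd.Series({k: ";".join(v) for k, v in manifest.items()}).to_csv(
        outdir / "manifest.csv", header=False
    )
    return manifest


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------


def run_imaging(cfg: RunConfig) -> dict[str, Path]:
    """Quantify N/C ratios for every configured field and compare groups.

    Writes ``cells.csv`` (one row per segmented cell, flagged or not),
    ``summary.csv`` (one row per field) and ``stats.csv`` (group comparison
    of unflagged cells).  Exits with an error if no field yields any nucleus.
    """
    icfg = cfg.imaging
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seg = icfg.segmentation
    frames = []
    summaries = []
    for idx, field in enumerate(icfg.fields):
        dapi = imaging.Image2D.read(field.dapi, pixel_size=icfg.pixel_size,
                                    channel=field.channel_dapi)
        marker = imaging.Image2D.read(field.marker, pixel_size=icfg.pixel_size,
                                      channel=field.channel_marker)
        nuclei = imaging.segment_nuclei(
            dapi,
            median_radius=seg.median_radius,
            min_area=seg.min_area_px,
            max_area=seg.max_area_px,
            exclude_border=seg.exclude_border,
        )
        rings = imaging.build_rings(nuclei, gap=icfg.ring.gap,
                                    ring_width=icfg.ring.ring_width,
                                    contested=icfg.ring.contested)
        mode = imaging.estimate_background_mode(marker,
                                                bin_width=icfg.mode_bin_width)
        records = imaging.measure_cells(marker, nuclei, rings, mode)
        rules = imaging.QCRules(
            min_area_px=icfg.qc.min_area_px,
            max_area_px=icfg.qc.max_area_px,
            min_ring_pixels=icfg.qc.min_ring_pixels,
            min_solidity=icfg.qc.min_solidity,
        )
        records = imaging.qc_filter(records, rules)
        n_ok = sum(r.ok for r in records)
        flag_counts: dict[str, int] = {}
        for r in records:
            for fl in r.qc_flags:
                flag_counts[fl] = flag_counts.get(fl, 0) + 1
        log.info(
            "imaging field %d (%s): %d nuclei, %d pass QC, mode=%s, drops=%s",
            idx, field.group, nuclei.n_labels, n_ok, mode, flag_counts,
        )
        frames.append(imaging.records_to_frame(
            records, group=field.group, field=idx,
            experiment=field.experiment or "",
        ))
        ratios = [r.nc_ratio for r in records if r.ok and r.nc_ratio is not None]
        summaries.append({
            "field": idx, "group": field.group,
            "experiment": field.experiment or "",
            "n_nuclei": nuclei.n_labels, "n_pass_qc": n_ok,
            "background_mode": mode,
            "median_nc_ratio": float(np.median(ratios)) if ratios else np.nan,
            **{f"drop_{k}": v for k, v in sorted(flag_counts.items())},
        })
        if icfg.export_labels:
            lbl_dir = outdir / "labels"
            lbl_dir.mkdir(exist_ok=True)
            tifffile.imwrite(lbl_dir / f"field{idx}_nuclei.tif",
                             nuclei.labels.astype(np.uint16))
            tifffile.imwrite(lbl_dir / f"field{idx}_rings.tif",
                             rings.labels.astype(np.uint16))

    cells = pd.concat(frames, ignore_index=True)
    if cells.empty:
        raise RuntimeError("no nuclei found in any field")

    paths = {
        "cells": outdir / "cells.csv",
        "summary": outdir / "summary.csv",
        "stats": outdir / "stats.csv",
    }
    cells.to_csv(paths["cells"], index=False)
    pd.DataFrame(summaries).to_csv(paths["summary"], index=False)

    usable = cells[(cells["qc_flags"] == "") & cells["nc_ratio"].notna()]
    if usable["group"].nunique() >= 2:
        stat_table = stats.compare_groups(
            usable, "nc_ratio", "group", unit=icfg.stats_unit,
            experiment_col="experiment" if icfg.stats_unit == "experiment" else None,
        )
    else:
        stat_table = pd.DataFrame(
            columns=["test", "groups", "n", "statistic", "df", "p", "tier",
                     "detail", "unit"]
        )
    stat_table.to_csv(paths["stats"], index=False)
    cfg.write_resolved(outdir)
    return paths


# ---------------------------------------------------------------------------
# silac
# ---------------------------------------------------------------------------


def run_silac(cfg: RunConfig) -> dict[str, Path]:
    """Differential SILAC analysis of a forward/reverse table pair.

    Writes ``differential.csv`` and, when a GMT file is configured,
    ``enrichment.csv`` over the significant gene list against the background
    of all analyzed genes.
    """
    scfg = cfg.silac
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    forward = silac.parse_table(scfg.forward)
    reverse = silac.parse_table(scfg.reverse)
    result, info = silac.differential_analysis(
        forward, reverse,
        mutant_channel_forward=scfg.mutant_channel_forward,
        min_unique=scfg.min_unique, min_loc_prob=scfg.min_loc_prob,
        center=scfg.center, n_sd=scfg.n_sd,
        impute_constant=scfg.impute_constant,
    )
    for rep in ("forward", "reverse"):
        log.info("silac %s: %d rows in, dropped %s, center=%.4f", rep,
                 info[rep]["input_rows"], info[rep]["dropped"],
                 info[rep]["center"])
    comb = info["combined"]
    log.info("silac combined: %d sites, sd=%.4f, %d significant, "
             "%d discordant, %d imputed", comb["n_sites"], comb["sd"],
             comb["n_significant"], comb["n_discordant"], comb["n_imputed"])

    paths = {"differential": outdir / "differential.csv"}
    result.to_csv(paths["differential"], index=False)

    if scfg.gene_sets:
        background = sorted(set(result["gene_names"].dropna()))
        sig = sorted(set(result.loc[result["significant"], "gene_names"].dropna()))
        enr = silac.fisher_enrichment(sig, background, scfg.gene_sets)
        paths["enrichment"] = outdir / "enrichment.csv"
        enr.to_csv(paths["enrichment"], index=False)
        log.info("silac enrichment: %d sets tested, %d with p_adj < 0.05",
                 len(enr), int((enr["p_adj"] < 0.05).sum()) if len(enr) else 0)
    cfg.write_resolved(outdir)
    return paths


# ---------------------------------------------------------------------------
# stats
# ---------------------------------------------------------------------------


def run_stats(cfg: RunConfig) -> dict[str, Path]:
    """Group statistics (and optional violin plot) for a per-cell CSV."""
    tcfg = cfg.stats
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = pd.read_csv(tcfg.cells_csv)
    if "qc_flags" in cells.columns:
        cells = cells[cells["qc_flags"].fillna("") == ""]
    table = stats.compare_groups(
        cells, tcfg.value_col, tcfg.group_col, unit=tcfg.unit,
        experiment_col=tcfg.experiment_col, welch=tcfg.welch,
    )
    paths = {"stats": outdir / "stats.csv"}
    table.to_csv(paths["stats"], index=False)
    if tcfg.plot:
        from .plots import violin_by_group

        paths["plot"] = outdir / "violin.png"
        violin_by_group(cells, tcfg.value_col, tcfg.group_col, paths["plot"])
    cfg.write_resolved(outdir)
    return paths


RUNNERS = {
    "simulate": run_simulate,
    "imaging": run_imaging,
    "silac": run_silac,
    "stats": run_stats,
}
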