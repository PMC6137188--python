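"""End-to-end driver: simulate culture -> sort -> render -> quantify -> analyse."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import analytics, focusing, imaging, pipeline, population
from .config import RunConfig, config_from_dict
from .errors import ScarflowError
from .io import RunLog

__all__ = ["end_to_end"]

#: Ports of interest: the centreline port and the concave-focus port.
CENTER_PORT = 2
CONCAVE_PORT = 4


def end_to_end(
    config: RunConfig | None = None,
    log: RunLog | None = None,
    n_render_per_port: int = 150,
    write_outputs: bool = True,
) -> dict:
    """Run the full workflow and return a nested summary report.

    Stages: culture simulation, outlet sorting, synthetic imaging of the
    centre- and concave-port samples, single-cell quantification, and the
    downstream statistics (age summaries, enrichment, diameter-scar
    regression on the pipeline's own measurements).  Fully reproducible
    from the config seed.
    """
    config = config or config_from_dict({})
    log = log or RunLog()
    if config.culture_n < 1:
        raise ScarflowError("culture.n must be at least 1 cell")
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(4, dtype=np.uint32) >> 1]

    log.log("device", **config.flow.summary())
    cells = population.simulate_culture(
        config.culture_mode,
        config.culture_n,
        seeds[0],
        params=config.culture,
        diameter_model=config.diameter_model,
    )
    mix_summary = analytics.age_distribution_summary(cells, scars_col="scars")
    log.counts("culture", config.culture_n, len(cells), mode=config.culture_mode)

    sorted_cells = population.apply_sort(
        cells, config.flow, config.force_model, seeds[1], edges_frac=config.outlet_edges
    )
    ports = population.split_ports(sorted_cells)
    log.counts("sort", len(cells), sum(len(p) for p in ports.values()))

    report: dict = {
        "device": config.flow.summary(),
        "mixture": {
            "n": mix_summary.n,
            "newborn_fraction": mix_summary.newborn_fraction,
            "young_fraction": mix_summary.young_fraction,
            "adult_fraction": mix_summary.adult_fraction,
            "mean_scars": mix_summary.mean_scars,
        },
        "ports": {},
    }

    measured_tables = []
    for port in sorted(ports):
        pcells = ports[port]
        em = population.enrichment_metrics(pcells, cells)
        entry = {
            "n": int(len(pcells)),
            "young_fraction": em.young_fraction,
            "adult_fraction": em.adult_fraction,
            "mean_scars": em.mean_scars,
            "sd_scars": em.sd_scars,
        }
        if port in (CENTER_PORT, CONCAVE_PORT) and len(pcells) > 0:
            sample = pcells.iloc[:n_render_per_port].reset_index(drop=True)
            rng = np.random.default_rng(seeds[2] + port)
            measured = []
            for bi, batch in enumerate(imaging.scene_batches(sample, config.optics)):
                scene = imaging.render_scene(
                    batch.reset_index(drop=True),
                    config.optics,
                    config.layout,
                    int(rng.integers(0, 2**31)),
                )
                table = pipeline.measure_scene(scene.channels, config.segmentation)
                table["port"] = port
                measured.append(table)
            mtab = pd.concat(measured, ignore_index=True)
            measured_tables.append(mtab)
            entry["n_measured"] = int(len(mtab))
            entry["measured_mean_scars"] = float(mtab["scar_count"].mean())
            entry["measured_mean_diameter_um"] = float(mtab["diameter_um"].mean())
            log.counts(f"pipeline_port_{port}", len(sample), len(mtab))
        report["ports"][port] = entry

    if measured_tables:
        pooled = pd.concat(measured_tables, ignore_index=True)
        try:
            reg = analytics.fit_diameter_scar_regression(pooled)
            report["regression"] = {
                "slope_um_per_scar": reg.slope_um_per_scar,
                "intercept_um": reg.intercept_um,
                "n": reg.n,
            }
        except ScarflowError:
            report["regression"] = None

    if write_outputs:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        sorted_cells.to_csv(outdir / "cells_sorted.csv", index=False)
        for port, pcells in ports.items():
            pcells.to_csv(outdir / f"cells_port{port}.csv", index=False)
        if measured_tables:
            pd.concat(measured_tables, ignore_index=True).to_csv(
                outdir / "measurements.csv", index=False
            )
        with open(outdir / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        log.log("outputs", directory=str(outdir))
    return report
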