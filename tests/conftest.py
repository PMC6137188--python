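"""Shared fixtures: flow conditions, calibrated model, rendered scenes.

Expensive artefacts (the bead-table calibration, the large end-to-end
imaging run) are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scarflow import focusing, imaging, pipeline, population
from scarflow.hydraulics import FlowCondition


@pytest.fixture(scope="session")
def flow_1500() -> FlowCondition:
    return FlowCondition(1500.0)


@pytest.fixture(scope="session")
def calibrated_model() -> focusing.ForceModel:
    """Force model fitted to the measured bead yield/purity record."""
    return focusing.calibrate(focusing.default_bead_table()).model


@pytest.fixture(scope="session")
def clean_scene() -> imaging.SyntheticScene:
    """Noise-free scene of 10 well-separated cells, none touching borders."""
    cells = population.simulate_culture("high_density", 10, seed=3)
    return imaging.render_scene(
        cells, layout=imaging.LayoutParams(border_fraction=0.0), seed=4, noise=False
    )


@pytest.fixture(scope="session")
def noisy_run_500():
    """500 simulated cells rendered with default noise and fully quantified.

    Returns the matched (measurement, ground-truth) table pooled over
    scenes — the shared substrate for accuracy checks.
    """
    cells = population.simulate_culture("high_density", 500, seed=21)
    matched = []
    for i, batch in enumerate(imaging.scene_batches(cells)):
        scene = imaging.render_scene(batch.reset_index(drop=True), seed=300 + i)
        table = pipeline.measure_scene(scene.channels)
        matched.append(pipeline.match_to_ground_truth(table, scene.ground_truth))
    return pd.concat(matched, ignore_index=True)


@pytest.fixture(scope="session")
def e2e_5000():
    """The full-scale synthetic study: 5000 cells imaged and quantified.

    Returns (measurements, matched) where ``measurements`` pools the raw
    per-cell pipeline output and ``matched`` joins it to ground truth.
    """
    cells = population.simulate_culture("high_density", 5000, seed=42)
    tables, matched = [], []
    for i, batch in enumerate(imaging.scene_batches(cells)):
        scene = imaging.render_scene(batch.reset_index(drop=True), seed=1000 + i)
        table = pipeline.measure_scene(scene.channels)
        tables.append(table)
        matched.append(pipeline.match_to_ground_truth(table, scene.ground_truth))
    return (
        pd.concat(tables, ignore_index=True),
        pd.concat(matched, ignore_index=True),
    )
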