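"""Shared fixtures: small synthetic scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

import ablatemap as am
from ablatemap.pipeline import records_from_traces
from ablatemap.segmentation import CellROI, LabelMap
from ablatemap.spatial import ElectrodeGeometry
from ablatemap.synthetic import simulate_traces


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A 128 px field at 10 Hz: every cell is within the ablation radius."""
    return am.SceneConfig(field_height=128, field_width=128, frame_rate=10.0,
                          duration=360.0, n_neurons=25, seed=11)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return am.generate_scene(small_config)


@pytest.fixture(scope="session")
def small_movie(small_scene):
    return am.render_movie(small_scene)


@pytest.fixture(scope="session")
def small_truth_labelmap(small_scene):
    """Ground-truth masks wrapped as a LabelMap (bypasses segmentation)."""
    return truth_labelmap(small_scene)


@pytest.fixture(scope="session")
def population():
    """200-neuron default-geometry scene with trace-level simulation.

    Returns ``(scene, records, dffs)`` computed through the trace-analysis
    pipeline with ground-truth centroids; used by the population-level
    spatial tests.
    """
    cfg = am.SceneConfig(frame_rate=10.0, duration=360.0, n_neurons=200,
                         seed=7)
    scene = am.generate_scene(cfg)
    raw = simulate_traces(scene)
    geom = ElectrodeGeometry(cfg.centre_px, cfg.electrode_radius,
                             cfg.pixel_size)
    centroids = np.array([c.centroid for c in scene.cells])
    records, dffs = records_from_traces(raw, centroids, geom, scene.protocol,
                                        cfg.frame_rate)
    return scene, records, dffs


def truth_labelmap(scene) -> LabelMap:
    rois = []
    for c in scene.cells:
        rr, cc = np.nonzero(scene.label_image == c.id)
        rois.append(CellROI(c.id, np.column_stack([rr, cc]), c.centroid,
                            rr.size, 0.0, 1.0))
    return LabelMap(scene.label_image, rois)


def centroid_recall_precision(scene, labelmap, radius_px: float = 5.0):
    """Match detected against true centroids within ``radius_px``."""
    true_c = np.array([c.centroid for c in scene.cells]).reshape(-1, 2)
    det = labelmap.centroids()
    if len(det) == 0 or len(true_c) == 0:
        return 0.0, 0.0
    d_true, _ = cKDTree(det).query(true_c)
    d_det, _ = cKDTree(true_c).query(det)
    return float(np.mean(d_true <= radius_px)), float(np.mean(d_det <= radius_px))
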