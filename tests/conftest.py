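import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from mcspatial.samples import TissueSample, make_detections
from mcspatial.synthetic import SimulationConfig


def toy_sample(points, region=None, group="control", sample_id="toy"):
    """Build a TissueSample from [(x, y, phenotype), ...] with 4 µm nuclei."""
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    phenos = [p[2] for p in points]
    major = np.full(len(points), 4.0)
    det = make_detections(xs, ys, phenos, major, major * 0.7)
    return TissueSample(sample_id=sample_id, group=group, detections=det,
                        region=region or box(0, 0, 1000, 1000))


@pytest.fixture
def small_config():
    """Fast config: dense MCs on a small region so spatial stats are testable."""
    return SimulationConfig(
        region_width=2000.0,
        region_height=2000.0,
        total_cell_density=3000.0,
        mc_fraction=0.01,
        cluster_mean_offspring=4.0,
        cluster_radius_sd=50.0,
        partner_fractions={"CD8": 0.01, "CD14": 0.01},
        coupling={"CD8": (0.10, 0.18)},
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
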