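import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from herdtrack.config import TrackerConfig
from herdtrack.evaluation import compute_metrics
from herdtrack.io_formats import MOT_COLUMNS
from herdtrack.synthetic import corrupt_detections, generate_scene, \
    scenario_suite
from herdtrack.tracker import run as run_tracker

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def rows_to_df(rows) -> pd.DataFrame:
    return pd.DataFrame([tuple(r) + (-1, -1, -1) for r in rows],
                        columns=MOT_COLUMNS)


@pytest.fixture(scope="session")
def scenario_run():
    """Run a named scenario once per session: returns the generated scene,
    the tracker output and the MOT metrics."""
    cache = {}

    def _run(name):
        if name not in cache:
            cfg = scenario_suite()[name]
            frames, gt, dets = generate_scene(cfg)
            dets = corrupt_detections(dets, cfg)
            rows, log = run_tracker(frames, dets, TrackerConfig())
            hyp = rows_to_df(rows)
            metrics = compute_metrics(gt.to_mot_dataframe(), hyp)
            cache[name] = dict(cfg=cfg, frames=frames, gt=gt, dets=dets,
                               rows=rows, log=log, hyp=hyp, metrics=metrics)
        return cache[name]

    return _run


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_crop(rng):
    """A small random RGB crop with a full mask, for descriptor tests."""
    crop = rng.integers(0, 256, size=(14, 14, 3), dtype=np.uint8)
    mask = np.ones((14, 14), dtype=bool)
    return crop, mask
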