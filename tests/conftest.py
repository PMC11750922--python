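import numpy as np
import pytest

import filagrow as fg


@pytest.fixture(scope="session")
def morph():
    return fg.DEFAULT_MORPHOMETRY


@pytest.fixture(scope="session")
def noise_free_experiment():
    """Default 20-filament experiment, rendered without blur or noise.

    pixel_size 0.5 keeps images small; area recovery is exact by
    construction at any pixel size.
    """
    return fg.make_paper_like_experiment(
        seed=42, pixel_size=0.5, noise=fg.NoiseParams.noise_free())


def make_obs(strip="S1", lane=0, day=0.0, area=68.44, centroid=(100.0, 200.0),
             obs_id=None, touches=False, pixel_size=0.25):
    """Hand-built observation for tracking tests."""
    return fg.FilamentObservation(
        obs_id=obs_id or f"{strip}_d{day:g}_L{lane}_{centroid[1]:.0f}",
        strip_id=strip, lane_id=lane, timepoint=day, area_um2=area,
        centroid=centroid, bbox=(0, 0, 1, 1), touches_roi_edge=touches,
        pixel_size=pixel_size)


@pytest.fixture
def obs_factory():
    return make_obs


def truth_to_observations(truth, strip="S1"):
    """Turn ground-truth records into perfect observations (no imaging)."""
    out = []
    for r in truth.records:
        out.append(fg.FilamentObservation(
            obs_id=f"{r.filament_id}@{r.timepoint:g}",
            strip_id=strip, lane_id=r.lane_id, timepoint=r.timepoint,
            area_um2=r.area_um2,
            centroid=(r.centroid_row_px, r.centroid_col_px),
            bbox=(0, 0, 1, 1), touches_roi_edge=False,
            pixel_size=truth.scene.pixel_size))
    return out


@pytest.fixture
def truth_obs():
    return truth_to_observations
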