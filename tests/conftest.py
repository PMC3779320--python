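"""Shared fixtures: one wild-type and one mutant synthetic scene, segmented
and tracked once per session (they are the expensive inputs reused across
segmentation, index, cycle and acceptance tests)."""

import numpy as np
import pytest

from meltkit import scenes, segmentation as seg, tracking as trk

SCENE_SEED = 1


@pytest.fixture(scope="session")
def wildtype_scene():
    cfg = scenes.scenario_presets()["wildtype"]
    stack, truth = scenes.generate_scene(cfg, SCENE_SEED)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def mutant_scene():
    cfg = scenes.scenario_presets()["mutant"]
    stack, truth = scenes.generate_scene(cfg, SCENE_SEED)
    return cfg, stack, truth


def _segment_stack(stack, channel=1):
    return np.stack([seg.segment_frame(stack[f, channel])
                     for f in range(stack.shape[0])])


@pytest.fixture(scope="session")
def wildtype_masks(wildtype_scene):
    _cfg, stack, _truth = wildtype_scene
    return _segment_stack(stack)


@pytest.fixture(scope="session")
def mutant_masks(mutant_scene):
    _cfg, stack, _truth = mutant_scene
    return _segment_stack(stack)


@pytest.fixture(scope="session")
def wildtype_tracks(wildtype_masks):
    tracks = trk.track(wildtype_masks, max_displacement=10.0)
    events = trk.detect_budding(tracks, wildtype_masks)
    return tracks, events


@pytest.fixture(scope="session")
def mutant_tracks(mutant_masks):
    tracks = trk.track(mutant_masks, max_displacement=10.0)
    events = trk.detect_budding(tracks, mutant_masks)
    return tracks, events


@pytest.fixture(scope="session")
def small_scene_config():
    """A one-cell, four-frame scene that never buds; cheap index testing."""
    base = scenes.scenario_presets()["wildtype"]
    from dataclasses import replace
    return replace(base, frame_shape=(180, 180), n_cells=1, n_frames=4,
                   cycle_period=100, localized_window=(0.0, 1.0))
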