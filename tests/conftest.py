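"""Shared fixtures: a small, fast phantom and an oracle network stub."""

import numpy as np
import pytest

from cardioshape.core import LANDMARK_NAMES, preprocess, PreprocSpec
from cardioshape.net.losses import one_hot, rasterise_landmarks
from cardioshape.phantom import PhantomSpec, make_phantom


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A compact heart on a 40x40x20 grid for unit tests (seconds, not
    minutes); the full-size default spec is exercised by the benchmark."""
    defaults = dict(
        grid_dims=(48, 48, 24),
        spacing=(2.0, 2.0, 2.0),
        lv_endo_radius=9.0,
        lv_epi_radius=13.0,
        rv_radius=13.0,
        rv_offset=10.5,
        rv_wall_thickness=2.5,
        extent=32.0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_spec():
    return small_phantom_spec()


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


class OracleModel:
    """A stand-in 'network' whose forward pass returns (near) one-hot maps of
    stored ground truth — lets pipeline plumbing be tested without training."""

    class cfg:
        n_seg_classes = 5
        n_lm_classes = 7
        in_slices = None

    def __init__(self, labels, landmarks, sharpness=0.98):
        self._lab = labels
        self._lm_grid = rasterise_landmarks(landmarks, labels.shape)
        self._sharp = sharpness
        self.cfg = type("cfg", (), dict(n_seg_classes=5, n_lm_classes=7,
                                        in_slices=labels.shape[2]))

    def forward(self, volume):
        def soften(grid, n):
            oh = one_hot(grid, n)
            return oh * self._sharp + (1 - self._sharp) / n
        return soften(self._lab.data, 5), soften(self._lm_grid, 7)


@pytest.fixture()
def oracle_model(small_phantom):
    _vol, lab, lm = small_phantom
    return OracleModel(lab, lm)


@pytest.fixture(scope="session")
def preprocessed_small(small_phantom, small_spec):
    vol, lab, lm = small_phantom
    return preprocess(vol, PreprocSpec(target_dims=small_spec.grid_dims)), lab, lm
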