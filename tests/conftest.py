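"""Shared fixtures: small rendered scenes with ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from iscatflow.synthetic import (CameraModel, GroundTruthParticle,
                                 OpticsModel, illumination_seed,
                                 make_flatfield_frames, make_scene,
                                 random_particles, render_fov)
from iscatflow.preprocess import build_flat_field, normalize_counts


def gaussian_spot(shape, x0, y0, sigma, amplitude=1.0):
    """Analytic Gaussian spot on a zero background."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2)
                              / (2.0 * sigma ** 2))


@pytest.fixture(scope="session")
def optics_256():
    return OpticsModel(fov_pixels=256)


@pytest.fixture(scope="session")
def camera_noiseless():
    return CameraModel(shot_noise_enabled=False)


@pytest.fixture(scope="session")
def rendered_scene_512():
    """512^2 noisy FOV with 40 known signal particles plus a matched
    flat-field stack; session-scoped because rendering 60 frames is the
    dominant cost of the imaging tests."""
    optics = OpticsModel(fov_pixels=512)
    camera = CameraModel(mean_background_counts=40000)
    parts = random_particles(0, 40, optics, seed=21, min_separation_px=12)
    truth = make_scene(parts, optics, camera, seed=21)
    frame = render_fov(truth)
    ff_frames = make_flatfield_frames(optics, camera, n_frames=60, seed=22,
                                      illum_seed=illumination_seed(21))
    flat = build_flat_field([normalize_counts(f) for f in ff_frames])
    return {"optics": optics, "camera": camera, "particles": parts,
            "truth": truth, "frame": frame, "flat": flat}
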