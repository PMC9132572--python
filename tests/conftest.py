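"""Shared fixtures: small synthetic shapes and a desk-scale stimulus catalog."""

import numpy as np
import pytest

from skelshape.stimuli import (RenderConfig, Segment, SkeletonSpec,
                               SurfaceFormSpec, default_render_config,
                               generate_stimulus_set)


@pytest.fixture(scope="session")
def three_part_spec() -> SkeletonSpec:
    """Vertical root with two side branches."""
    return SkeletonSpec((
        Segment(parent=None, attach_t=0.0, direction=(0, 1, 0), length=1.0),
        Segment(parent=0, attach_t=0.3, direction=(1, 0.2, 0), length=0.6),
        Segment(parent=0, attach_t=0.8, direction=(-0.8, 0.3, 0.4), length=0.5),
    ))


@pytest.fixture(scope="session")
def plain_form() -> SurfaceFormSpec:
    return SurfaceFormSpec(base_radius=0.12)


@pytest.fixture(scope="session")
def small_catalog():
    """2 skeletons x 2 forms at 48 px / 20 frames: fast enough for unit tests."""
    duration = 2 * 60.0 / 12.0
    cfg = RenderConfig(image_size=48, n_frames=20, rotation_amplitude=60.0,
                       angular_speed=12.0, fps=20 / duration)
    return generate_stimulus_set(2, 2, seed=11, cfg=cfg, candidate_pool=6)


@pytest.fixture(scope="session")
def rect_mask():
    """200 x 51 filled rectangle inside a larger frame (odd height, so pixel
    row 40 lies exactly on the medial line)."""
    m = np.zeros((82, 220), dtype=bool)
    m[15:66, 10:210] = True
    return m


@pytest.fixture(scope="session")
def disk_mask():
    yy, xx = np.mgrid[0:61, 0:61]
    return (yy - 30) ** 2 + (xx - 30) ** 2 <= 20 ** 2
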