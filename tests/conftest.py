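"""Shared fixtures: small, fast synthetic scenes."""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from moonwatch.scene import SceneConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def small_scene() -> SceneConfig:
    """420x420 scene, 0.7 deg FOV: moon disk radius 156 px, fast to render."""
    return SceneConfig(
        frame_width_px=420,
        frame_height_px=420,
        field_of_view_deg=0.7,
        fps_nominal=25.0,
        rng_seed=11,
    )


@pytest.fixture
def disk_image():
    """Synthetic bright disk (230 on background 10), radius 120 at (200, 150)."""

    def make(width=400, height=300, cx=200.0, cy=150.0, r=120.0, hi=230, lo=10):
        yy, xx = np.mgrid[0:height, 0:width]
        img = np.full((height, width), lo, dtype=np.uint8)
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = hi
        return img

    return make
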