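import numpy as np
import pytest

from flywalk.geometry import View, default_arena, pixel_to_ray, project_to_view


@pytest.fixture(scope="session")
def geom():
    """Default apparatus geometry (camera 95 mm / 50 deg / VGA, mirrors 39 deg)."""
    return default_arena()


def sample_tube_points(rng, geom, n, z_margin=0.0):
    """Uniform random points inside the tube volume."""
    r = geom.tube_radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    z = rng.uniform(z_margin, geom.tube_height - z_margin, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def rays_for_point(p, geom, views=(View.DIRECT, View.LEFT, View.RIGHT), noise_px=0.0, rng=None):
    """Project a world point into the given views and back-project the rays."""
    rays = []
    for v in views:
        u, vv = project_to_view(p, v, geom)
        if noise_px > 0.0:
            u += rng.normal(0.0, noise_px)
            vv += rng.normal(0.0, noise_px)
        rays.append(pixel_to_ray((u, vv), v, geom))
    return rays
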