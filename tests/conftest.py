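import logging
import warnings

import numpy as np
import pytest

import vaxdyn as v

logging.getLogger("vaxdyn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    """A compact world: 3x3 grid, 400 households, 4 rounds."""
    return v.WorldConfig(
        n_units=9,
        grid_shape=(3, 3),
        n_households=400,
        n_rounds=4,
        round_effects=(0.0, 0.0, -0.10, 0.05),
        n_constituencies=4,
        n_roads=15,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return v.generate_world(small_config)


@pytest.fixture(scope="session")
def world_files(small_world, tmp_path_factory):
    out = tmp_path_factory.mktemp("world")
    paths = v.write_world(small_world, out)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def winding_number_contains(poly_coords, x, y):
    """Independent point-in-polygon oracle (winding number, pure Python).

    ``poly_coords`` is the exterior ring as a list of (x, y); boundary points
    count as inside.
    """
    pts = list(poly_coords)
    if pts[0] == pts[-1]:
        pts = pts[:-1]
    wn = 0
    n = len(pts)
    for i in range(n):
        x0, y0 = pts[i]
        x1, y1 = pts[(i + 1) % n]
        # boundary check: point on segment
        cross = (x1 - x0) * (y - y0) - (x - x0) * (y1 - y0)
        if abs(cross) < 1e-12:
            if min(x0, x1) - 1e-12 <= x <= max(x0, x1) + 1e-12 and min(y0, y1) - 1e-12 <= y <= max(y0, y1) + 1e-12:
                return True
        if y0 <= y:
            if y1 > y and cross > 0:
                wn += 1
        else:
            if y1 <= y and cross < 0:
                wn -= 1
    return wn != 0
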