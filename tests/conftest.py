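import numpy as np
import pytest

import rescuekit as rk


@pytest.fixture(scope="session")
def default_counts():
    """One default six-condition count simulation shared across tests."""
    spec = rk.CountsSimSpec(seed=5)
    counts, design, truth = rk.gen_counts(spec)
    return spec, counts, design, truth


@pytest.fixture()
def disk_image():
    """Five bright disks (r = 8) on a dim background, with centers."""
    img = np.full((200, 200), 10.0)
    centers = [(30, 30), (30, 150), (100, 90), (170, 40), (170, 160)]
    yy, xx = np.mgrid[0:200, 0:200]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 64] = 200.0
    return img, centers
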