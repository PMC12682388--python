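from __future__ import annotations

import numpy as np
import pytest

from octcfa.labels import INTIMA, LIPID, LUMEN, MEDIA


def make_annulus_frame(
    grid=240,
    lumen_r=50.0,
    lipid_inner=56.0,
    lipid_outer=80.0,
    arc=(0.0, 360.0),
    spacing=10.0,
):
    """Analytic concentric geometry: lumen disc, intima, lipid ring sector."""
    from octcfa.frame import SegmentationFrame

    c = (grid - 1) / 2.0
    y, x = np.mgrid[0:grid, 0:grid].astype(float)
    r = np.hypot(x - c, y - c)
    theta = np.degrees(np.arctan2(y - c, x - c)) % 360.0
    labels = np.zeros((grid, grid), dtype=np.uint8)
    labels[r <= lipid_outer + 15] = INTIMA
    labels[(r > lipid_outer + 15) & (r <= lipid_outer + 23)] = MEDIA
    a0, a1 = arc
    if (a0, a1) != (0.0, 0.0):
        width = (a1 - a0) % 360.0 or 360.0
        sector = ((theta - a0) % 360.0) < width
        labels[sector & (r > lipid_inner) & (r <= lipid_outer)] = LIPID
    labels[r <= lumen_r] = LUMEN
    return SegmentationFrame(labels=labels, pixel_spacing_um=spacing)


def make_random_blob_frame(rng, grid=160):
    """Random frame: lumen disc plus random lipid (and guidewire) discs."""
    from octcfa.frame import SegmentationFrame

    c = (grid - 1) / 2.0
    y, x = np.mgrid[0:grid, 0:grid].astype(float)
    labels = np.full((grid, grid), INTIMA, dtype=np.uint8)
    lumen_r = rng.uniform(15, 30)
    labels[np.hypot(x - c, y - c) <= lumen_r] = LUMEN
    for _ in range(rng.integers(1, 5)):
        bx = rng.uniform(10, grid - 10)
        by = rng.uniform(10, grid - 10)
        br = rng.uniform(4, 22)
        labels[np.hypot(x - bx, y - by) <= br] = LIPID
    if rng.uniform() < 0.4:
        gx = rng.uniform(20, grid - 20)
        gy = rng.uniform(20, grid - 20)
        labels[np.hypot(x - gx, y - gy) <= rng.uniform(2, 6)] = 1  # guidewire
    # re-assert some lumen so a centroid always exists
    labels[np.hypot(x - c, y - c) <= max(lumen_r - 6, 4)] = LUMEN
    return SegmentationFrame(labels=labels, pixel_spacing_um=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def annulus_frame():
    return make_annulus_frame()
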