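import numpy as np
import pytest

from glut4quant.segmentation import segment_fibre
from glut4quant.synth import generate_fibre_geometry, plant_spots, render_image


@pytest.fixture(scope="session")
def circle_truth():
    """Noise-free circular fibre, radius 30 μm at 0.2 μm/px (150 px)."""
    return generate_fibre_geometry(30.0, 0.0, 0.2, seed=1)


@pytest.fixture(scope="session")
def circle_image(circle_truth):
    return render_image(circle_truth, psf_sigma_um=0.2, noise=None)


@pytest.fixture(scope="session")
def circle_roi(circle_image):
    return segment_fibre(circle_image.channel("dystrophin"), 2.5,
                         circle_image.pixel_size)


@pytest.fixture(scope="session")
def spotted_truth():
    """Irregular fibre with a known spot population (noise-free render)."""
    geo = generate_fibre_geometry(28.0, 0.12, 0.2, seed=7)
    return plant_spots(geo, n_large=12, n_small=40, seed=0)


@pytest.fixture(scope="session")
def spotted_image(spotted_truth):
    return render_image(spotted_truth, psf_sigma_um=0.2, noise=None)


@pytest.fixture(scope="session")
def spotted_roi(spotted_image):
    return segment_fibre(spotted_image.channel("dystrophin"), 2.5,
                         spotted_image.pixel_size)


def brute_force_polyline_distance(points, polyline):
    """Independent point-to-closed-polyline distance (exact segment math)."""
    pts = np.asarray(points, dtype=float)
    a = np.asarray(polyline, dtype=float)
    b = np.roll(a, -1, axis=0)
    ab = b - a
    denom = (ab ** 2).sum(axis=1)
    denom[denom == 0] = 1.0
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        ap = p - a
        t = np.clip((ap * ab).sum(axis=1) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        out[i] = np.sqrt(((p - proj) ** 2).sum(axis=1).min())
    return out
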