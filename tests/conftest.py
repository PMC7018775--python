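import numpy as np
import pytest

from gelcontact import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def five_ellipse_image():
    """Five well-separated same-shape ellipses (random orientations) plus 20
    sub-threshold speckle disks, with the rendering ground truth."""
    shape_rng = np.random.default_rng(7)
    a, b = 25.0, 12.0
    cells = []
    for i in range(5):
        cells.append(
            sd.EllipseCell(
                center=(90.0 + 160.0 * i, 90.0),
                a=a,
                b=b,
                orientation=float(shape_rng.uniform(0, np.pi)),
            )
        )
    # speckles: disks of radius 3 (~29 px, far below the 100-px cut)
    for j in range(20):
        cells.append(
            sd.EllipseCell(center=(30.0 + 38.0 * j, 200.0), a=3.0, b=3.0, intensity=180.0)
        )
    spec = sd.SyntheticImageSpec(
        width=840, height=260, cells=tuple(cells), background_intensity=20.0, noise_sd=5.0, seed=11
    )
    return sd.render_image(spec), (a, b)
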