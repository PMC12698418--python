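import numpy as np
import pytest
from hypothesis import settings

from collagensig.segmentation import ROIImage
from collagensig.simulate import FiberFieldParams, simulate_fiber_image

settings.register_profile("deterministic", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def straight_fiber_params() -> FiberFieldParams:
    """A single noiseless straight fiber, anchored at the image center."""
    return FiberFieldParams(n_fibers=1, curvature_sd=0.0, background_noise_sd=0.0,
                            crosslink_rate=0.0, length_mean=300.0, length_sd=0.0,
                            fiber_intensity_sd=0.0, start_at_center=True)


@pytest.fixture(scope="session")
def default_roi():
    """One default-parameter simulated ROI (512 px, ~1000 um FOV)."""
    img, gt = simulate_fiber_image(FiberFieldParams(), seed=7)
    return img, gt


def make_line_image(lines, shape=(64, 64), value=200, half_width=1,
                    pixel_size_um=1.0) -> ROIImage:
    """Binary-ish image with thick straight lines; helper for constructed
    geometry tests.  ``lines`` are ((r0, c0), (r1, c1)) pairs."""
    from skimage.draw import line as draw_line

    img = np.zeros(shape, dtype=np.uint8)
    for (r0, c0), (r1, c1) in lines:
        rr, cc = draw_line(r0, c0, r1, c1)
        img[rr, cc] = value
    if half_width > 0:
        from scipy.ndimage import grey_dilation
        img = grey_dilation(img, size=(2 * half_width + 1, 2 * half_width + 1))
    return ROIImage(img, pixel_size_um)
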