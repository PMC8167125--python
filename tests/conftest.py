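import numpy as np
import pytest
import scipy.ndimage as ndi


@pytest.fixture(scope="session")
def textured_rgb():
    """A smooth but feature-rich white-light frame (200x300)."""
    rng = np.random.default_rng(0)
    tex = ndi.gaussian_filter(rng.uniform(0, 255, (200, 300)), 2)
    tex = (tex - tex.min()) / np.ptp(tex) * 200 + 20
    return np.repeat(tex[..., None], 3, -1).astype(np.uint8)


@pytest.fixture(scope="session")
def checkerboard_rgb():
    """8x8 checkerboard of 20 px squares; interior crossings are ideal corners."""
    sq = 20
    ii, jj = np.indices((8 * sq, 8 * sq))
    board = ((ii // sq + jj // sq) % 2 * 200 + 20).astype(np.uint8)
    return np.repeat(board[..., None], 3, -1)


def make_trace(t, y, fps=None, label="t", cls="control"):
    from fluortrack.intensity import IntensityTrace

    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if fps is None:
        fps = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    return IntensityTrace(
        roi_label=label,
        tissue_class=cls,
        time_s=t,
        intensity_gu=y,
        n_pixels=np.ones(len(t), dtype=int),
        gap_flag=np.zeros(len(t), dtype=bool),
        fps_effective=fps,
    )
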