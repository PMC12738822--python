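import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def rasterized_iou(box_a, box_b, resolution=1000):
    """Independent IoU oracle: rasterise both boxes on a sub-pixel grid.

    The grid spans the union's bounding region at `resolution` cells along
    the longer side; cell centers are tested for membership.
    """
    def corners(b):
        cx, cy, w, h = b
        return cx - w / 2, cx + w / 2, cy - h / 2, cy + h / 2

    ax0, ax1, ay0, ay1 = corners(box_a)
    bx0, bx1, by0, by1 = corners(box_b)
    x0, x1 = min(ax0, bx0), max(ax1, bx1)
    y0, y1 = min(ay0, by0), max(ay1, by1)
    if x1 <= x0 or y1 <= y0:
        return 0.0
    nx = ny = resolution  # 1000 x 1000 sub-pixel grid over the union's extent
    xs = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
    ys = y0 + (np.arange(ny) + 0.5) * (y1 - y0) / ny
    xx, yy = np.meshgrid(xs, ys)
    in_a = (xx >= ax0) & (xx <= ax1) & (yy >= ay0) & (yy <= ay1)
    in_b = (xx >= bx0) & (xx <= bx1) & (yy >= by0) & (yy <= by1)
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 0.0
    return np.count_nonzero(in_a & in_b) / union
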