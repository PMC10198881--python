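import math

import numpy as np
import pytest

from spt_modes import Segment


def brownian_segment(rng, n, d, dt=0.02, sigma=0.0, cell_id=0, seg_id=0):
    """Free 2D Brownian segment with optional localization noise."""
    steps = rng.normal(0.0, math.sqrt(2 * d * dt), size=(n, 2))
    steps[0] = 0.0
    pos = np.cumsum(steps, axis=0)
    if sigma > 0:
        pos = pos + rng.normal(0.0, sigma, size=pos.shape)
    return Segment(
        cell_id=cell_id, segment_id=seg_id, frames=np.arange(n), xy=pos,
        uncertainty=np.full(n, sigma),
    )


def confined_segment(rng, n, d, radius, dt=0.02, sigma=0.0, cell_id=0, seg_id=0):
    """Random walk reflected at a circular corral, plus localization noise."""
    pos = np.empty((n, 2))
    cur = np.zeros(2)
    pos[0] = cur
    steps = rng.normal(0.0, math.sqrt(2 * d * dt), size=(n - 1, 2))
    for i, s in enumerate(steps, start=1):
        cur = cur + s
        norm = float(np.hypot(*cur))
        if norm > radius:
            folded = 2 * radius - norm
            cur = cur * (max(folded, 0.0) / norm if folded > 0 else radius / norm)
        pos[i] = cur
    if sigma > 0:
        pos = pos + rng.normal(0.0, sigma, size=pos.shape)
    return Segment(
        cell_id=cell_id, segment_id=seg_id, frames=np.arange(n), xy=pos,
        uncertainty=np.full(n, sigma),
    )


def static_segment(n, sigma=0.0, rng=None, cell_id=0, seg_id=0):
    pos = np.zeros((n, 2))
    if sigma > 0:
        pos = pos + rng.normal(0.0, sigma, size=pos.shape)
    return Segment(
        cell_id=cell_id, segment_id=seg_id, frames=np.arange(n), xy=pos,
        uncertainty=np.full(n, sigma),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
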