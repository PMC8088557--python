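"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from rtqa_bench import Mask3D, default_head_neck_spec, make_phantom

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# oracles (kept deliberately naive and independent of the implementation)
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def brute_surface_indices(data: np.ndarray) -> set[tuple[int, int, int]]:
    """Exhaustive neighbour scan: occupied voxels with a free 6-neighbour."""
    nz, ny, nx = data.shape
    out = set()
    for i, j, k in zip(*np.nonzero(data)):
        for di, dj, dk in _NEIGHBORS:
            a, b, c = i + di, j + dj, k + dk
            if not (0 <= a < nz and 0 <= b < ny and 0 <= c < nx) or not data[a, b, c]:
                out.add((int(i), int(j), int(k)))
                break
    return out


def brute_directed_hd(src: np.ndarray, dst: np.ndarray, p: float) -> float:
    """All-pairs minimum distances plus hand-rolled nearest-rank percentile."""
    diffs = src[:, None, :] - dst[None, :, :]
    mins = np.sqrt((diffs**2).sum(axis=2)).min(axis=1)
    mins = np.sort(mins)
    k = math.ceil(p * len(mins) / 100.0)
    return float(mins[max(k, 1) - 1])


def brute_dsi(a: np.ndarray, b: np.ndarray) -> float:
    """Set-based Dice on voxel index tuples."""
    sa = set(map(tuple, np.argwhere(a)))
    sb = set(map(tuple, np.argwhere(b)))
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def brute_inverse_dvh(doses: np.ndarray, percent_volume: float) -> float:
    """Inverse cumulative DVH via hand-rolled linear order-statistic
    interpolation at quantile (100 - x)/100."""
    v = np.sort(np.asarray(doses, dtype=float))
    n = v.size
    q = (100.0 - percent_volume) / 100.0
    h = (n - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def random_mask(rng: np.random.Generator, shape, spacing, origin=(0, 0, 0), density=0.3) -> Mask3D:
    data = rng.random(shape) < density
    if not data.any():
        data[tuple(rng.integers(0, s) for s in shape)] = True
    return Mask3D(data, spacing, origin)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def head_neck_gold():
    """The default 15-structure benchmark phantom (shared; treat read-only)."""
    return make_phantom(default_head_neck_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
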