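"""Shared fixtures and independent brute-force oracles.

The oracles deliberately enumerate voxel pairs in plain Python loops,
independent of the vectorized implementations they validate.
"""

import numpy as np
import pytest

from hemispan.volume import LEFT, RIGHT, BoldVolume4D


def pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def brute_force_ai(vol, threshold, use_absolute=False):
    """Exhaustive pairwise-enumeration Autonomy Index."""
    n = vol.n_voxels
    ai = np.zeros(n)
    for v in range(n):
        ni = nc = 0
        for w in range(n):
            if w == v:
                continue
            r = pearson(vol.series[v], vol.series[w])
            connected = (abs(r) if use_absolute else r) > threshold
            if not connected:
                continue
            if vol.hemilabel[w] == vol.hemilabel[v]:
                ni += 1
            else:
                nc += 1
        hi = int(np.sum(vol.hemilabel == vol.hemilabel[v])) - 1
        hc = int(np.sum(vol.hemilabel == -vol.hemilabel[v]))
        ai[v] = ni / hi - nc / hc
    return ai


def brute_force_cfh(vol):
    """Exhaustive max-correlation search over the contralateral hemisphere."""
    n = vol.n_voxels
    cfh = np.zeros(n)
    partner = np.zeros(n, dtype=int)
    for v in range(n):
        best_r, best_w = -2.0, -1
        for w in range(n):
            if vol.hemilabel[w] == vol.hemilabel[v]:
                continue
            r = pearson(vol.series[v], vol.series[w])
            if r > best_r + 1e-15:
                best_r, best_w = r, w
        cfh[v] = best_r
        partner[v] = best_w
    return cfh, partner


def make_volume(series_left, series_right):
    """Tiny volume from explicit per-voxel series lists (left then right).

    Voxels are laid out on a (2, k, 1) grid: left voxels at x=0, their
    geometric mirrors at x=1.
    """
    series_left = np.asarray(series_left, float)
    series_right = np.asarray(series_right, float)
    k = max(len(series_left), len(series_right))
    mask = np.zeros((2, k, 1), dtype=bool)
    mask[0, : len(series_left), 0] = True
    mask[1, : len(series_right), 0] = True
    data = np.zeros((2, k, 1, series_left.shape[1]))
    data[0, : len(series_left), 0] = series_left
    data[1, : len(series_right), 0] = series_right
    return BoldVolume4D.from_array(data, mask)


def random_volume(rng, shape=(4, 4, 3), n_timepoints=30):
    data = rng.standard_normal(shape + (n_timepoints,))
    return BoldVolume4D.from_array(data)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
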