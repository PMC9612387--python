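"""Texture-matrix builders operating on discretized gray-level volumes.

All builders take a ``levels`` volume (int, gray levels 1..Ng inside the VOI,
0 outside) produced by :func:`fetrad.features.discretize.discretize`.

Conventions (documented in docs/methods.md):

* distance 1, 26-neighborhood; GLCM/GLRLM use the 13 unique 3D directions
  (the other 13 are their negatives);
* GLCM matrices are symmetrized per direction;
* GLSZM zones use 26-connectivity;
* GLDM dependence size j counts the centre voxel plus its neighbors with
  identical gray level (alpha = 0), so j ranges 1..27;
* NGTDM neighborhood averages use only in-mask neighbors; voxels without any
  in-mask neighbor do not contribute.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrices",
    "glrlm_matrices",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_stats",
]

DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in ((-1, 0, 1) if dx == 1 else (0, 1))
    for dz in ((-1, 0, 1) if (dx, dy) != (0, 0) else (1,))
)
assert len(DIRECTIONS_13) == 13

_ALL_26 = tuple(d for d in DIRECTIONS_13) + tuple(
    (-a, -b, -c) for a, b, c in DIRECTIONS_13
)


def _neighbor_values(a: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """out[v] = a[v + d], 0 where v + d leaves the grid."""
    out = np.zeros_like(a)
    src, dst = [], []
    for dim, delta in enumerate(d):
        n = a.shape[dim]
        if abs(delta) >= n:
            return out
        if delta >= 0:
            dst.append(slice(0, n - delta))
            src.append(slice(delta, n))
        else:
            dst.append(slice(-delta, n))
            src.append(slice(0, n + delta))
    out[tuple(dst)] = a[tuple(src)]
    return out


def glcm_matrices(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts per direction, shape (13, Ng, Ng)."""
    out = np.zeros((len(DIRECTIONS_13), n_levels, n_levels))
    for k, d in enumerate(DIRECTIONS_13):
        nb = _neighbor_values(levels, d)
        valid = (levels > 0) & (nb > 0)
        i = levels[valid] - 1
        j = nb[valid] - 1
        np.add.at(out[k], (i, j), 1.0)
        out[k] += out[k].T.copy()
    return out


def glrlm_matrices(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts per direction, shape (13, Ng, max_run)."""
    max_run = max(levels.shape)
    out = np.zeros((len(DIRECTIONS_13), n_levels, max_run))
    shape = np.asarray(levels.shape)
    for k, d in enumerate(DIRECTIONS_13):
        dv = np.asarray(d)
        prev = _neighbor_values(levels, tuple(-x for x in d))
        start = (levels > 0) & (prev != levels)
        coords = np.argwhere(start)
        glev = levels[start]  # same C-order as argwhere
        length = 1
        while coords.size:
            nxt = coords + dv
            inside = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(len(coords), dtype=bool)
            if inside.any():
                idx = tuple(nxt[inside].T)
                cont[inside] = levels[idx] == glev[inside]
            ended = ~cont
            if ended.any():
                np.add.at(out[k], (glev[ended] - 1, length - 1), 1.0)
            coords = nxt[cont]
            glev = glev[cont]
            length += 1
    return out


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts (26-connectivity), shape (Ng, max_zone_size)."""
    n_vox = int(np.count_nonzero(levels))
    out = np.zeros((n_levels, n_vox))
    structure = np.ones((3, 3, 3), dtype=int)
    for g in range(1, n_levels + 1):
        binary = levels == g
        if not binary.any():
            continue
        labeled, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            out[g - 1, s - 1] += 1.0
    return out


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts, shape (Ng, 27); column j-1 holds dependence size j."""
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int32)
    for d in _ALL_26:
        nb = _neighbor_values(levels, d)
        dep += ((nb > 0) & (np.abs(nb - levels) <= alpha)).astype(np.int32)
    out = np.zeros((n_levels, 27))
    np.add.at(out, (levels[mask] - 1, dep[mask]), 1.0)  # j = dep + 1 (centre included)
    return out


def ngtdm_stats(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood gray-tone difference sums and level counts.

    Returns ``(s, n)`` with ``s[i-1]`` = sum over voxels of level i of
    |i - mean(in-mask 26-neighborhood)| and ``n[i-1]`` the number of
    contributing voxels (those with at least one in-mask neighbor).
    """
    mask = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=np.int32)
    for d in _ALL_26:
        nb = _neighbor_values(levels, d)
        valid = nb > 0
        nb_sum += np.where(valid, nb, 0)
        nb_cnt += valid.astype(np.int32)
    contrib = mask & (nb_cnt > 0)
    diff = np.zeros(levels.shape, dtype=float)
    diff[contrib] = np.abs(
        levels[contrib] - nb_sum[contrib] / nb_cnt[contrib]
    )
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    np.add.at(s, levels[contrib] - 1, diff[contrib])
    np.add.at(n, levels[contrib] - 1, 1.0)
    return s, n
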