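"""Naive, loop-based reference constructions of the texture matrices.

Deliberately written as plain Python scalar loops, independent of the
vectorized builders in fetrad.features.matrices.
"""

import numpy as np

DIRS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]
DIRS_26 = DIRS_13 + [(-a, -b, -c) for a, b, c in DIRS_13]


def _inside(shape, c):
    return all(0 <= c[i] < shape[i] for i in range(3))


def naive_glcm(levels, n_levels):
    out = np.zeros((13, n_levels, n_levels))
    shape = levels.shape
    for k, d in enumerate(DIRS_13):
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    g1 = levels[x, y, z]
                    if g1 == 0:
                        continue
                    nb = (x + d[0], y + d[1], z + d[2])
                    if not _inside(shape, nb):
                        continue
                    g2 = levels[nb]
                    if g2 == 0:
                        continue
                    out[k, g1 - 1, g2 - 1] += 1
                    out[k, g2 - 1, g1 - 1] += 1  # symmetrize
    return out


def naive_glrlm(levels, n_levels):
    max_run = max(levels.shape)
    out = np.zeros((13, n_levels, max_run))
    shape = levels.shape
    for k, d in enumerate(DIRS_13):
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    g = levels[x, y, z]
                    if g == 0:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _inside(shape, prev) and levels[prev] == g:
                        continue  # not a run start
                    length = 1
                    cur = (x + d[0], y + d[1], z + d[2])
                    while _inside(shape, cur) and levels[cur] == g:
                        length += 1
                        cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                    out[k, g - 1, length - 1] += 1
    return out


def naive_glszm(levels, n_levels):
    n_vox = int(np.count_nonzero(levels))
    out = np.zeros((n_levels, n_vox))
    visited = np.zeros(levels.shape, dtype=bool)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0 or visited[x, y, z]:
                    continue
                stack = [(x, y, z)]
                visited[x, y, z] = True
                size = 0
                while stack:
                    c = stack.pop()
                    size += 1
                    for d in DIRS_26:
                        nb = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
                        if _inside(shape, nb) and not visited[nb] and levels[nb] == g:
                            visited[nb] = True
                            stack.append(nb)
                out[g - 1, size - 1] += 1
    return out


def naive_gldm(levels, n_levels, alpha=0):
    out = np.zeros((n_levels, 27))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                dep = 0
                for d in DIRS_26:
                    nb = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, nb) and levels[nb] > 0 and abs(levels[nb] - g) <= alpha:
                        dep += 1
                out[g - 1, dep] += 1  # j = dep + 1, centre voxel included
    return out


def naive_ngtdm(levels, n_levels):
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                vals = []
                for d in DIRS_26:
                    nb = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, nb) and levels[nb] > 0:
                        vals.append(levels[nb])
                if not vals:
                    continue
                s[g - 1] += abs(g - sum(vals) / len(vals))
                n[g - 1] += 1
    return s, n
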