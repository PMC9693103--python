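"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over definitions, deliberately
sharing no code path with the package.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np
from scipy import stats


def bf_discretize(dose: np.ndarray, mask: np.ndarray, width: float = 1.0):
    """floor(d/width)+1 with top-edge clamp; voxel loop."""
    dmax = max(dose[z, y, x] for z, y, x in np.argwhere(mask))
    n_levels = max(1, math.ceil(dmax / width))
    levels = np.zeros(dose.shape, dtype=int)
    for z, y, x in np.argwhere(mask):
        levels[z, y, x] = min(int(dose[z, y, x] // width) + 1, n_levels)
    return levels, n_levels


def bf_glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric merged co-occurrence over all 26 neighbour directions."""
    counts = np.zeros((n_levels, n_levels))
    shape = levels.shape
    offsets = [
        (dz, dy, dx)
        for dz, dy, dx in product((-1, 0, 1), repeat=3)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for z, y, x in np.argwhere(mask):
        for dz, dy, dx in offsets:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]:
                if mask[zz, yy, xx]:
                    counts[levels[z, y, x] - 1, levels[zz, yy, xx] - 1] += 1
    return counts / counts.sum()


def bf_glcm_features(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    py = [sum(p[i, j] for i in range(n)) for j in range(n)]
    mu = sum((i + 1) * px[i] for i in range(n))
    variance = sum(
        p[i, j] * ((i + 1) - mu) ** 2 for i in range(n) for j in range(n)
    )
    contrast = sum(p[i, j] * (i - j) ** 2 for i in range(n) for j in range(n))
    pdiff = [0.0] * n
    for i in range(n):
        for j in range(n):
            pdiff[abs(i - j)] += p[i, j]
    mud = sum(k * pdiff[k] for k in range(n))
    dvar = sum(pdiff[k] * (k - mud) ** 2 for k in range(n))
    ent = -sum(
        p[i, j] * math.log2(p[i, j])
        for i in range(n)
        for j in range(n)
        if p[i, j] > 0
    )
    hx = -sum(q * math.log2(q) for q in px if q > 0)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    ic1 = 0.0 if hx == 0 else (ent - hxy1) / hx
    return {
        "variance": variance,
        "difference_variance": dvar,
        "contrast": contrast,
        "entropy": ent,
        "ic1": ic1,
    }


def bf_histogram_energy(levels: np.ndarray, mask: np.ndarray) -> float:
    vals = [levels[z, y, x] for z, y, x in np.argwhere(mask)]
    return sum((vals.count(v) / len(vals)) ** 2 for v in set(vals))


def bf_vx(dose: np.ndarray, mask: np.ndarray, x: float) -> float:
    hits = total = 0
    for z, y, xx in np.argwhere(mask):
        total += 1
        if dose[z, y, xx] >= x:
            hits += 1
    return 100.0 * hits / total


def bf_dmean(dose: np.ndarray, mask: np.ndarray) -> float:
    vals = [dose[z, y, x] for z, y, x in np.argwhere(mask)]
    return sum(vals) / len(vals)


def exhaustive_max_t_p(data: np.ndarray, labels: np.ndarray):
    """Exact max-T permutation p per voxel by full label enumeration.

    ``data`` is (n, voxels). Also returns the exact per-voxel (unadjusted)
    permutation p, for dominance checks.
    """
    n, n1 = labels.size, int(labels.sum())
    obs_t = np.array([
        stats.ttest_ind(data[labels, v], data[~labels, v], equal_var=False)[0]
        for v in range(data.shape[1])
    ])
    obs = np.abs(obs_t)
    assigns = list(combinations(range(n), n1))
    maxima = []
    pervox = np.zeros(data.shape[1])
    for idx in assigns:
        lab = np.zeros(n, dtype=bool)
        lab[list(idx)] = True
        ts = np.array([
            stats.ttest_ind(data[lab, v], data[~lab, v], equal_var=False)[0]
            for v in range(data.shape[1])
        ])
        ts = np.nan_to_num(np.abs(ts))
        maxima.append(ts.max())
        pervox += ts >= obs - 1e-12
    maxima = np.array(maxima)
    p_fwe = np.array([(maxima >= o - 1e-12).sum() for o in obs]) / len(assigns)
    return p_fwe, pervox / len(assigns)


def allpairs_auc(scores, labels) -> float:
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = wins = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                wins += 1
            elif a == b:
                wins += 0.5
    return wins / total
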