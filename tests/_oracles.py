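"""Independent brute-force oracles used by the unit and acceptance tests:
written as naive loops/enumerations, deliberately separate from the array
implementations they check."""

import itertools

import numpy as np
from scipy import stats

from chronomap.maps import LabelMap


def lmap(arr, voxel_size=1.0):
    arr = np.asarray(arr, float)
    return LabelMap(label=arr, stat=np.where(np.isfinite(arr), 5.0, np.nan),
                    voxel_size=voxel_size)


def brute_force_wrd(label_arr, value, axis, d1, td, voxel_size):
    """Naive per-voxel loop: w_i = Nnbrs_i/Nvd, RD_i = D1_i/TD,
    wRD = sum w_i RD_i / Nvd."""
    label_arr = np.asarray(label_arr, float)
    coords = [tuple(c) for c in np.argwhere(np.isclose(label_arr, value))]
    nvd = len(coords)
    total = 0.0
    for c in coords:
        nbrs = 0
        for ax in range(label_arr.ndim):
            for step in (-1, 1):
                n = list(c)
                n[ax] += step
                if 0 <= n[ax] < label_arr.shape[ax] and tuple(n) in coords:
                    nbrs += 1
        w = nbrs / nvd
        rd = abs(c[axis] * voxel_size - d1) / td
        total += w * rd
    return total / nvd


def brute_force_signed_rank_p(values):
    """Exact one-sided (less) p by enumerating all sign assignments of the
    ranked magnitudes."""
    values = np.asarray(values, float)
    n = len(values)
    ranks = stats.rankdata(np.abs(values))
    w_obs = ranks[values > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= w_obs:
            count += 1
    return count / 2 ** n


def brute_force_kendall(x, y):
    n = len(x)
    num = 0
    tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = np.sign(x[i] - x[j])
            b = np.sign(y[i] - y[j])
            num += a * b
            tx += a != 0
            ty += b != 0
    return num / np.sqrt(tx * ty)
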