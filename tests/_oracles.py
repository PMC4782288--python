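"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the code paths of the package implementation:
distances are computed by exhaustive pairwise enumeration, thickness by
explicit sphere fitting, and Mann-Whitney p-values by enumerating every
group assignment.
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def brute_force_dnv(vessel_mask: np.ndarray) -> np.ndarray:
    """Distance (voxels) from every voxel to the nearest vessel voxel."""
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    vessels = np.argwhere(vessel_mask)
    if len(vessels) == 0:
        raise ValueError("no vessel voxels")
    coords = np.indices(vessel_mask.shape).reshape(3, -1).T
    out = np.empty(len(coords))
    chunk = 4096
    for i in range(0, len(coords), chunk):
        d2 = ((coords[i:i + chunk, None, :].astype(np.int64)
               - vessels[None, :, :]) ** 2).sum(-1)
        out[i:i + chunk] = np.sqrt(d2.min(axis=1))
    return out.reshape(vessel_mask.shape)


def brute_force_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Largest-inscribed-sphere diameter at every mask voxel (voxels).

    For each candidate center c the sphere radius is the exact distance
    to the nearest background voxel; a voxel p is covered by that
    sphere iff |p - c| < r(c).  The thickness at p is twice the largest
    covering radius.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape)
    centers = np.argwhere(mask)
    if len(centers) == 0:
        return out
    background = np.argwhere(~mask)
    if len(background) == 0:
        raise ValueError("mask fills the whole volume")
    radii = np.empty(len(centers))
    chunk = 2048
    for i in range(0, len(centers), chunk):
        d2 = ((centers[i:i + chunk, None, :].astype(np.int64)
               - background[None, :, :]) ** 2).sum(-1)
        radii[i:i + chunk] = np.sqrt(d2.min(axis=1))
    flat = out[mask]
    for c, r in zip(centers, radii):
        d = np.sqrt(((centers - c) ** 2).sum(axis=1))
        covered = d < r
        flat[covered] = np.maximum(flat[covered], 2.0 * r)
    out[mask] = flat
    return out


def enumeration_mannwhitney_p(a, b) -> float:
    """Exact two-tailed Mann-Whitney p by enumerating all assignments.

    Assumes tie-free pooled data.  The p-value is
    2 * min(P(U <= u), P(U >= u)) capped at 1, which for the symmetric
    tie-free null distribution equals P(|U - mean| >= |u - mean|).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size != pooled.size:
        raise ValueError("enumeration oracle requires tie-free data")
    n_a = len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2

    us = np.array([ranks[list(c)].sum() for c
                   in combinations(range(len(pooled)), n_a)])
    us = us - n_a * (n_a + 1) / 2
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)
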