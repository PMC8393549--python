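"""Independent brute-force oracles shared by the test suite.

Everything here is deliberately naive (exhaustive pairwise scans,
explicit enumerations) and independent of the library code paths it
checks.
"""

import itertools

import numpy as np


def brute_boundary(mask):
    """Neighbour-scan boundary: foreground voxels with a face-adjacent
    background voxel (out-of-lattice neighbours are not background)."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    for idx in np.ndindex(mask.shape):
        if not mask[idx]:
            continue
        for axis in range(mask.ndim):
            for step in (-1, 1):
                nb = list(idx)
                nb[axis] += step
                if 0 <= nb[axis] < mask.shape[axis] and not mask[tuple(nb)]:
                    out[idx] = True
    return out


def brute_dtm(mask, spacing=None):
    """Exhaustive min-over-boundary-voxels Euclidean distance field."""
    mask = np.asarray(mask, dtype=bool)
    spacing = np.ones(mask.ndim) if spacing is None else np.asarray(spacing)
    boundary = np.argwhere(brute_boundary(mask)) * spacing
    assert len(boundary), "degenerate mask"
    out = np.empty(mask.shape)
    for idx in np.ndindex(mask.shape):
        d = np.linalg.norm(boundary - np.asarray(idx) * spacing, axis=1)
        out[idx] = d.min()
    return out


def brute_directed_distances(a_surface, b_surface, spacing=None):
    """Min distance from every voxel of surface a to surface b."""
    spacing = (np.ones(a_surface.ndim) if spacing is None
               else np.asarray(spacing))
    pa = np.argwhere(a_surface) * spacing
    pb = np.argwhere(b_surface) * spacing
    return np.array([np.linalg.norm(pb - x, axis=1).min() for x in pa])


def exact_wilcoxon_p(diffs):
    """Two-sided signed-rank p by full enumeration of sign assignments.

    Zeros dropped; average ranks for tied magnitudes.  Feasible for
    n <= ~14.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    order = np.abs(d)
    ranks = np.empty(n)
    srt = np.argsort(order)
    sorted_abs = order[srt]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[srt[i:j]] = (i + j + 1) / 2.0
        i = j
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    stat = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if min(wp, total - wp) <= stat:
            count += 1
    return count / 2 ** n
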