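"""Boundary sets, distance transform maps (DTM) and distance penalty terms (DPT).

Two distance-based per-voxel loss weightings are supported, both derived
from the ground-truth label of a class:

* DTM weighting ``W = 1 + DTM`` emphasises voxels far from the label
  boundary (DTM is the Euclidean distance to the boundary set, zero on
  the boundary itself).
* DPT weighting ``W = 1 + DPT`` emphasises voxels close to the boundary.
  DPT is a bounded, max-normalised inversion of the DTM with range
  [0, 1]: 1 on the boundary, 0 at the voxel(s) farthest from it.

The boundary of a mask is the set of foreground voxels with at least one
background neighbour under face connectivity (4-connectivity in 2D,
6-connectivity in 3D).  Voxels outside the lattice are not treated as
background, so a mask filling the lattice has an empty boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceField",
    "WeightField",
    "DegenerateMaskError",
    "extract_boundary",
    "compute_dtm",
    "compute_dpt",
    "dtm_weight",
    "dpt_weight",
    "class_weight_maps",
]


class DegenerateMaskError(ValueError):
    """Raised when a mask has no boundary (all background or all foreground)."""


@dataclass(frozen=True)
class DistanceField:
    """A nonnegative distance lattice of kind ``"dtm"`` or ``"dpt"``."""

    grid: np.ndarray
    kind: str

    def __post_init__(self):
        if self.kind not in ("dtm", "dpt"):
            raise ValueError(f"unknown distance field kind {self.kind!r}")


@dataclass(frozen=True)
class WeightField:
    """A per-voxel loss-weight lattice, everywhere >= 1."""

    grid: np.ndarray
    scheme: str


def _as_binary(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary (values in {0, 1})")
        arr = arr.astype(bool)
    return arr


def extract_boundary(mask, connectivity: int = 1) -> np.ndarray:
    """Foreground voxels with >= 1 background neighbour.

    Parameters
    ----------
    mask : array-like of {0, 1}
        Binary lattice (any dimensionality).
    connectivity : int
        Neighbourhood order as in :func:`scipy.ndimage.generate_binary_structure`;
        1 (the default) is face connectivity.

    Returns
    -------
    numpy.ndarray of bool
        Boundary set, a subset of the mask; empty iff the mask is empty
        or fills the lattice entirely.
    """
    arr = _as_binary(mask)
    structure = ndimage.generate_binary_structure(arr.ndim, connectivity)
    # border_value=1: out-of-lattice neighbours count as foreground, so a
    # full lattice has no boundary.
    interior = ndimage.binary_erosion(arr, structure=structure, border_value=1)
    return arr & ~interior


def compute_dtm(mask, spacing=None, connectivity: int = 1) -> DistanceField:
    """Euclidean distance to the mask boundary (zero on the boundary).

    Distances are taken to the boundary set itself, so both interior and
    exterior voxels receive positive values.  ``spacing`` scales per-axis
    distances; unit spacing when absent.
    """
    boundary = extract_boundary(mask, connectivity=connectivity)
    if not boundary.any():
        raise DegenerateMaskError("mask has no boundary (empty or full lattice)")
    grid = ndimage.distance_transform_edt(~boundary, sampling=spacing)
    return DistanceField(grid=grid, kind="dtm")


def compute_dpt(mask, spacing=None, connectivity: int = 1) -> DistanceField:
    """Bounded inversion of the DTM: 1 on the boundary, 0 at maximal distance.

    ``DPT = (max(DTM) - DTM) / max(DTM)``, a strictly monotone decreasing
    transform of the DTM with range [0, 1].
    """
    dtm = compute_dtm(mask, spacing=spacing, connectivity=connectivity)
    peak = dtm.grid.max()
    if peak == 0.0:
        # every voxel is boundary; the penalty is maximal everywhere
        grid = np.ones_like(dtm.grid)
    else:
        grid = (peak - dtm.grid) / peak
    return DistanceField(grid=grid, kind="dpt")


def dtm_weight(field: DistanceField) -> WeightField:
    """DTM loss weight ``W = 1 + DTM``; minimum 1, attained on the boundary."""
    if field.kind != "dtm":
        raise ValueError(f"expected a DTM field, got kind {field.kind!r}")
    if (field.grid < 0).any():
        raise ValueError("DTM field has negative entries")
    return WeightField(grid=1.0 + field.grid, scheme="dtm")


def dpt_weight(field: DistanceField) -> WeightField:
    """DPT loss weight ``W = 1 + DPT``; range [1, 2], 2 on the boundary."""
    if field.kind != "dpt":
        raise ValueError(f"expected a DPT field, got kind {field.kind!r}")
    if (field.grid < 0).any() or (field.grid > 1).any():
        raise ValueError("DPT field has entries outside [0, 1]")
    return WeightField(grid=1.0 + field.grid, scheme="dpt")


def class_weight_maps(labels, n_classes: int, scheme: str) -> np.ndarray:
    """Per-class DTM/DPT weight maps for one label lattice.

    Degenerate classes (absent from the lattice, or covering it entirely)
    get an all-ones map, i.e. weighting is a no-op for them; this keeps
    per-slice training loops robust, where empty classes are routine.

    Returns an array of shape ``(n_classes,) + labels.shape``.
    """
    labels = np.asarray(labels)
    if scheme not in ("dtm", "dpt"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    out = np.ones((n_classes,) + labels.shape, dtype=float)
    for c in range(n_classes):
        mask = labels == c
        try:
            field = compute_dtm(mask) if scheme == "dtm" else compute_dpt(mask)
        except DegenerateMaskError:
            logger.debug("class %d degenerate on this lattice; unit weights", c)
            continue
        weight = dtm_weight(field) if scheme == "dtm" else dpt_weight(field)
        out[c] = weight.grid
    return out
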