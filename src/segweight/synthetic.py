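"""Seeded synthetic phantoms emulating imbalanced brain-structure segmentation.

Each phantom volume contains up to four kinds of foreground structure on
a dark background, mirroring the qualitative anatomy of brain MR
segmentation tasks without any anatomical realism:

* ``large-blob`` — a rippled superellipsoid (cerebrum-like, low imbalance),
* ``medium-blob`` — a smooth ellipsoid placed inferior to it (cerebellum-like),
* ``small-blob`` — a small elongated ellipsoid (brainstem-like),
* ``tubes`` — thin random 3D polyline tubes (blood-vessel-like, extreme
  imbalance, variable location and shape).

Class voxel budgets are specified as integer ratios (background first)
and realised almost exactly: every class claims its target number of
voxels by thresholding a smooth shape field at the matching quantile,
smallest classes first, on the voxels still unassigned.  Presets
reproduce the study-like imbalance regimes:

==========  =======================  =========
preset      ratio                    channels
==========  =======================  =========
cerebrum    BG:FG = 9:1              1 (MRC-like)
cerebellum  BG:FG = 86:1             1
brainstem   BG:FG = 352:1            1
vessels     BG:FG = 749:1            1 (MRA-like)
three       BG:CR:BV = 677:72:1      2
four        BG:CR:CL:BV = 668:72:9:1 2
five        BG:CR:CL:BS:BV = 666:72:9:2:1  2
==========  =======================  =========

The MRC-like channel carries a bright rim around the blob union
(cerebrospinal-fluid-like contrast separating brain surface from
background); the MRA-like channel is bright only on tube voxels.
Voxels get per-class mean intensities plus additive Gaussian noise, then
each channel is normalised to zero mean and unit standard deviation.
Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "PRESETS",
    "generate_case",
    "generate_cases",
    "class_frequencies",
    "make_dataset",
    "load_dataset",
]

GEOMETRIES = ("large-blob", "medium-blob", "small-blob", "tubes")

# (ratios incl. background, geometry per foreground class, channel kinds)
PRESETS = {
    "cerebrum": ((9, 1), ("large-blob",), ("mrc",)),
    "cerebellum": ((86, 1), ("medium-blob",), ("mrc",)),
    "brainstem": ((352, 1), ("small-blob",), ("mrc",)),
    "vessels": ((749, 1), ("tubes",), ("mra",)),
    "three": ((677, 72, 1), ("large-blob", "tubes"), ("mrc", "mra")),
    "four": ((668, 72, 9, 1),
             ("large-blob", "medium-blob", "tubes"), ("mrc", "mra")),
    "five": ((666, 72, 9, 2, 1),
             ("large-blob", "medium-blob", "small-blob", "tubes"),
             ("mrc", "mra")),
}

# canonical placement (centre, semi-axes, ripple) in [-1, 1]^3 coordinates
_BLOB_LAYOUT = {
    "large-blob": (np.array([0.0, 0.0, 0.25]), np.array([0.78, 0.78, 0.62])),
    "medium-blob": (np.array([0.0, 0.38, -0.42]), np.array([0.42, 0.36, 0.30])),
    "small-blob": (np.array([0.0, -0.25, -0.45]), np.array([0.16, 0.16, 0.42])),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of one synthetic dataset's geometry and noise.

    ``ratios`` are target voxel ratios, background first; foreground class
    ``c`` (label ``c``) uses ``geometries[c-1]``.  The default desk-scale
    lattice is 96x96x24 at unit spacing; a study-scale 512x512x160 lattice
    at (0.47, 0.47, 1.0) mm works identically but is not the default.
    """

    shape: tuple = (96, 96, 24)
    spacing: tuple = (1.0, 1.0, 1.0)
    ratios: tuple = (9, 1)
    geometries: tuple = ("large-blob",)
    channels: tuple = ("mrc",)
    noise_sigma: float = 0.1
    ripple_amp: float = 0.08
    n_tubes: int = 3
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        if len(self.ratios) != len(self.geometries) + 1:
            raise ValueError("need one ratio per class including background")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be positive")
        unknown = set(self.geometries) - set(GEOMETRIES)
        if unknown:
            raise ValueError(f"unknown geometries {sorted(unknown)}")
        fg = 1.0 - self.ratios[0] / sum(self.ratios)
        if fg > 0.5:
            raise ValueError("infeasible ratios: foreground exceeds half "
                             "of the lattice")

    @property
    def n_classes(self) -> int:
        return len(self.ratios)

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "PhantomSpec":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from "
                             f"{sorted(PRESETS)}")
        ratios, geoms, channels = PRESETS[name]
        return cls(ratios=ratios, geometries=geoms, channels=channels,
                   name=name, **overrides)


@dataclass
class PhantomCase:
    """One generated case: integer labels, image channels, realised
    class frequencies."""

    case_id: str
    labels: np.ndarray          # (nx, ny, nz) integer classes
    image: np.ndarray           # (n_channels, nx, ny, nz) float
    frequencies: np.ndarray     # per-class F_c, sums to 1
    seed: int


def class_frequencies(labels, n_classes: Optional[int] = None) -> np.ndarray:
    """Per-class voxel fractions ``F_c`` (background included; sums to 1)."""
    labels = np.asarray(labels)
    counts = np.bincount(labels.ravel(),
                         minlength=n_classes or labels.max() + 1)
    return counts / labels.size


def _unit_grid(shape):
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _blob_field(spec, geometry, rng, grid):
    """Smooth radial field with minimum inside the blob; lower = more interior."""
    centre, axes = _BLOB_LAYOUT[geometry]
    centre = centre + rng.uniform(-0.06, 0.06, 3)
    axes = axes * rng.uniform(0.88, 1.12, 3)
    x = (grid[0] - centre[0]) / axes[0]
    y = (grid[1] - centre[1]) / axes[1]
    z = (grid[2] - centre[2]) / axes[2]
    power = 2.5 if geometry == "large-blob" else 2.0
    r = (np.abs(x) ** power + np.abs(y) ** power
         + np.abs(z) ** power) ** (1.0 / power)
    amp = spec.ripple_amp if geometry == "large-blob" else spec.ripple_amp / 3
    ripple = np.zeros_like(r)
    for _ in range(3):  # low-frequency surface ripple (sulci-like)
        k = rng.uniform(2.5, 6.0, 3)
        phase = rng.uniform(0, 2 * np.pi)
        ripple += np.sin(k[0] * grid[0] + k[1] * grid[1]
                         + k[2] * grid[2] + phase)
    return r * (1.0 + amp * ripple / 3.0)


def _tube_field(spec, rng, target_count):
    """Distance field to a set of random downward-drifting polylines."""
    nx, ny, nz = spec.shape
    # keep the marked centreline comfortably below the voxel budget so the
    # threshold yields tubes of >= 1 voxel radius
    est_len = 1.5 * nz
    n_tubes = int(np.clip(round(target_count / (2.5 * est_len)), 1,
                          spec.n_tubes))
    marked = np.zeros(spec.shape, dtype=bool)
    for _ in range(n_tubes):
        pos = np.array([rng.uniform(0.25, 0.75) * nx,
                        rng.uniform(0.25, 0.75) * ny,
                        nz - 1.5])
        direction = np.array([rng.uniform(-0.3, 0.3),
                              rng.uniform(-0.3, 0.3), -1.0])
        for _ in range(4 * nz):
            i, j, k = np.round(pos).astype(int)
            if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
                break
            marked[i, j, k] = True
            direction = direction + rng.normal(0.0, 0.25, 3)
            direction[2] -= 0.08  # downward drift
            direction /= np.linalg.norm(direction)
            pos = pos + direction
    if not marked.any():
        marked[nx // 2, ny // 2, nz // 2] = True
    return ndimage.distance_transform_edt(~marked)


def _claim(field, labels, class_id, count):
    """Assign the ``count`` unassigned voxels with smallest field value."""
    free = labels == 0
    idx = np.flatnonzero(free.ravel())
    if count > idx.size:
        raise ValueError("infeasible ratios for the given shape")
    vals = field.ravel()[idx]
    order = np.argpartition(vals, count - 1)[:count]
    labels.ravel()[idx[order]] = class_id


def generate_case(spec: PhantomSpec, case_seed: int,
                  case_id: Optional[str] = None) -> PhantomCase:
    """Generate one phantom case, deterministic given ``(spec, case_seed)``.

    Realised voxel counts match the targets implied by ``spec.ratios`` up
    to rounding; per-case random perturbations of position, size, surface
    ripple and tube paths emulate inter-individual variability.
    """
    rng = np.random.default_rng([spec.seed, int(case_seed)])
    n_vox = int(np.prod(spec.shape))
    fractions = np.asarray(spec.ratios, dtype=float) / sum(spec.ratios)
    targets = np.round(fractions * n_vox).astype(int)
    grid = _unit_grid(spec.shape)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    # smallest classes claim voxels first so thin structures survive
    order = sorted(range(1, spec.n_classes), key=lambda c: targets[c])
    for c in order:
        geometry = spec.geometries[c - 1]
        if geometry == "tubes":
            f = _tube_field(spec, rng, targets[c])
        else:
            f = _blob_field(spec, geometry, rng, grid)
        _claim(f, labels, c, targets[c])

    blob_union = np.zeros(spec.shape, dtype=bool)
    tube_mask = np.zeros(spec.shape, dtype=bool)
    for c in range(1, spec.n_classes):
        mask = labels == c
        if spec.geometries[c - 1] == "tubes":
            tube_mask |= mask
        else:
            blob_union |= mask
    rim = (ndimage.binary_dilation(blob_union, iterations=2)
           & ~blob_union & ~tube_mask)

    image = np.empty((len(spec.channels),) + spec.shape, dtype=np.float64)
    for ch, kind in enumerate(spec.channels):
        if kind == "mrc":
            vol = np.full(spec.shape, 0.2)
            vol[blob_union] = 0.55
            vol[tube_mask] = 0.3
            vol[rim] = 0.95  # CSF-like bright rim around the parenchyma
        elif kind == "mra":
            vol = np.full(spec.shape, 0.15)
            vol[blob_union] = 0.2
            vol[tube_mask] = 0.95
        else:
            raise ValueError(f"unknown channel kind {kind!r}")
        vol = vol + rng.normal(0.0, spec.noise_sigma, spec.shape)
        image[ch] = (vol - vol.mean()) / vol.std()

    return PhantomCase(
        case_id=case_id or f"case_{case_seed:05d}",
        labels=labels,
        image=image,
        frequencies=class_frequencies(labels, spec.n_classes),
        seed=int(case_seed),
    )


def generate_cases(spec: PhantomSpec, case_seeds: Sequence[int],
                   prefix: str = "case") -> list[PhantomCase]:
    return [generate_case(spec, s, case_id=f"{prefix}_{s:05d}")
            for s in case_seeds]


def generate_split(spec: PhantomSpec, n_train: int, n_val: int, n_test: int,
                   seed: int = 0) -> dict:
    """In-memory train/val/test phantom splits with disjoint per-case seeds."""
    spec = dataclasses.replace(spec, seed=seed)
    offsets = {"train": 0, "val": 10_000, "test": 20_000}
    sizes = {"train": n_train, "val": n_val, "test": n_test}
    return {split: generate_cases(spec, range(off, off + sizes[split]),
                                  prefix=split)
            for split, off in offsets.items()}


def _affine(spacing):
    return np.diag(list(spacing) + [1.0])


def make_dataset(spec: PhantomSpec, n_train: int, n_val: int, n_test: int,
                 out_dir, seed: int = 0, force: bool = False) -> dict:
    """Write a phantom dataset (NIfTI image/label pairs + JSON manifest).

    Refuses to write into an existing non-empty directory unless
    ``force``.  Returns the manifest.
    """
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("all split sizes must be >= 1")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    splits = generate_split(spec, n_train, n_val, n_test, seed=seed)
    manifest = {
        "spec": dataclasses.asdict(dataclasses.replace(spec, seed=seed)),
        "seed": seed,
        "splits": {},
    }
    affine = _affine(spec.spacing)
    for split, cases in splits.items():
        entries = []
        for case in cases:
            img_name = f"{case.case_id}_image.nii.gz"
            lbl_name = f"{case.case_id}_label.nii.gz"
            img = np.moveaxis(case.image, 0, -1).astype(np.float32)
            nib.save(nib.Nifti1Image(img, affine), out / img_name)
            nib.save(nib.Nifti1Image(case.labels.astype(np.uint8), affine),
                     out / lbl_name)
            entries.append({"case_id": case.case_id, "seed": case.seed,
                            "image": img_name, "label": lbl_name,
                            "frequencies": case.frequencies.tolist()})
        manifest["splits"][split] = entries
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_dataset(data_dir) -> dict:
    """Reload a written phantom dataset into PhantomCase splits."""
    data = Path(data_dir)
    with open(data / "manifest.json") as fh:
        manifest = json.load(fh)
    n_classes = len(manifest["spec"]["ratios"])
    splits = {}
    for split, entries in manifest["splits"].items():
        cases = []
        for entry in entries:
            labels = np.asarray(nib.load(data / entry["label"]).dataobj)
            labels = labels.astype(np.uint8)
            image = np.asarray(nib.load(data / entry["image"]).dataobj,
                               dtype=np.float64)
            cases.append(PhantomCase(
                case_id=entry["case_id"], labels=labels,
                image=np.moveaxis(image, -1, 0),
                frequencies=class_frequencies(labels, n_classes),
                seed=entry["seed"]))
        splits[split] = cases
    return splits
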