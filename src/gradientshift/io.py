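"""Volumetric I/O, analysis masks and vectorization.

All downstream analysis operates on 1-D vectors extracted from 3-D volumes
over a common analysis mask.  The mask is the intersection of the supports of
the gradient maps (finite *and* nonzero voxels — zeros in a gradient map mark
out-of-support background) with the finite voxels of every activation map.
Zeros in unthresholded contrast maps are valid data and are kept.

Voxel ordering inside a mask is sorted C-order linear index, so vectors are
reproducible across runs and platforms.  Images are never resampled: grids
must match exactly, otherwise an :class:`AlignmentError` is raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "VoxelImage",
    "AnalysisMask",
    "ActivationMap",
    "RegionAtlas",
    "AlignmentError",
    "EmptyMaskError",
    "load_volume",
    "save_volume",
    "load_atlas",
    "build_common_mask",
    "vectorize",
    "scatter_back",
    "extract_region_means",
]

BACKGROUND_SENTINEL = np.nan


class Condition(str, Enum):
    """Task condition of a contrast map."""

    LOOK = "Look"
    REGULATE = "Regulate"


class AlignmentError(ValueError):
    """Two images live on different voxel grids / spatial references."""


class EmptyMaskError(ValueError):
    """The common-support intersection contains no voxels."""


@dataclass
class VoxelImage:
    """A 3-D scalar volume plus its voxel-to-world mapping.

    ``affine`` is treated as an opaque spatial reference: two images are
    aligned iff their grid shapes match and their affines agree elementwise.
    """

    values: np.ndarray
    affine: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected a 3-D volume, got {self.values.ndim}-D "
                f"(offending axes beyond 3: {self.values.shape[3:]})"
            )
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def aligned_with(self, other: "VoxelImage | AnalysisMask | RegionAtlas") -> bool:
        if self.grid_shape != other.grid_shape:
            return False
        other_affine = getattr(other, "affine", None)
        if other_affine is None:
            return True
        return np.array_equal(self.affine, other_affine)


@dataclass
class AnalysisMask:
    """Ordered set of in-analysis voxel linear indices on a fixed grid."""

    indices: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if self.indices.size == 0:
            raise EmptyMaskError("analysis mask is empty")
        if np.any(np.diff(self.indices) <= 0):
            self.indices = np.unique(self.indices)
        n_grid = int(np.prod(self.grid_shape))
        if self.indices[0] < 0 or self.indices[-1] >= n_grid:
            raise ValueError("mask indices out of grid bounds")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def n_voxels(self) -> int:
        return len(self)


@dataclass
class ActivationMap:
    """One subject x condition contrast map, vectorized over a mask."""

    subject_id: str
    condition: Condition
    vector: np.ndarray
    mask: AnalysisMask

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if self.vector.size != len(self.mask):
            raise ValueError(
                f"vector length {self.vector.size} != mask size {len(self.mask)}"
            )
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("activation vector contains non-finite values")


@dataclass
class RegionAtlas:
    """Integer-labelled parcellation volume; 0 is background."""

    labels: np.ndarray
    region_ids: Sequence[int]
    family: str = "cortical"
    affine: np.ndarray | None = None
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3-D volume")
        present = set(np.unique(self.labels[self.labels > 0]).tolist())
        declared = set(int(r) for r in self.region_ids)
        missing = present - declared
        if missing:
            raise ValueError(f"labels present but not declared: {sorted(missing)}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


def load_volume(path: str | Path, name: str | None = None) -> VoxelImage:
    """Load a NIfTI-1 volume; 4-D inputs are rejected, NaNs pass through."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # squeeze trailing singleton dims some writers emit
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: expected 3-D volume, got shape {data.shape} "
            f"(offending axis 3 has length {data.shape[3]})"
        )
    return VoxelImage(values=data.astype(np.float64), affine=img.affine,
                      name=name or path.name)


def save_volume(image: VoxelImage, path: str | Path) -> Path:
    """Write a VoxelImage as NIfTI-1 (float64)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(image.values.astype(np.float64), image.affine), str(path))
    return path


def load_atlas(path: str | Path, names_csv: str | Path | None = None,
               family: str = "cortical") -> RegionAtlas:
    """Read an integer-labelled NIfTI parcellation.

    ``names_csv`` is an optional two-column (region_id, name) table; without
    it, region ids are taken from the labels present in the volume.
    """
    img = load_volume(path)
    labels = np.rint(np.nan_to_num(img.values)).astype(np.int64)
    names: dict[int, str] = {}
    if names_csv is not None:
        table = pd.read_csv(names_csv)
        if table.shape[1] < 2:
            raise ValueError("atlas names CSV needs (region_id, name) columns")
        rid_col, name_col = table.columns[:2]
        names = {int(r): str(n) for r, n in zip(table[rid_col], table[name_col])}
        region_ids = sorted(names)
    else:
        region_ids = sorted(int(v) for v in np.unique(labels) if v > 0)
    return RegionAtlas(labels=labels, region_ids=region_ids, family=family,
                       affine=img.affine, region_names=names)


def _check_aligned(images: Iterable[VoxelImage]) -> None:
    images = list(images)
    ref = images[0]
    for img in images[1:]:
        if not ref.aligned_with(img):
            raise AlignmentError(
                f"images '{ref.name}' and '{img.name}' are not aligned "
                f"(shapes {ref.grid_shape} vs {img.grid_shape})"
            )


def build_common_mask(
    gradient_images: Sequence[VoxelImage],
    activation_images: Sequence[VoxelImage] = (),
    user_mask: VoxelImage | None = None,
) -> AnalysisMask:
    """Intersect supports into a common analysis mask.

    A voxel is kept iff it is finite and nonzero in every gradient image,
    finite in every activation image, and nonzero in ``user_mask`` when given.
    """
    all_images = list(gradient_images) + list(activation_images)
    if user_mask is not None:
        all_images.append(user_mask)
    if not all_images:
        raise ValueError("no images supplied")
    _check_aligned(all_images)

    keep = np.ones(all_images[0].grid_shape, dtype=bool)
    for img in gradient_images:
        keep &= np.isfinite(img.values) & (img.values != 0)
    for img in activation_images:
        keep &= np.isfinite(img.values)
    if user_mask is not None:
        with np.errstate(invalid="ignore"):
            keep &= np.nan_to_num(user_mask.values) != 0
    idx = np.flatnonzero(keep.ravel(order="C"))
    if idx.size == 0:
        raise EmptyMaskError("no voxel survives the support intersection")
    return AnalysisMask(indices=idx, grid_shape=all_images[0].grid_shape,
                        affine=all_images[0].affine.copy())


def vectorize(image: VoxelImage, mask: AnalysisMask) -> np.ndarray:
    """Extract masked values in sorted linear-index order."""
    if image.grid_shape != mask.grid_shape:
        raise AlignmentError(
            f"image '{image.name}' grid {image.grid_shape} != mask grid {mask.grid_shape}"
        )
    vec = image.values.ravel(order="C")[mask.indices]
    n_bad = int(np.count_nonzero(~np.isfinite(vec)))
    if n_bad:
        raise ValueError(f"{n_bad} non-finite voxel(s) inside the analysis mask")
    return vec


def scatter_back(vector: np.ndarray, mask: AnalysisMask,
                 fill: float = BACKGROUND_SENTINEL) -> VoxelImage:
    """Inverse of :func:`vectorize`; background voxels get ``fill``."""
    vector = np.asarray(vector, dtype=np.float64)
    if vector.size != len(mask):
        raise ValueError("vector length does not match mask size")
    flat = np.full(int(np.prod(mask.grid_shape)), fill, dtype=np.float64)
    flat[mask.indices] = vector
    affine = mask.affine if mask.affine is not None else np.eye(4)
    return VoxelImage(values=flat.reshape(mask.grid_shape),
                      affine=affine, name="scattered")


def extract_region_means(
    image: VoxelImage, atlas: RegionAtlas, mask: AnalysisMask
) -> pd.DataFrame:
    """Mean image value per atlas region over (region ∩ mask).

    Returns a DataFrame indexed by region_id with columns ``mean`` and
    ``n_voxels``; regions with no surviving voxel get ``mean = NaN`` (absent,
    not zero).
    """
    if image.grid_shape != atlas.grid_shape:
        raise AlignmentError("image and atlas grids differ")
    if image.grid_shape != mask.grid_shape:
        raise AlignmentError("image and mask grids differ")
    labels_flat = atlas.labels.ravel(order="C")[mask.indices]
    values_flat = image.values.ravel(order="C")[mask.indices]
    rows = []
    for rid in atlas.region_ids:
        sel = labels_flat == rid
        n = int(np.count_nonzero(sel))
        mean = float(values_flat[sel].mean()) if n else np.nan
        rows.append({"region_id": int(rid), "mean": mean, "n_voxels": n})
    return pd.DataFrame(rows).set_index("region_id")
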