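"""Lesion quantification on PET volumes.

Implements the two measurement primitives of the pipeline:

* fractional-isocontour segmentation (default 40 % of the lesion maximum),
  yielding SUV_max and SUV_mean over the connected isocontour volume, and
* the 30 mm spherical liver reference VOI whose SUV_mean anchors the
  tumor-to-liver ratio and the E-PSMA visual score.

Volumes are axis-aligned SUV grids; world coordinates follow
``world = origin + index * spacing`` with 0-based voxel indices.  NIfTI
affines with rotation/shear are rejected rather than resampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DegenerateSignalError, GeometryError, SchemaError

__all__ = [
    "PetVolume",
    "IsocontourResult",
    "isocontour_segment",
    "liver_reference",
    "quantify_lesions",
    "read_seed_list",
]

#: 26-connectivity structuring element used for isocontour component growth.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PetVolume:
    """A 3D PET volume in SUV units on an axis-aligned grid.

    Parameters
    ----------
    values
        3D array of voxel values, already calibrated to SUV.
    spacing
        Voxel edge length per axis in mm, strictly positive.
    origin
        World-space (mm) position of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres."""
        return float(np.prod(self.spacing)) / 1000.0

    def world_to_index(self, point_mm: Sequence[float]) -> np.ndarray:
        """Continuous voxel index of a world-space point (no rounding)."""
        return (np.asarray(point_mm, float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_grids_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates in mm."""
        return tuple(
            self.origin[ax] + self.spacing[ax] * np.arange(self.shape[ax]) for ax in range(3)
        )

    @classmethod
    def from_nifti(cls, path) -> "PetVolume":
        """Load a NIfTI volume; the affine must be axis-aligned (no rotation)."""
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        rot = affine[:3, :3]
        off_diag = rot - np.diag(np.diag(rot))
        if np.any(np.abs(off_diag) > 1e-6):
            raise GeometryError(
                "NIfTI affine contains rotation/shear; only axis-aligned volumes are supported"
            )
        spacing = np.abs(np.diag(rot))
        data = np.asanyarray(img.dataobj, dtype=float)
        if data.ndim != 3:
            raise GeometryError(f"expected a 3D NIfTI volume, got shape {data.shape}")
        return cls(values=data, spacing=tuple(spacing), origin=tuple(affine[:3, 3]))

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))


@dataclass(frozen=True)
class IsocontourResult:
    """Outcome of fractional-isocontour segmentation of one lesion."""

    mask: np.ndarray  # boolean, full-grid shape
    suv_max: float
    suv_mean: float
    fraction: float
    n_voxels: int
    peak_index: tuple[int, int, int]


def _check_box(volume: PetVolume, box: tuple[slice, slice, slice]) -> tuple[slice, slice, slice]:
    slices = []
    for ax, sl in enumerate(box):
        start, stop, step = sl.indices(volume.shape[ax])
        if step != 1 or stop <= start:
            raise GeometryError(f"search_region axis {ax} is empty or strided: {sl}")
        slices.append(slice(start, stop))
    return tuple(slices)


def isocontour_segment(
    volume: PetVolume,
    search_region: tuple[slice, slice, slice],
    fraction: float = 0.40,
) -> IsocontourResult:
    """Segment one lesion with a fractional isocontour.

    SUV_max is the hottest voxel inside ``search_region``.  The mask is the
    26-connected component of voxels ``>= fraction * SUV_max`` that contains
    that peak; growth may extend beyond the search region but is clipped to
    the grid.  SUV_mean averages the volume over the mask.

    Parameters
    ----------
    volume
        The SUV grid.
    search_region
        Voxel-index slices bounding the peak search (e.g. a box around a seed).
    fraction
        Relative threshold in (0, 1); 0.40 reproduces the conventional
        40 % isocontour.

    Raises
    ------
    GeometryError
        If the search region is empty or outside the grid.
    DegenerateSignalError
        If the search region contains no positive signal.
    ValueError
        If ``fraction`` is outside (0, 1).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    box = _check_box(volume, search_region)
    sub = volume.values[box]
    # argmax in the region; ties broken by lowest linear index (argmax default)
    flat = int(np.argmax(sub))
    local = np.unravel_index(flat, sub.shape)
    peak = tuple(int(local[ax] + box[ax].start) for ax in range(3))
    suv_max = float(volume.values[peak])
    if suv_max <= 0.0:
        raise DegenerateSignalError("search region holds no positive uptake")

    above = volume.values >= fraction * suv_max
    labels, _ = ndimage.label(above, structure=_STRUCT_26)
    mask = labels == labels[peak]
    suv_mean = float(volume.values[mask].mean())
    return IsocontourResult(
        mask=mask,
        suv_max=suv_max,
        suv_mean=suv_mean,
        fraction=float(fraction),
        n_voxels=int(mask.sum()),
        peak_index=peak,
    )


def sphere_mask(volume: PetVolume, center_mm: Sequence[float], diameter_mm: float) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the sphere.

    Raises :class:`GeometryError` if the sphere is not fully inside the
    voxel-center extent of the grid (no silent truncation).
    """
    center = np.asarray(center_mm, dtype=float)
    radius = float(diameter_mm) / 2.0
    if radius <= 0:
        raise GeometryError(f"diameter must be positive, got {diameter_mm}")
    for ax in range(3):
        lo = volume.origin[ax]
        hi = volume.origin[ax] + volume.spacing[ax] * (volume.shape[ax] - 1)
        if center[ax] - radius < lo or center[ax] + radius > hi:
            raise GeometryError(
                f"sphere (center {tuple(center)}, radius {radius} mm) extends outside the "
                f"grid along axis {ax} [{lo}, {hi}] mm"
            )
    gx, gy, gz = volume.index_grids_mm()
    d2 = (
        (gx[:, None, None] - center[0]) ** 2
        + (gy[None, :, None] - center[1]) ** 2
        + (gz[None, None, :] - center[2]) ** 2
    )
    return d2 <= radius**2


def liver_reference(
    volume: PetVolume, center_mm: Sequence[float], diameter_mm: float = 30.0
) -> float:
    """SUV_mean over a spherical liver reference VOI (default 30 mm)."""
    mask = sphere_mask(volume, center_mm, diameter_mm)
    if not mask.any():
        raise GeometryError("liver VOI covers no voxel centers; check spacing vs diameter")
    return float(volume.values[mask].mean())


SEED_LIST_COLUMNS = ["lesion_id", "x_mm", "y_mm", "z_mm", "box_halfwidth_mm"]


def read_seed_list(path) -> pd.DataFrame:
    """Read a lesion seed list CSV (lesion_id, x_mm, y_mm, z_mm, box_halfwidth_mm)."""
    df = pd.read_csv(path)
    missing = [c for c in SEED_LIST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"seed list is missing columns: {missing}")
    return df


def _seed_box(volume: PetVolume, center_mm: Sequence[float], halfwidth_mm: float):
    idx = volume.world_to_index(center_mm)
    slices = []
    for ax in range(3):
        half = halfwidth_mm / volume.spacing[ax]
        lo = int(np.floor(idx[ax] - half))
        hi = int(np.ceil(idx[ax] + half)) + 1
        if hi <= 0 or lo >= volume.shape[ax]:
            raise GeometryError(f"seed box lies outside the grid along axis {ax}")
        slices.append(slice(max(lo, 0), min(hi, volume.shape[ax])))
    return tuple(slices)


def quantify_lesions(
    volume: PetVolume,
    seeds: pd.DataFrame,
    liver_center_mm: Sequence[float],
    fraction: float = 0.40,
    liver_diameter_mm: float = 30.0,
) -> pd.DataFrame:
    """Quantify a batch of seeded lesions on one scan.

    Runs :func:`isocontour_segment` in a box around every seed and attaches
    the scan's liver reference SUV_mean to each row.  Errors raised for a
    lesion are re-raised annotated with its ``lesion_id``.

    Returns a DataFrame with columns ``lesion_id, suv_max, suv_mean,
    n_voxels, volume_ml, liver_mean``.
    """
    liver_mean = liver_reference(volume, liver_center_mm, liver_diameter_mm)
    rows = []
    for rec in seeds.itertuples(index=False):
        center = (rec.x_mm, rec.y_mm, rec.z_mm)
        try:
            box = _seed_box(volume, center, rec.box_halfwidth_mm)
            res = isocontour_segment(volume, box, fraction=fraction)
        except (GeometryError, DegenerateSignalError, ValueError) as exc:
            raise type(exc)(f"lesion {rec.lesion_id}: {exc}") from exc
        rows.append(
            {
                "lesion_id": rec.lesion_id,
                "suv_max": res.suv_max,
                "suv_mean": res.suv_mean,
                "n_voxels": res.n_voxels,
                "volume_ml": res.n_voxels * volume.voxel_volume_ml,
                "liver_mean": liver_mean,
            }
        )
    columns = ["lesion_id", "suv_max", "suv_mean", "n_voxels", "volume_ml", "liver_mean"]
    return pd.DataFrame(rows, columns=columns)
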