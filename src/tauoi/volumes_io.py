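"""Reading, writing and validating 3D volumes, label maps and masks.

All downstream metrics assume that serial scans, atlases and masks live on
one common voxel grid.  Volumes are reoriented to the closest canonical
(RAS) axis order on load so that a scan and its atlas can never disagree
silently about axis conventions; no resampling is ever performed, because
resampling would alter cluster topology and hence the overlap index.

Non-finite voxels are carried through I/O untouched; they are excluded (and
counted) only at the point where a statistic is computed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: default per-axis tolerance (mm) for grid-compatibility checks
DEFAULT_GRID_TOL_MM = 1e-3

VALID_UNITS = ("raw", "suvr")


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with voxel spacing and orientation.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (raw counts or SUVR).  Non-finite values are
        permitted and flagged.
    spacing : tuple of float
        Voxel edge lengths in mm, strictly positive.
    affine : ndarray, shape (4, 4)
        Voxel-to-world mapping.
    units : {"raw", "suvr"}
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    units: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume data must be 3D with all dimensions >= 1, "
                f"got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        n_bad = int(np.sum(~np.isfinite(self.data)))
        if n_bad:
            log.warning("volume contains %d non-finite voxels; they are "
                        "excluded from downstream statistics", n_bad)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_nonfinite(self) -> int:
        return int(np.sum(~np.isfinite(self.data)))


@dataclass
class BinaryMask:
    """A 0/1 volume (ROI, CSF segmentation, or thresholded scan mask)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.isin(np.unique(arr), (0, 1)).all():
            raise ValueError("mask data must contain only 0/1 values")
        self.data = arr.astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_set(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelVolume:
    """An integer ROI label map plus a name -> label-id(s) lookup table.

    Bilateral regions are supported by mapping one region name to several
    label ids (e.g. left and right hemisphere labels).
    """

    labels: np.ndarray
    lut: dict[str, tuple[int, ...]]
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must hold integers")
        if self.labels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.labels.shape}")
        self.lut = {str(k): tuple(int(i) for i in v) for k, v in self.lut.items()}
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        empty = self.empty_regions()
        if empty:
            log.warning("lut regions with no voxels in the label map: %s", sorted(empty))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def region_names(self) -> list[str]:
        return list(self.lut)

    def empty_regions(self) -> set[str]:
        """Region names whose label ids never occur in the label grid."""
        present = set(np.unique(self.labels).tolist())
        return {name for name, ids in self.lut.items()
                if not present.intersection(ids)}


@dataclass
class GridCompatibility:
    """Report of a pairwise grid check; ``verdict`` is the conjunction."""

    same_shape: bool
    same_spacing: bool
    same_orientation: bool

    @property
    def verdict(self) -> bool:
        return self.same_shape and self.same_spacing and self.same_orientation


def _grid_of(obj):
    shape = obj.shape
    return shape, obj.spacing, obj.affine


def check_grid(a, b, tol_mm: float = DEFAULT_GRID_TOL_MM) -> GridCompatibility:
    """Verify that two gridded objects live on one common voxel grid.

    Accepts any mix of :class:`Volume3D`, :class:`LabelVolume` and
    :class:`BinaryMask`.  Spacing and orientation are compared elementwise
    with absolute tolerance ``tol_mm``; the check is symmetric.
    """
    shape_a, sp_a, aff_a = _grid_of(a)
    shape_b, sp_b, aff_b = _grid_of(b)
    same_shape = shape_a == shape_b
    same_spacing = np.allclose(sp_a, sp_b, rtol=0.0, atol=tol_mm)
    same_orient = np.allclose(aff_a, aff_b, rtol=0.0, atol=tol_mm)
    return GridCompatibility(same_shape, bool(same_spacing), bool(same_orient))


def require_same_grid(*objs, tol_mm: float = DEFAULT_GRID_TOL_MM) -> None:
    """Raise ``ValueError`` unless all objects share one voxel grid."""
    first = objs[0]
    for other in objs[1:]:
        rep = check_grid(first, other, tol_mm=tol_mm)
        if not rep.verdict:
            raise ValueError(
                "inputs are not on a common voxel grid "
                f"(same_shape={rep.same_shape}, same_spacing={rep.same_spacing}, "
                f"same_orientation={rep.same_orientation}); serial scans and "
                "masks must be co-registered upstream"
            )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_canonical(path):
    try:
        img = nib.load(os.fspath(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several distinct types
        raise ValueError(f"cannot read {path!s} as a NIfTI image: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path!s}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in spacing):
        raise ValueError(f"{path!s}: non-positive voxel spacing {spacing}")
    return data, spacing, np.asarray(img.affine, dtype=float)


def read_volume(path, units: str = "raw") -> Volume3D:
    """Read a 3D NIfTI-1 intensity volume (4D with singleton last axis OK)."""
    data, spacing, affine = _load_canonical(path)
    return Volume3D(data.astype(float), spacing, affine, units=units)


def read_label_volume(path, lut: dict[str, tuple[int, ...]] | None = None) -> LabelVolume:
    """Read an integer atlas/label NIfTI; ``lut`` maps names to label ids."""
    data, spacing, affine = _load_canonical(path)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path!s}: label volume contains non-integer values")
    return LabelVolume(data.astype(np.int32), lut or {}, spacing, affine)


def read_mask(path) -> BinaryMask:
    """Read a binary (0/1) NIfTI mask."""
    data, spacing, affine = _load_canonical(path)
    return BinaryMask(data.astype(np.int8), spacing, affine)


def write_volume(vol, path) -> None:
    """Write a Volume3D / LabelVolume / BinaryMask as NIfTI-1.

    Integer labels and masks round-trip bit-exactly; intensities are stored
    as float32.
    """
    parent = os.path.dirname(os.path.abspath(os.fspath(path)))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    if isinstance(vol, LabelVolume):
        arr, dtype = vol.labels, np.int32
    elif isinstance(vol, BinaryMask):
        arr, dtype = vol.data, np.uint8
    elif isinstance(vol, Volume3D):
        arr, dtype = vol.data, np.float32
    else:
        raise TypeError(f"cannot write object of type {type(vol).__name__}")
    img = nib.Nifti1Image(np.asarray(arr, dtype=dtype), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, os.fspath(path))


# ---------------------------------------------------------------------------
# Lookup tables and ROI masks


def read_lut(path) -> dict[str, tuple[int, ...]]:
    """Read a two-column CSV (label_id, region_name) into a name -> ids map."""
    df = pd.read_csv(path)
    required = {"label_id", "region_name"}
    if not required.issubset(df.columns):
        raise ValueError(f"lut CSV must have columns {sorted(required)}, got {list(df.columns)}")
    lut: dict[str, list[int]] = {}
    for _, row in df.iterrows():
        lut.setdefault(str(row["region_name"]), []).append(int(row["label_id"]))
    return {k: tuple(sorted(v)) for k, v in lut.items()}


def write_lut(lut: dict[str, tuple[int, ...]], path) -> None:
    rows = [{"label_id": i, "region_name": name}
            for name, ids in lut.items() for i in ids]
    pd.DataFrame(rows, columns=["label_id", "region_name"]).to_csv(path, index=False)


def roi_mask(atlas: LabelVolume, region_names: list[str] | tuple[str, ...]) -> BinaryMask:
    """Union mask of the voxels belonging to the named (bilateral) regions."""
    if not region_names:
        raise ValueError("region_names must not be empty")
    unknown = [n for n in region_names if n not in atlas.lut]
    if unknown:
        raise ValueError(
            f"unknown region name(s) {unknown}; valid names: {sorted(atlas.lut)}"
        )
    ids: list[int] = []
    for name in region_names:
        ids.extend(atlas.lut[name])
    mask = np.isin(atlas.labels, np.array(sorted(set(ids)), dtype=atlas.labels.dtype))
    return BinaryMask(mask, atlas.spacing, atlas.affine)
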