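"""The overlap index (OI): voxelwise consistency of serial tau PET scans.

Early neurofibrillary-tangle signal is small and easily confused with
interscan noise.  The OI rests on the observation that random noise and
transient artifacts rarely recur in the same voxels across serial scans,
while true tracer binding does.  Each scan is thresholded inside an ROI,
binarized, cleaned of small clusters, and the surviving baseline voxels are
checked for persistence at follow-up:

    OI = N_overlap / N_b

where ``N_b`` is the number of supra-threshold, cluster-filtered baseline
voxels and ``N_overlap`` the number of those that remain supra-threshold
(and cluster-filtered) at follow-up.  The index is asymmetric by design —
it is normalized to the baseline mask only, so a growing lesion still
scores 1 — which distinguishes it from the symmetric Dice and Jaccard
coefficients computed alongside for comparison.  An overlap size,
``N_overlap / N_ROI``, expresses the same overlap relative to the full ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes_io import BinaryMask, Volume3D, require_same_grid

#: default SUVR intensity threshold applied inside the ROI
DEFAULT_INTENSITY_THRESHOLD = 1.4
#: clusters with fewer voxels than this are discarded
DEFAULT_MIN_CLUSTER_VOXELS = 20
#: default 3D neighborhood: 6 face + 12 edge neighbors; corners excluded
DEFAULT_CONNECTIVITY = 18

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class OiParams:
    """Tunable parameters of the OI pipeline.

    intensity_threshold
        SUVR above which a voxel counts as elevated (strictly greater).
    min_cluster_voxels
        Minimum cluster extent; clusters with *fewer* voxels are excluded,
        so a cluster of exactly ``min_cluster_voxels`` survives.
    connectivity
        3D neighborhood definition: 6 (faces), 18 (faces+edges) or
        26 (faces+edges+corners).
    strict_threshold
        If False, voxels equal to the threshold also survive.
    count_before_filter
        If True, N_b/N_f are counted before cluster filtering (the overlap
        itself is always computed on filtered masks).
    """

    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS
    connectivity: int = DEFAULT_CONNECTIVITY
    strict_threshold: bool = True
    count_before_filter: bool = False

    def __post_init__(self) -> None:
        if self.intensity_threshold <= 0:
            raise ValueError("intensity_threshold must be > 0")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")


@dataclass
class ClusterLabeling:
    """Connected components of a binary mask under a given connectivity."""

    labels: np.ndarray          # int grid, 0 = background, clusters 1..K
    sizes: np.ndarray           # voxel count of cluster k at index k-1
    connectivity: int
    spacing: tuple[float, float, float]
    affine: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


@dataclass
class OverlapResult:
    """Per-scan-pair overlap metrics.

    ``oi`` is None when the baseline mask is empty (nothing to persist);
    ``undefined_reason`` then distinguishes ``empty_baseline`` (follow-up
    non-empty) from ``empty_both``.
    """

    n_b: int
    n_f: int
    n_overlap: int
    n_roi: int
    oi: float | None
    overlap_size: float
    dice: float | None
    jaccard: float | None
    undefined_reason: str | None = None

    def as_dict(self) -> dict:
        return {
            "n_b": self.n_b, "n_f": self.n_f, "n_overlap": self.n_overlap,
            "n_roi": self.n_roi, "oi": self.oi, "overlap_size": self.overlap_size,
            "dice": self.dice, "jaccard": self.jaccard,
            "undefined_reason": self.undefined_reason,
        }


def binarize(suvr: Volume3D, roi: BinaryMask, threshold: float = DEFAULT_INTENSITY_THRESHOLD,
             strict: bool = True) -> BinaryMask:
    """Mask of ROI voxels whose (finite) SUVR exceeds the threshold."""
    require_same_grid(suvr, roi)
    vals = suvr.data
    with np.errstate(invalid="ignore"):
        above = vals > threshold if strict else vals >= threshold
    mask = roi.data & np.isfinite(vals) & above
    return BinaryMask(mask, suvr.spacing, suvr.affine)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 structuring element for 6-, 18- or 26-connectivity."""
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    return ndimage.generate_binary_structure(3, rank)


def label_components(mask: BinaryMask, connectivity: int = DEFAULT_CONNECTIVITY) -> ClusterLabeling:
    """Label maximal connected clusters of a binary mask.

    Under 18-connectivity two voxels are neighbors iff they differ by at
    most 1 along each axis and are not corner-only contacts (all three
    axes differing).
    """
    labels, n = ndimage.label(mask.data, structure=connectivity_structure(connectivity))
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return ClusterLabeling(labels, sizes, connectivity, mask.spacing, mask.affine)


def filter_small_clusters(labeling: ClusterLabeling,
                          min_size: int = DEFAULT_MIN_CLUSTER_VOXELS) -> BinaryMask:
    """Drop clusters with fewer than ``min_size`` voxels (size == min_size survives)."""
    keep = np.zeros(labeling.n_clusters + 1, dtype=bool)
    keep[1:] = labeling.sizes >= min_size
    return BinaryMask(keep[labeling.labels], labeling.spacing, labeling.affine)


def _clean_mask(suvr: Volume3D, roi: BinaryMask, params: OiParams) -> tuple[BinaryMask, int]:
    """Threshold + binarize + cluster-filter one scan; also return the raw count."""
    raw = binarize(suvr, roi, params.intensity_threshold, strict=params.strict_threshold)
    labeling = label_components(raw, params.connectivity)
    return filter_small_clusters(labeling, params.min_cluster_voxels), raw.n_set


def compute_overlap(mask_b: BinaryMask, mask_f: BinaryMask, roi: BinaryMask,
                    n_b: int | None = None, n_f: int | None = None) -> OverlapResult:
    """Overlap metrics from two already thresholded/cluster-filtered masks.

    The overlap count is the voxel count of the product (logical AND) of the
    two masks.  ``n_b``/``n_f`` default to the mask counts; they can be
    overridden to support counting conventions that differ from the masks
    actually intersected.
    """
    require_same_grid(mask_b, mask_f, roi)
    if roi.n_set == 0:
        raise ValueError("ROI mask is empty")
    n_b = mask_b.n_set if n_b is None else int(n_b)
    n_f = mask_f.n_set if n_f is None else int(n_f)
    n_overlap = int((mask_b.data & mask_f.data).sum())
    n_union = int((mask_b.data | mask_f.data).sum())
    n_roi = roi.n_set

    if n_b > 0:
        oi, reason = n_overlap / n_b, None
    else:
        oi = None
        reason = "empty_both" if n_f == 0 else "empty_baseline"
    dice = 2.0 * n_overlap / (n_b + n_f) if (n_b + n_f) > 0 else None
    jaccard = n_overlap / n_union if n_union > 0 else None
    return OverlapResult(
        n_b=n_b, n_f=n_f, n_overlap=n_overlap, n_roi=n_roi,
        oi=oi, overlap_size=n_overlap / n_roi, dice=dice, jaccard=jaccard,
        undefined_reason=reason,
    )


def compute_oi_pair(suvr_b: Volume3D, suvr_f: Volume3D, roi: BinaryMask,
                    params: OiParams | None = None) -> OverlapResult:
    """Full OI pipeline for one serial scan pair.

    Order: threshold -> binarize -> label -> size-filter for each scan, then
    multiply the two cleaned masks and normalize.  By default N_b counts
    cluster-filtered voxels, so discarded noise cannot deflate the index.
    """
    params = params or OiParams()
    require_same_grid(suvr_b, suvr_f, roi)
    clean_b, raw_b = _clean_mask(suvr_b, roi, params)
    clean_f, raw_f = _clean_mask(suvr_f, roi, params)
    if params.count_before_filter:
        return compute_overlap(clean_b, clean_f, roi, n_b=raw_b, n_f=raw_f)
    return compute_overlap(clean_b, clean_f, roi)
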