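"""SUVR volumes and scalar SUVR summaries.

Standardized uptake value ratio (SUVR) normalizes tracer uptake to the
median uptake of a reference region (cerebellar crus).  Regional values are
medians over ROI voxels with cerebrospinal-fluid voxels excluded; the tau
meta-ROI composite is the unweighted mean of six temporal-lobe regional
medians, while the global amyloid composite is a voxel-number-weighted
average over seven cortical regions.  Abnormality cutoffs (tau 1.29,
amyloid 1.42) are strict "more than" thresholds, and longitudinal change
is the annualized difference of two meta-ROI SUVRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .volumes_io import BinaryMask, Volume3D, require_same_grid

log = logging.getLogger(__name__)

TAU_CUTOFF = 1.29
AMYLOID_CUTOFF = 1.42
DAYS_PER_YEAR = 365.25

#: temporal meta-ROI summarizing early tau deposition (bilateral regions)
DEFAULT_META_REGIONS = (
    "amygdala",
    "entorhinal",
    "fusiform",
    "parahippocampal",
    "inferior_temporal",
    "middle_temporal",
)

#: cortical regions entering the voxel-number-weighted amyloid composite
DEFAULT_AMYLOID_REGIONS = (
    "prefrontal",
    "orbitofrontal",
    "parietal",
    "temporal",
    "anterior_cingulate",
    "posterior_cingulate",
    "precuneus",
)


@dataclass
class MetaRoiSpec:
    """Ordered, unique region names entering the tau meta-ROI average."""

    region_names: tuple[str, ...] = DEFAULT_META_REGIONS

    def __post_init__(self) -> None:
        self.region_names = tuple(self.region_names)
        if not self.region_names:
            raise ValueError("meta-ROI must contain at least one region")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("meta-ROI region names must be unique")


@dataclass
class SuvrSummary:
    """Per-scan scalar SUVR summaries."""

    per_region_median: dict[str, float]
    n_voxels_used: dict[str, int]
    meta_suvr: float
    abnormal_tau: bool
    abnormal_amyloid: bool | None = None


@dataclass
class DeltaSuvr:
    """Annualized SUVR change between two scans (SUVR per year)."""

    value: float
    interval_years: float
    baseline: float
    followup: float


def normalize_suvr(raw: Volume3D, reference: BinaryMask) -> Volume3D:
    """Divide a raw-uptake volume by the median uptake in the reference mask.

    Non-finite reference voxels are excluded from the median.  The result
    carries ``units='suvr'``; scaling the raw volume by any k > 0 leaves it
    unchanged.
    """
    require_same_grid(raw, reference)
    ref_vals = raw.data[reference.data]
    ref_vals = ref_vals[np.isfinite(ref_vals)]
    if ref_vals.size == 0:
        raise ValueError("reference mask contains no finite voxels")
    ref_median = float(np.median(ref_vals))
    if ref_median <= 0:
        raise ValueError(f"reference median must be positive, got {ref_median}")
    return Volume3D(raw.data / ref_median, raw.spacing, raw.affine, units="suvr")


def regional_median_suvr(suvr: Volume3D, region: BinaryMask,
                         csf: BinaryMask | None = None,
                         name: str = "region") -> tuple[float, int]:
    """Median SUVR over the region's finite voxels, CSF voxels excluded.

    Returns ``(median, n_voxels_used)``.  For an even voxel count the
    median is the mean of the two middle order statistics.
    """
    require_same_grid(suvr, region)
    sel = region.data.copy()
    if csf is not None:
        require_same_grid(suvr, csf)
        sel &= ~csf.data
    else:
        log.debug("no CSF mask supplied for %s; using all region voxels", name)
    vals = suvr.data[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"region {name!r} has no usable voxels after CSF/finite exclusion")
    return float(np.median(vals)), int(vals.size)


def meta_roi_suvr(per_region_median: dict[str, float],
                  spec: MetaRoiSpec | None = None) -> float:
    """Unweighted mean of the per-region median SUVRs over the meta-ROI."""
    spec = spec or MetaRoiSpec()
    missing = [r for r in spec.region_names if r not in per_region_median]
    if missing:
        raise ValueError(f"missing meta-ROI regions: {missing}")
    return float(np.mean([per_region_median[r] for r in spec.region_names]))


def global_amyloid_suvr(per_region_median: dict[str, float],
                        per_region_voxels: dict[str, int],
                        regions: tuple[str, ...] = DEFAULT_AMYLOID_REGIONS) -> float:
    """Voxel-number-weighted average of regional median SUVRs."""
    missing = [r for r in regions if r not in per_region_median or r not in per_region_voxels]
    if missing:
        raise ValueError(f"missing regions in medians/voxel counts: {missing}")
    n = np.array([per_region_voxels[r] for r in regions], dtype=float)
    if np.any(n <= 0):
        bad = [r for r in regions if per_region_voxels[r] <= 0]
        raise ValueError(f"non-positive voxel counts for regions: {bad}")
    m = np.array([per_region_median[r] for r in regions], dtype=float)
    return float(np.sum(m * n) / np.sum(n))


def classify_abnormal(value: float, modality: str,
                      tau_cutoff: float = TAU_CUTOFF,
                      amyloid_cutoff: float = AMYLOID_CUTOFF) -> bool:
    """Abnormality call: strictly more than 1.29 (tau) or 1.42 (amyloid)."""
    if not np.isfinite(value):
        raise ValueError(f"SUVR value must be finite, got {value}")
    if modality == "tau":
        return bool(value > tau_cutoff)
    if modality == "amyloid":
        return bool(value > amyloid_cutoff)
    raise ValueError(f"modality must be 'tau' or 'amyloid', got {modality!r}")


def annualized_delta(baseline: float, followup: float, interval_days: float) -> DeltaSuvr:
    """Annualized SUVR change: (follow-up - baseline) / (interval in years)."""
    if interval_days <= 0:
        raise ValueError(f"scan interval must be positive, got {interval_days} days")
    years = interval_days / DAYS_PER_YEAR
    return DeltaSuvr(value=(followup - baseline) / years, interval_years=years,
                     baseline=baseline, followup=followup)


def summarize_scan(suvr: Volume3D, atlas, csf: BinaryMask | None = None,
                   spec: MetaRoiSpec | None = None,
                   amyloid_value: float | None = None) -> SuvrSummary:
    """Regional medians, meta-ROI SUVR and abnormality flags for one scan."""
    from .volumes_io import roi_mask  # local import keeps module deps acyclic

    spec = spec or MetaRoiSpec()
    medians: dict[str, float] = {}
    counts: dict[str, int] = {}
    for region in spec.region_names:
        mask = roi_mask(atlas, [region])
        medians[region], counts[region] = regional_median_suvr(suvr, mask, csf, name=region)
    meta = meta_roi_suvr(medians, spec)
    abnormal_amy = None if amyloid_value is None else classify_abnormal(amyloid_value, "amyloid")
    return SuvrSummary(per_region_median=medians, n_voxels_used=counts,
                       meta_suvr=meta, abnormal_tau=classify_abnormal(meta, "tau"),
                       abnormal_amyloid=abnormal_amy)
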