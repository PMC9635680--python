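"""Synthetic serial tau PET phantoms.

The generator embodies the central assumption behind the overlap index:
persistent NFT-like lesions recur in the same voxels across serial scans,
while voxel noise and transient artifacts do not.  Each simulated scan is

    background + persistent lesions(t) + transient artifacts + N(0, noise_sd)

on a block-layout atlas with a cerebellar-crus stand-in reference region
(background + noise only) and CSF voxels fixed at low uptake.  Lesions are
ellipsoids that may grow in radius and amplitude over time (accumulators);
artifacts are fresh supra-threshold ellipsoids placed at random in each
scan with sizes near the cluster-filter boundary, so they stress exactly
the mechanism the OI relies on.

Every random draw descends deterministically from one seed, with per-scan
and per-subject substreams, so cohorts are reproducible piecewise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .suvr_metrics import DEFAULT_META_REGIONS, DAYS_PER_YEAR
from .volumes_io import (BinaryMask, LabelVolume, Volume3D, roi_mask,
                         write_lut, write_volume)

DEFAULT_SPACING = (2.0, 2.0, 2.0)  # mm; free metadata, metrics are voxel-based

#: simulated subject groups
GROUPS = ("noise_only", "stable_lesion", "accumulator")

# cohort lesion defaults: one ellipsoid covering most of a single meta-ROI
# region, so the CSF-excluded regional *median* (hence meta-SUVR) tracks
# lesion amplitude; a lesion smaller than half the region cannot move it
DEFAULT_LESION_REGION = "entorhinal"
DEFAULT_LESION_RADII = (6.5, 6.5, 5.0)
DEFAULT_LESION_AMPLITUDE = 0.55          # SUVR above background at baseline
LESION_AMPLITUDE_JITTER = 0.12           # per-subject uniform +/- jitter
DEFAULT_AMPLITUDE_RATE = 0.05            # SUVR/y for accumulators
DEFAULT_GROWTH_RATE = 0.3                # voxels/y radius growth

#: synthetic clinical labels attached per group so the cohort layer can be
#: exercised end to end (a demonstration convention, not a diagnosis model)
GROUP_CLINICAL_LABELS = {
    "noise_only": ("CU", False),
    "stable_lesion": ("CU", True),
    "accumulator": ("MCI", True),
}


@dataclass
class LesionSpec:
    """One ellipsoidal lesion and its longitudinal behaviour.

    ``growth_rate`` (voxels/y) is added to every radius and
    ``amplitude_rate`` (SUVR/y) to the amplitude at scan time t.
    Non-persistent lesions appear in exactly one scan (``appears_at``).
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    amplitude: float
    growth_rate: float = 0.0
    amplitude_rate: float = 0.0
    persistent: bool = True
    appears_at: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("lesion radii must be strictly positive")
        if self.amplitude < 0:
            raise ValueError("lesion amplitude must be >= 0")

    def support(self, grid_shape: tuple[int, int, int], t: float) -> np.ndarray:
        radii_t = tuple(r + self.growth_rate * t for r in self.radii)
        return ellipsoid_mask(grid_shape, self.center, radii_t)

    def amplitude_at(self, t: float) -> float:
        return self.amplitude + self.amplitude_rate * t


@dataclass
class SubjectSimParams:
    """All knobs for one simulated subject's serial scans.

    Same seed implies bit-identical output.  ``atlas``/``csf`` default to
    the package's block-layout atlas on ``grid_shape``.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 10)
    background_mean: float = 1.0
    noise_sd: float = 0.1
    lesions: tuple[LesionSpec, ...] = ()
    artifact_rate: float = 2.0           # expected transient clusters/scan
    artifact_amplitude: float = 0.6      # SUVR above background
    artifact_radius_range: tuple[float, float] = (1.6, 2.2)
    csf_value: float = 0.3
    scan_times: tuple[float, ...] = (0.0, 1.5)   # years
    seed: int = 0
    atlas: LabelVolume | None = None
    csf: BinaryMask | None = None
    reference_region: str = "cerebellar_crus"
    noise_smooth_sigma: float = 0.0      # voxels; >0 = spatially correlated noise

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        times = tuple(self.scan_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("scan_times must be strictly increasing")
        self.scan_times = times
        self.lesions = tuple(self.lesions)
        if self.atlas is None:
            self.atlas, default_csf = default_atlas(self.grid_shape)
            if self.csf is None:
                self.csf = default_csf
        self.grid_shape = self.atlas.shape


@dataclass
class PhantomTruthSlice:
    """Ground truth for one simulated scan (noise- and artifact-free)."""

    scan_index: int
    time_years: float
    lesion_mask: BinaryMask
    true_meta_suvr: float
    n_artifacts: int


@dataclass
class PhantomTruth:
    """Ground truth for one subject's full scan series."""

    accumulating: bool
    slices: list[PhantomTruthSlice] = field(default_factory=list)


def ellipsoid_mask(grid_shape, center, radii) -> np.ndarray:
    """Boolean mask of voxels inside an axis-aligned ellipsoid."""
    grids = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


# ---------------------------------------------------------------------------
# Atlas construction


@dataclass
class BlockRegion:
    """A rectangular atlas region; bilateral regions get two label ids
    (left/right halves split along the first axis)."""

    name: str
    origin: tuple[int, int, int]
    size: tuple[int, int, int]
    bilateral: bool = True


def make_atlas(grid_shape: tuple[int, int, int], regions: list[BlockRegion],
               csf_thickness: int = 1,
               reference_region: str = "cerebellar_crus",
               spacing=DEFAULT_SPACING) -> tuple[LabelVolume, BinaryMask]:
    """Build a block-layout label volume plus a CSF mask.

    Regions must fit in the grid and be pairwise disjoint.  The CSF mask
    marks the lowest ``csf_thickness`` z-slice(s) of every non-reference
    region: voxels that carry a region label but are segmented as CSF, so
    CSF exclusion in regional medians is meaningful.
    """
    labels = np.zeros(grid_shape, dtype=np.int32)
    csf = np.zeros(grid_shape, dtype=bool)
    lut: dict[str, tuple[int, ...]] = {}
    next_id = 1
    for reg in regions:
        o, s = reg.origin, reg.size
        if any(oi < 0 or oi + si > g for oi, si, g in zip(o, s, grid_shape)):
            raise ValueError(f"region {reg.name!r} does not fit in grid {grid_shape}")
        if reg.name in lut:
            raise ValueError(f"duplicate region name {reg.name!r}")
        block = (slice(o[0], o[0] + s[0]), slice(o[1], o[1] + s[1]),
                 slice(o[2], o[2] + s[2]))
        if np.any(labels[block] != 0):
            raise ValueError(f"region {reg.name!r} overlaps a previous region")
        if reg.bilateral:
            half = s[0] // 2
            labels[o[0]:o[0] + half, block[1], block[2]] = next_id
            labels[o[0] + half:o[0] + s[0], block[1], block[2]] = next_id + 1
            lut[reg.name] = (next_id, next_id + 1)
            next_id += 2
        else:
            labels[block] = next_id
            lut[reg.name] = (next_id,)
            next_id += 1
        if reg.name != reference_region and csf_thickness > 0:
            csf[block[0], block[1], o[2]:o[2] + csf_thickness] = True
    affine = np.diag(list(spacing) + [1.0])
    return (LabelVolume(labels, lut, spacing, affine),
            BinaryMask(csf, spacing, affine))


def default_atlas(grid_shape=(48, 48, 10)) -> tuple[LabelVolume, BinaryMask]:
    """14-region block atlas: 6 tau meta-ROI regions, 7 amyloid-composite
    regions, and a cerebellar-crus reference block."""
    names = list(DEFAULT_META_REGIONS) + [
        "prefrontal", "orbitofrontal", "parietal", "temporal",
        "anterior_cingulate", "posterior_cingulate", "precuneus",
        "cerebellar_crus",
    ]
    if grid_shape[0] < 47 or grid_shape[1] < 47 or grid_shape[2] < 9:
        raise ValueError(f"grid {grid_shape} too small for the default 4x4 block layout")
    origins = [(x, y, 1) for y in (1, 13, 25, 37) for x in (1, 13, 25, 37)]
    regions = [BlockRegion(name, origin, (10, 10, 8))
               for name, origin in zip(names, origins)]
    return make_atlas(grid_shape, regions)


def region_centroid(atlas: LabelVolume, name: str) -> tuple[float, float, float]:
    mask = roi_mask(atlas, [name])
    return tuple(float(c) for c in np.array(np.nonzero(mask.data)).mean(axis=1))


# ---------------------------------------------------------------------------
# Scan simulation


def _subject_rng_seed(master_seed: int, subject_index: int) -> int:
    """Deterministic, well-mixed per-subject seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(subject_index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _noiseless_field(params: SubjectSimParams, t: float, scan_index: int,
                     ref: np.ndarray, csf: np.ndarray) -> np.ndarray:
    field_ = np.full(params.grid_shape, params.background_mean, dtype=float)
    for lesion in params.lesions:
        if not lesion.persistent and lesion.appears_at != scan_index:
            continue
        sup = lesion.support(params.grid_shape, t) & ~ref
        field_[sup] += lesion.amplitude_at(t)
    field_[csf] = params.csf_value
    return field_


def _true_meta_suvr(field_: np.ndarray, atlas: LabelVolume, csf: np.ndarray) -> float:
    medians = []
    for name in DEFAULT_META_REGIONS:
        if name not in atlas.lut:
            return float("nan")
        sel = np.isin(atlas.labels, atlas.lut[name]) & ~csf
        medians.append(np.median(field_[sel]))
    return float(np.mean(medians))


def simulate_scan(params: SubjectSimParams, t: float,
                  scan_index: int) -> tuple[Volume3D, PhantomTruthSlice]:
    """Simulate one scan at time ``t`` (years); deterministic in (seed, scan_index)."""
    if t not in params.scan_times:
        raise ValueError(f"t={t} is not one of scan_times {params.scan_times}")
    rng = np.random.default_rng([int(params.seed), int(scan_index)])
    atlas, csf_mask = params.atlas, params.csf
    csf = csf_mask.data if csf_mask is not None else np.zeros(params.grid_shape, bool)
    if params.reference_region in atlas.lut:
        ref = roi_mask(atlas, [params.reference_region]).data
    else:
        ref = np.zeros(params.grid_shape, bool)

    field_ = _noiseless_field(params, t, scan_index, ref, csf)
    true_meta = _true_meta_suvr(field_, atlas, csf)
    lesion_mask = np.zeros(params.grid_shape, bool)
    for lesion in params.lesions:
        if lesion.persistent or lesion.appears_at == scan_index:
            lesion_mask |= lesion.support(params.grid_shape, t) & ~ref & ~csf

    # transient artifacts: fresh placement each scan, supra-threshold
    # amplitude, sizes straddling the cluster-filter boundary
    n_artifacts = int(rng.poisson(params.artifact_rate))
    candidates = np.array(np.nonzero((atlas.labels > 0) & ~ref & ~csf)).T
    for _ in range(n_artifacts):
        center = candidates[rng.integers(len(candidates))]
        radii = rng.uniform(*params.artifact_radius_range, size=3)
        sup = ellipsoid_mask(params.grid_shape, center, radii) & ~ref & ~csf
        field_[sup] += params.artifact_amplitude

    if params.noise_sd > 0:
        white = rng.standard_normal(params.grid_shape)
        if params.noise_smooth_sigma > 0:
            white = ndimage.gaussian_filter(white, params.noise_smooth_sigma)
            white /= white.std()
        field_ = field_ + params.noise_sd * white

    vol = Volume3D(field_, atlas.spacing, atlas.affine, units="suvr")
    truth = PhantomTruthSlice(scan_index=scan_index, time_years=float(t),
                              lesion_mask=BinaryMask(lesion_mask, atlas.spacing, atlas.affine),
                              true_meta_suvr=true_meta, n_artifacts=n_artifacts)
    return vol, truth


def simulate_subject(params: SubjectSimParams) -> tuple[list[Volume3D], PhantomTruth]:
    """Simulate all scans of one subject."""
    accumulating = any(l.persistent and (l.growth_rate > 0 or l.amplitude_rate > 0)
                       for l in params.lesions)
    truth = PhantomTruth(accumulating=accumulating)
    vols = []
    for k, t in enumerate(params.scan_times):
        vol, sl = simulate_scan(params, t, k)
        vols.append(vol)
        truth.slices.append(sl)
    return vols, truth


# ---------------------------------------------------------------------------
# Cohorts


def _group_counts(n_subjects: int, group_mix) -> list[int]:
    p = np.asarray(group_mix, dtype=float)
    if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("group_mix must be 3 non-negative proportions summing to 1")
    counts = np.floor(p * n_subjects).astype(int)
    # largest-remainder rounding, ties broken by group order
    for _ in range(n_subjects - counts.sum()):
        rem = p * n_subjects - counts
        counts[int(np.argmax(rem))] += 1
    return counts.tolist()


def subject_params_for_group(group: str, subject_seed: int,
                             base: SubjectSimParams | None = None) -> SubjectSimParams:
    """Build one subject's simulation parameters for a cohort group.

    Lesion subjects receive an ellipsoid covering most of one meta-ROI
    region with per-subject amplitude jitter; accumulators additionally
    grow in amplitude and radius over time.
    """
    base = base or SubjectSimParams()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if group == "noise_only":
        return replace(base, seed=subject_seed, lesions=())
    rng = np.random.default_rng([subject_seed, 915])  # lesion-parameter substream
    amplitude = DEFAULT_LESION_AMPLITUDE + rng.uniform(-LESION_AMPLITUDE_JITTER,
                                                       LESION_AMPLITUDE_JITTER)
    center = region_centroid(base.atlas, DEFAULT_LESION_REGION)
    lesion = LesionSpec(
        center=center, radii=DEFAULT_LESION_RADII, amplitude=float(amplitude),
        growth_rate=DEFAULT_GROWTH_RATE if group == "accumulator" else 0.0,
        amplitude_rate=DEFAULT_AMPLITUDE_RATE if group == "accumulator" else 0.0,
    )
    return replace(base, seed=subject_seed, lesions=(lesion,))


def cohort_subject_specs(n_subjects: int, group_mix, seed: int,
                         base: SubjectSimParams | None = None):
    """Yield ``(subject_id, group, SubjectSimParams)`` deterministically."""
    base = base or SubjectSimParams()
    counts = _group_counts(n_subjects, group_mix)
    groups = [g for g, c in zip(GROUPS, counts) for _ in range(c)]
    for i, group in enumerate(groups):
        subject_seed = _subject_rng_seed(seed, i)
        yield f"sub-{i:04d}", group, subject_params_for_group(group, subject_seed, base)


def simulate_cohort(n_subjects: int, group_mix, out_dir, seed: int = 0,
                    base: SubjectSimParams | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and write NIfTI volumes, manifest and truth CSVs.

    Returns ``(manifest, truth)`` DataFrames.  The manifest is ready for
    batch OI computation (subject_id, scan_index, date_offset_days, path)
    and carries the per-group synthetic clinical labels.
    """
    base = base or SubjectSimParams()
    os.makedirs(out_dir, exist_ok=True)
    write_volume(base.atlas, os.path.join(out_dir, "atlas.nii.gz"))
    write_lut(base.atlas.lut, os.path.join(out_dir, "lut.csv"))
    if base.csf is not None:
        write_volume(base.csf, os.path.join(out_dir, "csf.nii.gz"))

    manifest_rows, truth_rows = [], []
    for subject_id, group, params in cohort_subject_specs(n_subjects, group_mix, seed, base):
        vols, truth = simulate_subject(params)
        dx, amy = GROUP_CLINICAL_LABELS[group]
        lesion = params.lesions[0] if params.lesions else None
        for k, (vol, sl) in enumerate(zip(vols, truth.slices)):
            path = os.path.join(out_dir, f"{subject_id}_scan-{k}.nii.gz")
            write_volume(vol, path)
            manifest_rows.append({
                "subject_id": subject_id, "scan_index": k,
                "date_offset_days": round(sl.time_years * DAYS_PER_YEAR, 2),
                "path": path, "group": group, "diagnosis": dx,
                "amyloid_abnormal": amy,
            })
            truth_rows.append({
                "subject_id": subject_id, "group": group,
                "accumulating": truth.accumulating,
                "lesion_amplitude": lesion.amplitude if lesion else 0.0,
                "growth_rate": lesion.growth_rate if lesion else 0.0,
                "amplitude_rate": lesion.amplitude_rate if lesion else 0.0,
                "scan_index": k, "true_meta_suvr": sl.true_meta_suvr,
                "n_artifacts": sl.n_artifacts,
            })
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    return manifest, truth
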