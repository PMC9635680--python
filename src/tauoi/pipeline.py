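"""Convenience drivers tying the modules together for pair and batch runs."""

from __future__ import annotations

import logging

import pandas as pd

from .cohort_analysis import ScanVisit, SubjectRecord, build_pairs
from .overlap_index import OiParams, compute_oi_pair
from .suvr_metrics import MetaRoiSpec, annualized_delta, summarize_scan
from .volumes_io import BinaryMask, LabelVolume, Volume3D, read_volume, roi_mask

log = logging.getLogger(__name__)


def pair_metrics(vol_b: Volume3D, vol_f: Volume3D, atlas: LabelVolume,
                 regions: list[str] | tuple[str, ...],
                 csf: BinaryMask | None = None,
                 params: OiParams | None = None,
                 interval_days: float | None = None) -> dict:
    """OI + SUVR summary for one co-registered serial scan pair.

    ``regions`` selects the ROI (the union of the named bilateral regions).
    Returns a flat dict ready for JSON/CSV serialization.
    """
    params = params or OiParams()
    roi = roi_mask(atlas, list(regions))
    res = compute_oi_pair(vol_b, vol_f, roi, params)
    spec = MetaRoiSpec(tuple(regions))
    sum_b = summarize_scan(vol_b, atlas, csf, spec)
    sum_f = summarize_scan(vol_f, atlas, csf, spec)
    out = res.as_dict()
    out.update({
        "suvr_b": sum_b.meta_suvr, "suvr_f": sum_f.meta_suvr,
        "abnormal_tau_b": sum_b.abnormal_tau, "abnormal_tau_f": sum_f.abnormal_tau,
        "intensity_threshold": params.intensity_threshold,
        "min_cluster_voxels": params.min_cluster_voxels,
        "connectivity": params.connectivity,
        "regions": ",".join(regions),
    })
    if interval_days is not None:
        delta = annualized_delta(sum_b.meta_suvr, sum_f.meta_suvr, interval_days)
        out["interval_years"] = delta.interval_years
        out["delta_suvr_per_year"] = delta.value
    return out


def batch_pairs(manifest: pd.DataFrame, atlas: LabelVolume,
                regions: list[str] | tuple[str, ...],
                csf: BinaryMask | None = None,
                params: OiParams | None = None) -> pd.DataFrame:
    """Consecutive-pair OI/SUVR metrics for every subject in a manifest.

    The manifest needs columns subject_id, scan_index, date_offset_days,
    path; scans are paired consecutively per subject in scan order.
    """
    required = {"subject_id", "scan_index", "date_offset_days", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    rows = []
    for subject_id, grp in manifest.groupby("subject_id", sort=True):
        grp = grp.sort_values("scan_index")
        if len(grp) < 2:
            log.warning("subject %s has %d scan(s); skipped", subject_id, len(grp))
            continue
        scans = grp.to_dict("records")
        vols = [read_volume(s["path"], units="suvr") for s in scans]
        for i in range(len(scans) - 1):
            b, f = scans[i], scans[i + 1]
            interval = float(f["date_offset_days"]) - float(b["date_offset_days"])
            row = pair_metrics(vols[i], vols[i + 1], atlas, regions, csf,
                               params, interval_days=interval)
            row.update({"subject_id": subject_id, "pair_index": i,
                        "scan_index_b": b["scan_index"], "scan_index_f": f["scan_index"]})
            rows.append(row)
    return pd.DataFrame(rows)


def records_from_tables(manifest: pd.DataFrame,
                        pairs: pd.DataFrame) -> list[SubjectRecord]:
    """Assemble SubjectRecords from a scan manifest and a batch-pairs table.

    The manifest supplies dates, diagnoses and amyloid status per scan; the
    pairs table supplies per-pair OI and per-scan meta-SUVR.
    """
    records = []
    for subject_id, grp in manifest.groupby("subject_id", sort=True):
        grp = grp.sort_values("scan_index")
        sub_pairs = pairs[pairs["subject_id"] == subject_id].sort_values("pair_index")
        if len(grp) < 2 or sub_pairs.empty:
            continue
        suvr_by_scan = {}
        for _, pr in sub_pairs.iterrows():
            suvr_by_scan[pr["scan_index_b"]] = pr["suvr_b"]
            suvr_by_scan[pr["scan_index_f"]] = pr["suvr_f"]
        scans = [ScanVisit(date=float(s["date_offset_days"]),
                           meta_suvr=float(suvr_by_scan[s["scan_index"]]),
                           diagnosis=str(s["diagnosis"]),
                           amyloid_abnormal=None if pd.isna(s.get("amyloid_abnormal"))
                           else bool(s["amyloid_abnormal"]))
                 for s in grp.to_dict("records")]
        oi_values = [None if pd.isna(v) else float(v) for v in sub_pairs["oi"]]
        records.append(build_pairs(SubjectRecord(str(subject_id), scans), oi_values))
    return records
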