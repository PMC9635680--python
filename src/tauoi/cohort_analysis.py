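"""Longitudinal cohort layer: scan pairing, subgrouping and group statistics.

Serial scans are paired consecutively; each pair carries its overlap index,
annualized meta-ROI SUVR change, scan interval, and a clinical-progression
category built from diagnosis and amyloid status at the two time points.
Group comparisons use the rank-based Kruskal-Wallis omnibus test followed
by Dunn's post hoc pairwise z-tests on the pooled ranking, with a
configurable multiplicity adjustment (Holm by default).
"""

from __future__ import annotations

import datetime as _dt
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .suvr_metrics import TAU_CUTOFF, annualized_delta

log = logging.getLogger(__name__)

DIAGNOSES = ("CU", "MCI", "AD")

#: clinical-progression categories for a scan pair, in canonical order
PROGRESSION_CATEGORIES = (
    "CUA- to CUA-",
    "CUA- to CUA+",
    "CUA+ to CUA+",
    "CU to MCI/AD",
    "MCI to MCI",
    "MCI to AD",
    "AD to AD",
    "other",
)

SUVR_BIN_EDGES = (TAU_CUTOFF, 1.5)   # low < 1.29 <= mid < 1.5 <= high
OI_SPLIT = 0.5


@dataclass
class ScanVisit:
    """One scan's metadata: date (datetime/date or day offset), meta-ROI
    SUVR, diagnosis and optional amyloid status."""

    date: object
    meta_suvr: float
    diagnosis: str
    amyloid_abnormal: bool | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}")


@dataclass
class PairMetrics:
    """Derived metrics for one consecutive scan pair."""

    oi: float | None
    delta_suvr: float
    interval_years: float
    progression_group: str
    baseline_meta_suvr: float


@dataclass
class SubjectRecord:
    """One participant's longitudinal scan series and derived pair metrics."""

    subject_id: str
    scans: list[ScanVisit]
    pairs: list[PairMetrics] = field(default_factory=list)


def _interval_days(a, b) -> float:
    if isinstance(a, (_dt.date, _dt.datetime)):
        return (b - a) / _dt.timedelta(days=1)
    return float(b) - float(a)


def progression_group(dx_b: str, amy_b: bool | None,
                      dx_f: str, amy_f: bool | None) -> str:
    """Map a scan pair's clinical states to its progression category.

    CU->MCI and CU->AD both map to ``CU to MCI/AD``; pairs outside the
    listed categories (reversions, CUA+ to CUA-) map to ``other``.
    Amyloid status is required only when both diagnoses are CU.
    """
    for dx in (dx_b, dx_f):
        if dx not in DIAGNOSES:
            raise ValueError(f"diagnosis must be one of {DIAGNOSES}, got {dx!r}")
    if dx_b == "CU" and dx_f == "CU":
        if amy_b is None or amy_f is None:
            raise ValueError("amyloid status required for CU-to-CU pairs")
        if not amy_b:
            return "CUA- to CUA+" if amy_f else "CUA- to CUA-"
        return "CUA+ to CUA+" if amy_f else "other"
    if dx_b == "CU":
        return "CU to MCI/AD"
    if dx_b == "MCI" and dx_f == "MCI":
        return "MCI to MCI"
    if dx_b == "MCI" and dx_f == "AD":
        return "MCI to AD"
    if dx_b == "AD" and dx_f == "AD":
        return "AD to AD"
    return "other"


def suvr_bin(meta_suvr: float) -> str:
    """Baseline meta-SUVR bin: low (<1.29), mid ([1.29, 1.5)), high (>=1.5)."""
    if not np.isfinite(meta_suvr):
        raise ValueError(f"meta_suvr must be finite, got {meta_suvr}")
    if meta_suvr < SUVR_BIN_EDGES[0]:
        return "low"
    return "mid" if meta_suvr < SUVR_BIN_EDGES[1] else "high"


def oi_bin(oi: float | None) -> str:
    """Low/high OI split at 0.5 (boundary value assigned high)."""
    if oi is None or not np.isfinite(oi):
        raise ValueError("cannot bin an undefined OI; exclude the pair instead")
    return "low" if oi < OI_SPLIT else "high"


def build_pairs(record: SubjectRecord, oi_results) -> SubjectRecord:
    """Fill a subject's consecutive-pair metrics from per-pair OI results.

    ``oi_results`` holds one item per consecutive scan pair; each may be an
    OverlapResult, a float, or None (undefined OI).  Subjects with fewer
    than two scans are skipped with a log entry.
    """
    record.pairs = []
    if len(record.scans) < 2:
        log.warning("subject %s has %d scan(s); no pairs formed",
                    record.subject_id, len(record.scans))
        return record
    if len(oi_results) != len(record.scans) - 1:
        raise ValueError(
            f"subject {record.subject_id}: expected {len(record.scans) - 1} "
            f"OI results, got {len(oi_results)}"
        )
    for (scan_b, scan_f), oi_res in zip(itertools.pairwise(record.scans), oi_results):
        days = _interval_days(scan_b.date, scan_f.date)
        if days <= 0:
            raise ValueError(
                f"subject {record.subject_id}: scan dates must be strictly increasing"
            )
        delta = annualized_delta(scan_b.meta_suvr, scan_f.meta_suvr, days)
        oi = getattr(oi_res, "oi", oi_res)
        record.pairs.append(PairMetrics(
            oi=None if oi is None else float(oi),
            delta_suvr=delta.value,
            interval_years=delta.interval_years,
            progression_group=progression_group(
                scan_b.diagnosis, scan_b.amyloid_abnormal,
                scan_f.diagnosis, scan_f.amyloid_abnormal),
            baseline_meta_suvr=scan_b.meta_suvr,
        ))
    return record


# ---------------------------------------------------------------------------
# Group statistics


@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    z_statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupComparison:
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseTest]
    reference_group: str | None = None
    adjust: str = "holm"


_ADJUST_METHODS = {"holm": "holm", "bonferroni": "bonferroni", "none": None}


def _dunn_z(pooled_ranks: np.ndarray, idx_a, idx_b, tie_term: float) -> float:
    n = len(pooled_ranks)
    var_factor = n * (n + 1) / 12.0 - tie_term
    ra, rb = pooled_ranks[idx_a].mean(), pooled_ranks[idx_b].mean()
    se = np.sqrt(var_factor * (1.0 / len(idx_a) + 1.0 / len(idx_b)))
    return float((ra - rb) / se) if se > 0 else 0.0


def compare_groups(values: dict[str, list | np.ndarray],
                   reference: str | None = None,
                   adjust: str = "holm") -> GroupComparison:
    """Kruskal-Wallis omnibus test plus Dunn post hoc pairwise z-tests.

    Dunn's z compares mean pooled ranks with the tie-corrected rank
    variance; for two tie-free groups it coincides with the normal
    rank-sum z.  ``reference`` restricts pairwise tests to reference vs
    each other group; otherwise all pairs are tested.  Adjusted p-values
    use Holm (default), Bonferroni, or no correction.
    """
    if adjust not in _ADJUST_METHODS:
        raise ValueError(f"adjust must be one of {sorted(_ADJUST_METHODS)}")
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    degenerate = [k for k, v in groups.items() if len(v) < 2]
    if len(groups) < 2 or degenerate:
        raise ValueError(
            f"need >= 2 groups with >= 2 observations each; degenerate: {degenerate}"
        )
    if reference is not None and reference not in groups:
        raise ValueError(f"reference group {reference!r} not among {sorted(groups)}")

    samples = list(groups.values())
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        h, p_omni = 0.0, 1.0      # all observations identical
    else:
        h, p_omni = stats.kruskal(*samples)

    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = len(pooled)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n - 1))

    names = list(groups)
    bounds = np.cumsum([0] + [len(groups[k]) for k in names])
    index = {k: np.arange(bounds[i], bounds[i + 1]) for i, k in enumerate(names)}
    if reference is None:
        pairs = list(itertools.combinations(names, 2))
    else:
        pairs = [(reference, k) for k in names if k != reference]

    zs = [_dunn_z(ranks, index[a], index[b], tie_term) for a, b in pairs]
    p_raw = [2.0 * stats.norm.sf(abs(z)) for z in zs]
    method = _ADJUST_METHODS[adjust]
    p_adj = list(p_raw) if method is None else list(multipletests(p_raw, method=method)[1])
    pairwise = [PairwiseTest(a, b, z, pr, pa)
                for (a, b), z, pr, pa in zip(pairs, zs, p_raw, p_adj)]
    return GroupComparison(float(h), float(p_omni), pairwise,
                           reference_group=reference, adjust=adjust)


@dataclass
class LinearAssociation:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def linear_association(x, y) -> LinearAssociation:
    """Ordinary least-squares fit of y on x with R^2 and slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is not identifiable")
    fit = stats.linregress(x, y)
    return LinearAssociation(slope=float(fit.slope), intercept=float(fit.intercept),
                             r_squared=float(fit.rvalue ** 2), p=float(fit.pvalue),
                             n=len(x))


# ---------------------------------------------------------------------------
# Tidy-table helpers


def pairs_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """One tidy row per scan pair, with SUVR and OI bins attached.

    Pairs with undefined OI keep NaN in ``oi``/``oi_bin`` and are counted
    in the log; they are excluded from OI-binned statistics rather than
    coded as 0, which would bias low-SUVR groups.
    """
    rows = []
    n_undefined = 0
    for rec in records:
        for i, p in enumerate(rec.pairs):
            defined = p.oi is not None and np.isfinite(p.oi)
            n_undefined += not defined
            rows.append({
                "subject_id": rec.subject_id, "pair_index": i,
                "oi": p.oi if defined else np.nan,
                "delta_suvr": p.delta_suvr,
                "interval_years": p.interval_years,
                "progression_group": p.progression_group,
                "baseline_meta_suvr": p.baseline_meta_suvr,
                "suvr_bin": suvr_bin(p.baseline_meta_suvr),
                "oi_bin": oi_bin(p.oi) if defined else np.nan,
            })
    if n_undefined:
        log.info("%d pair(s) with undefined OI excluded from OI-binned statistics",
                 n_undefined)
    return pd.DataFrame(rows)


def delta_by_suvr_and_oi(pairs: pd.DataFrame) -> pd.DataFrame:
    """Mean/count of annualized change by baseline-SUVR bin and OI bin."""
    ok = pairs.dropna(subset=["oi_bin"])
    out = (ok.groupby(["suvr_bin", "oi_bin"])["delta_suvr"]
             .agg(["mean", "count"]).reset_index())
    return out
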