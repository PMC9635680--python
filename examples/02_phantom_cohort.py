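"""Simulate a small serial-phantom cohort and compare groups by OI.

Three groups: noise-only subjects (artifacts + noise, no lesion), subjects
with a stable persistent lesion, and accumulators whose lesion grows in
amplitude and extent.  For each subject we compute the meta-ROI overlap
index and the annualized meta-SUVR change, then summarize per group.
"""

import dataclasses

import numpy as np

from tauoi import OiParams, annualized_delta, compute_oi_pair, roi_mask, summarize_scan
from tauoi import phantom as ph
from tauoi.suvr_metrics import DEFAULT_META_REGIONS

N_PER_GROUP = 15
SEED = 42

params = OiParams()
print(f"{'group':<15} {'n OI def.':>9} {'mean OI':>8} {'mean ΔSUVR/y':>13} {'mean SUVR_b':>12}")
for k, group in enumerate(ph.GROUPS):
    ois, deltas, metas = [], [], []
    for i in range(N_PER_GROUP):
        subj_seed = ph._subject_rng_seed(SEED + k, i)
        p = ph.subject_params_for_group(group, subj_seed)
        vols, truth = ph.simulate_subject(p)
        roi = roi_mask(p.atlas, DEFAULT_META_REGIONS)
        res = compute_oi_pair(vols[0], vols[1], roi, params)
        meta_b = summarize_scan(vols[0], p.atlas, p.csf).meta_suvr
        meta_f = summarize_scan(vols[1], p.atlas, p.csf).meta_suvr
        interval_days = (p.scan_times[1] - p.scan_times[0]) * 365.25
        deltas.append(annualized_delta(meta_b, meta_f, interval_days).value)
        metas.append(meta_b)
        if res.oi is not None:
            ois.append(res.oi)
    mean_oi = np.mean(ois) if ois else float("nan")
    print(f"{group:<15} {len(ois):>9} {mean_oi:>8.3f} {np.mean(deltas):>13.4f} "
          f"{np.mean(metas):>12.4f}")

print()
print("Noise-only OI is near 0 (noise and artifacts do not repeat in place);")
print("lesion groups score high OI. Accumulators show a positive annualized")
print("ΔSUVR while all groups stay in the low-SUVR window (< 1.29), which is")
print("exactly the regime where OI separates accumulators and SUVR cannot.")
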