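"""Approach 1: marker-wise survival scan with fused-lasso smoothing.

Tests every marker's normalized intensity against survival with a
left-truncated Cox model, smooths the per-chromosome -log10 p profile
with an exact fused-lasso signal approximator, reports regions of
interest (smoothed value > 2), and calls per-sample states inside them.
"""

import numpy as np

from cnvsurv import (PlantedRegion, SimulationConfig, associate_roi,
                     detect_roi, flsa_smooth, normalize_pipeline, refine_roi,
                     scan_markers, select_lambda_fuse, simulate_dataset)

config = SimulationConfig(
    n_samples=400, n_chrom=4, markers_per_chrom=150, seed=7,
    planted_regions=(
        PlantedRegion("2", 50, 8, -1, 0.20, np.log(2.2)),))
marker_map, manifest, panel, truth = simulate_dataset(config)
z, _ = normalize_pipeline(panel, manifest.df["plate_id"].to_numpy())
survival = manifest.survival_data(n_pcs=1)

scan = scan_markers(z.Z, marker_map, survival)
print(f"scanned {len(marker_map)} markers "
      f"({scan.skipped.sum()} skipped), min p = {np.nanmin(scan.p):.2e} at "
      f"{scan.marker_ids[np.nanargmin(scan.p)]}")

profiles = []
for chrom in marker_map.chromosomes():
    idx = np.nonzero((scan.chrom == chrom) & ~scan.skipped)[0]
    y = scan.neglog10p[idx]
    lam = select_lambda_fuse(y)
    profiles.append(flsa_smooth(y, lam, chrom=chrom, marker_idx=idx))

rois = detect_roi(profiles, marker_map, threshold=2.0)
for roi in rois:
    print(f"ROI chr{roi.chrom}:{roi.start_bp}-{roi.end_bp} "
          f"({roi.n_markers} markers, peak smooth -log10 p = "
          f"{roi.peak_smoothed:.2f} at {roi.peak_marker_id})")
    window = roi.marker_idx
    calls = refine_roi(z.Z[:, window], manifest.sample_ids)
    res = associate_roi(calls, survival, roi)
    print(f"  states: {res.n_gain} gain / {res.n_normal} normal / "
          f"{res.n_loss} loss")
    if res.testable:
        print(f"  trend HR {res.hr:.2f} ({res.ci95[0]:.2f}-{res.ci95[1]:.2f})"
              f", p = {res.p:.2e}; 2-df categorical p = {res.p_2df:.2e}")
# The planted chr2 loss should dominate the scan: its markers carry the
# smallest p-values, the smoothed profile exceeds 2 there, and the ROI's
# trend HR is protective per +1 state (carriers sit at state -1).
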