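"""End-to-end composition: simulate/load -> normalize -> segment -> test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .burden import compute_burden, test_burden
from .cbs import derive_common_regions, segment_cohort, test_all_regions
from .normalize import normalize_pipeline
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["SegmentationRun", "run_segmentation_pipeline"]


@dataclass
class SegmentationRun:
    """Everything the genome-wide segmentation arm produced."""

    marker_map: object
    manifest: object
    truth: object
    Z: np.ndarray
    calls: dict
    regions: list
    results: list
    burden_table: object = None

    def result_overlapping(self, chrom: str, start_bp: int, end_bp: int):
        """The tested region overlapping a bp interval, or None."""
        for r in self.results:
            if r.chrom == chrom and r.start_bp <= end_bp and r.end_bp >= start_bp:
                return r
        return None


def run_segmentation_pipeline(config: SimulationConfig, alpha: float = 0.01,
                              n_perm: int = 1000, min_width: int = 3,
                              lower_pct: float = 3.0, upper_pct: float = 97.0,
                              recurrence: int = 5, n_pcs: int = 1,
                              with_burden: bool = False,
                              seed=None) -> SegmentationRun:
    """Simulate a cohort and run the full CBS association arm on it.

    ``seed`` drives the segmentation permutations (defaults to
    ``config.seed + 1`` so data and analysis noise are decoupled).
    """
    marker_map, manifest, panel, truth = simulate_dataset(config)
    z, _ = normalize_pipeline(panel, manifest.df["plate_id"].to_numpy())
    if seed is None:
        seed = config.seed + 1
    calls = segment_cohort(z.Z, marker_map, manifest.sample_ids, alpha=alpha,
                           n_perm=n_perm, min_width=min_width,
                           lower_pct=lower_pct, upper_pct=upper_pct, seed=seed)
    regions = derive_common_regions(calls, marker_map, recurrence=recurrence)
    results = test_all_regions(regions, manifest.survival_data(n_pcs=n_pcs))
    burden_table = None
    if with_burden:
        _, burden_table = test_burden(compute_burden(calls),
                                      manifest.survival_data(n_pcs=n_pcs))
    return SegmentationRun(marker_map=marker_map, manifest=manifest,
                           truth=truth, Z=z.Z, calls=calls, regions=regions,
                           results=results, burden_table=burden_table)
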