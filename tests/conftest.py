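import numpy as np
import pandas as pd
import pytest

from cnvsurv.io import MarkerMap
from cnvsurv.simulate import PlantedRegion, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale synthetic cohort with one hazardous loss and one neutral gain."""
    cfg = SimulationConfig(
        n_samples=200, n_chrom=4, markers_per_chrom=60, seed=3,
        planted_regions=(
            PlantedRegion("2", 20, 8, -1, 0.2, np.log(2.0)),
            PlantedRegion("3", 10, 6, +1, 0.3, 0.0),
        ))
    marker_map, manifest, panel, truth = simulate_dataset(cfg)
    return cfg, marker_map, manifest, panel, truth


def toy_marker_map(n=10, chrom="1", start=1000, step=1000):
    return MarkerMap(pd.DataFrame({
        "marker_id": [f"m{chrom}_{j}" for j in range(n)],
        "chrom": chrom,
        "pos_bp": np.arange(n) * step + start,
        "probe_class": "snp",
    }))
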