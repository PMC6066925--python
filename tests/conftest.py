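import numpy as np
import pandas as pd
import pytest

from loopmut import (
    GenomeLayout,
    IntervalSet,
    SimulationConfig,
    simulate_bundle,
)


def random_interval_df(rng, chrom, n, length, max_width=2000):
    starts = rng.integers(0, length - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": np.minimum(starts + widths, length)}
    )


def coverage_mask(intervals: IntervalSet, chrom: str, length: int) -> np.ndarray:
    """Per-base boolean-array oracle for interval coverage."""
    mask = np.zeros(length, dtype=bool)
    starts, ends = intervals.arrays(chrom)
    for s, e in zip(starts, ends):
        mask[s:e] = True
    return mask


@pytest.fixture(scope="session")
def toy_layout():
    return GenomeLayout([("chr1", 1_000_000), ("chr2", 500_000)])


@pytest.fixture(scope="session")
def bundle():
    """A small but fully featured synthetic bundle shared across tests."""
    cfg = SimulationConfig(
        seed=7,
        chrom_lengths={"chr1": 6_000_000, "chr2": 6_000_000},
        n_union_anchors=80,
        hotspot_count=140,
        n_samples=30,
        dsb_count=600,
    )
    return simulate_bundle(cfg)
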