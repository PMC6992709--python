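import numpy as np
import pandas as pd
import pytest

from aneupipe import simdata
from aneupipe.karyocall import CoverageProfile


def small_config(**overrides) -> simdata.SimConfig:
    """A fast ~240 kb configuration for pipeline-level tests."""
    defaults = dict(
        n_chromosomes=4,
        chrom_lengths=(60_000, 60_000, 60_000, 60_000),
        n_disomes=3,
        lines_per_strain=3,
        depth=40.0,
        seed=0,
    )
    defaults.update(overrides)
    return simdata.SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_truth():
    cfg = simdata.SimConfig(seed=11)
    genome = simdata.make_genome(cfg)
    return simdata.simulate_lineages(genome, cfg)


@pytest.fixture(scope="session")
def small_truth():
    cfg = small_config(seed=5)
    genome = simdata.make_genome(cfg)
    return simdata.simulate_lineages(genome, cfg)


def flat_profile(sample: str, counts, chrom: str = "chr1", window: int = 100
                 ) -> CoverageProfile:
    counts = np.asarray(counts)
    starts = np.arange(len(counts)) * window
    win = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + window, "count": counts,
    })
    return CoverageProfile(sample=sample, windows=win)
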