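import numpy as np
import pandas as pd
import pytest

from dgsearch.segmentation import GenomicProfile
from dgsearch.simulate import (PlantedRegion, SimConfig, default_cohort_config,
                               generate_cohort)


def make_profile(values, positions=None, chrom="1", subject="S0"):
    """A single-chromosome profile from a value vector."""
    values = np.asarray(values, dtype=float)
    if positions is None:
        positions = (np.arange(values.size) + 1) * 1000
    return GenomicProfile(
        subject=subject,
        probes=pd.DataFrame({"chrom": chrom, "pos": positions,
                             "log2ratio": values}))


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort: 120 subjects, 3 planted amplified drivers."""
    return generate_cohort(default_cohort_config(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast unit tests: 60 subjects, 2 planted regions."""
    regions = [
        PlantedRegion(chromosome="1", start=400_000, end=1_000_000,
                      polarity="amplification", mean_amplitude=0.8,
                      carrier_fraction=0.3, n_targets=40, target_effect=2.5),
        PlantedRegion(chromosome="2", start=400_000, end=1_000_000,
                      polarity="deletion", mean_amplitude=-0.8,
                      carrier_fraction=0.3, n_targets=30, target_effect=2.5),
    ]
    cfg = SimConfig(n_subjects=60, n_chromosomes=2, probes_per_chromosome=30,
                    n_genes=300, n_mirnas=30, planted_regions=regions,
                    noise_sd_probe=0.1, seed=7)
    return generate_cohort(cfg)
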