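import numpy as np
import pandas as pd
import pytest

from mosaicmap import synthetic_data as sd
from mosaicmap.variant_io import FrequencyTable, GenotypeMatrix


def hw_sample(freqs: FrequencyTable, n_animals: int, seed: int, prefix: str = "s") -> GenotypeMatrix:
    """Hardy-Weinberg genotype sample from a frequency table."""
    rng = np.random.default_rng(seed)
    calls = rng.binomial(2, freqs.af[:, None], size=(freqs.n_sites, n_animals)).astype(np.int8)
    return GenotypeMatrix(
        freqs.sites.copy(), [f"{prefix}_{i}" for i in range(n_animals)], calls
    )


def tiny_matrix(calls, chrom="1", start_pos=100, animals=None) -> GenotypeMatrix:
    """GenotypeMatrix from a nested list (sites x animals)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_animals = calls.shape
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + 10 * np.arange(n_sites),
            "ref": "A",
            "alt": "C",
        }
    )
    if animals is None:
        animals = [f"a{i}" for i in range(n_animals)]
    return GenotypeMatrix(sites, animals, calls)


@pytest.fixture(scope="session")
def founders_f25():
    """Founder frequency tables diverged to F = 0.25 (3,000 sites)."""
    model = sd.FounderModel(n_sites=3000, divergence_fst=0.25, seed=101)
    return sd.draw_founder_frequencies(model)


@pytest.fixture(scope="session")
def mosaic_cohort(founders_f25):
    """A 20-animal 10% taurine mosaic cohort with tract ground truth.

    ~3,000 sites over 10 Mb = 40 windows of 250 kb, ~75 SNPs per window.
    """
    spec = sd.MosaicSpec(
        chrom_length=10_000_000,
        taurine_target_fraction=0.1,
        tract_mean_bp=2_000_000,
        n_animals=20,
        seed=202,
    )
    g, truth = sd.simulate_mosaic_cohort(spec, founders_f25)
    return g, truth, founders_f25
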