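import numpy as np
import pandas as pd
import pytest

from mosaicall.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort reused by read-only tests."""
    cfg = SimulationConfig(
        n_donors_case=5,
        n_donors_control=5,
        n_sites=400,
        mean_depth=1000,
        clone_vaf_range=(0.02, 0.06),
        carrier_prob_case=1.0,
        carrier_prob_control=0.2,
        germline_het_fraction=0.03,
        error_prior_dispersion=1e-3,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_callset(rng, n=40, with_q=True):
    """Random call table spanning the filter thresholds."""
    depth = rng.integers(20, 2000, size=n)
    vaf = rng.uniform(0.0, 0.6, size=n)
    alt = np.minimum(depth, np.round(vaf * depth).astype(int))
    alt_fwd = rng.integers(0, alt + 1)
    df = pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in rng.integers(0, 30, size=n)],
            "chrom": rng.choice(["chr1", "chr2"], size=n),
            "pos": rng.integers(1, 5000, size=n),
            "ref": rng.choice(list("ACGT"), size=n),
            "alt": rng.choice(list("ACGT"), size=n),
            "sample_id": [f"smp{i}" for i in rng.integers(0, 6, size=n)],
            "vaf": vaf,
            "alt_reads": alt,
            "depth": depth,
            "alt_fwd": alt_fwd,
            "alt_rev": alt - alt_fwd,
        }
    )
    if with_q:
        df["q"] = rng.uniform(0, 0.05, size=n)
    return df
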