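import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture()
def small_meta():
    """Two-genotype, one-tissue metadata: a tetraploid and a diploid with
    three replicates each."""
    rows = []
    for geno, ploidy in (("PI377655", "tetraploid_AABB"), ("AS2386", "diploid_DD"),
                         ("C66", "hexaploid_AABBDD")):
        for rep in (1, 2, 3):
            rows.append({
                "sample_id": f"{geno}_shoot_r{rep}", "genotype_id": geno,
                "ploidy": ploidy, "tissue": "shoot", "replicate": rep,
                "library_size": 1_000_000,
            })
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


@pytest.fixture(scope="session")
def tiny_sim():
    """A small full-design simulation shared by shape/partition tests."""
    import shwheb as sw

    cfg = sw.SimConfig(seed=7, n_triads=60, tissues=("shoot", "root"),
                       frac_d_biased=0.2, frac_ab_biased=0.1,
                       d_repression_factor=0.5, repressed_fraction=0.5,
                       library_size=2_000_000)
    return sw.generate(cfg)
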