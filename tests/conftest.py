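import numpy as np
import pandas as pd
import pytest

from igaseq.io import AbundanceTable, MetadataTable, SampleMetadata


@pytest.fixture
def two_sample_tables():
    """A tiny aligned coated/uncoated pair with metadata (2 samples x 2 taxa)."""
    idx = pd.Index(["S1", "S2"], name="sample_id")
    taxa = ["TaxA", "TaxB"]
    coated = AbundanceTable(
        pd.DataFrame([[0.5, 0.5], [0.25, 0.75]], index=idx, columns=taxa), "coated"
    )
    uncoated = AbundanceTable(
        pd.DataFrame([[0.25, 0.75], [0.6, 0.4]], index=idx, columns=taxa), "uncoated"
    )
    metadata = MetadataTable(
        [
            SampleMetadata("S1", "adult", 40.0, 500.0),
            SampleMetadata("S2", "elderly", 25.0, 300.0),
        ]
    )
    return coated, uncoated, metadata


def make_metadata(n_per_group: int, groups=("adult", "elderly"), binding=30.0):
    samples = []
    for g in groups:
        for k in range(n_per_group):
            samples.append(SampleMetadata(f"{g}_{k:02d}", g, binding))
    return MetadataTable(samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20170912)
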