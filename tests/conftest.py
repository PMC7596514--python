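import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import stemcnv.synthetic_data as sd

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_config():
    return sd.SyntheticStudyConfig(seed=1)


@pytest.fixture(scope="session")
def study(default_config):
    """Gene model, network and truth of the seed-1 reference study."""
    gm = sd.generate_gene_model(default_config)
    net = sd.generate_network(default_config, gm)
    truth = sd.make_truth(default_config, gm, net)
    return default_config, gm, net, truth


@pytest.fixture(scope="session")
def bulk_study(study):
    cfg, gm, net, truth = study
    counts, groups = sd.simulate_bulk_counts(cfg, truth, gm)
    return cfg, truth, counts, groups


def tiny_gene_model():
    """Hand-built gene model for interval-overlap tests."""
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [100, 500, 100],
            "end": [200, 600, 300],
            "gene": ["A", "B", "C"],
            "strand": ["+", "-", "+"],
        }
    )
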