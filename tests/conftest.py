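import numpy as np
import pandas as pd
import pytest

from rnasetiling.datatypes import (
    GeneratorConfig,
    NoiseConfig,
    SampleMeta,
    sample_frame,
)
from rnasetiling.simulate import design_probes, make_genome, simulate_expression


@pytest.fixture(scope="session")
def main_samples() -> pd.DataFrame:
    """Metadata for the four main conditions in duplicate."""
    samples = [SampleMeta("wt", "na", r) for r in (1, 2)]
    for cond in ("rnc", "rnjA", "rny"):
        samples += [SampleMeta(cond, "minus", r) for r in (1, 2)]
    return sample_frame(samples)


@pytest.fixture(scope="session")
def clean_layout():
    """A genome whose features and gaps all span many probes.

    Long genes and generous intergenic gaps keep every probe's
    local neighbourhood homogeneous, which makes the positional
    decomposition exactly identifiable.
    """
    config = GeneratorConfig(
        n_genes=20,
        mean_gap=400,
        min_gap=250,
        asRNA_fraction=0.0,
        utr5_fraction=0.0,
        sd_log_gene_length=0.1,
    )
    annotation = make_genome(config, seed=7)
    design = design_probes(annotation)
    return config, annotation, design


@pytest.fixture(scope="session")
def noiseless(clean_layout):
    config, annotation, design = clean_layout
    zero = NoiseConfig(0.0, 0.0, 0.0, 0.0)
    hyb = simulate_expression(
        annotation, design, effects=[], noise=zero, seed=3, config=config
    )
    return annotation, design, hyb


def gauss_frame(rng: np.random.Generator, index, columns, loc=8.0, scale=1.0):
    return pd.DataFrame(
        rng.normal(loc, scale, (len(index), len(columns))), index=index, columns=columns
    )
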