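import numpy as np
import pytest

from panelconcord import SimulationConfig, builtin_panel, run_pipeline
from panelconcord.variant_io import VariantCall


def make_call(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    sample_id="S0001",
    gene="SHG001",
    af=0.25,
    depth=500,
    tier=None,
    assay="TO",
):
    return VariantCall(
        sample_id=sample_id,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        allele_frequency=af,
        read_depth=depth,
        actionability_tier=tier,
        assay_id=assay,
    )


@pytest.fixture(scope="session")
def panel_to():
    return builtin_panel("TO")


@pytest.fixture(scope="session")
def panel_tn():
    return builtin_panel("TN")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_bundle():
    """One full default pipeline run (30 samples), shared across tests."""
    return run_pipeline(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def big_bundle():
    """A 999-sample cohort used for the Monte-Carlo acceptance properties."""
    config = SimulationConfig(seed=11, n_ff=333, n_ffpe_h=333, n_ffpe_l=333)
    return run_pipeline(config)


@pytest.fixture(scope="session")
def truth_origin_index(big_bundle):
    index = {}
    for sample_id, truth in big_bundle["truths"].items():
        for tv in truth.variants:
            index[(sample_id,) + tv.key] = tv.origin
    return index
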