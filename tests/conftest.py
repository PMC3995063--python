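import pytest

from apaseq.simulate import SimConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """60-gene bundle with planted shifts, jitter and internal priming —
    shared read-only across tests."""
    return generate_bundle(SimConfig(n_genes=60, apa_gene_fraction=0.2, seed=7))


@pytest.fixture(scope="session")
def small_result(small_bundle):
    from apaseq.pipeline import run_pipeline_on_bundle
    return run_pipeline_on_bundle(small_bundle)
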