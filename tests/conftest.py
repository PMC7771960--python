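import numpy as np
import pytest

from combisig import (SynthConfig, build_response_table, fit_noise_model,
                      generate_dataset)


@pytest.fixture(scope="session")
def small_bundle():
    """A complete synthetic input bundle small enough for fast tests."""
    cfg = SynthConfig(n_genes=60, n_peaks=150, seed=11,
                      genome_length=5_000_000)
    ds, gene_truth, peak_truth = generate_dataset(cfg)
    return cfg, ds, gene_truth, peak_truth


@pytest.fixture(scope="session")
def gene_model(small_bundle):
    """Fitted noise model and response table for the bundle's genes."""
    _, ds, _, _ = small_bundle
    values = ds.expression.rename(columns={"gene_id": "feature_id",
                                           "tpm": "value"})
    means, cvs = fit_noise_model(values, ds.expression_annotations)
    responses = build_response_table(means, cvs)
    return means, cvs, responses


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
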