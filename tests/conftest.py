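import numpy as np
import pytest

from apobecsig.synthetic import (SiteIndex, make_reference,
                                 synthetic_signature_matrix,
                                 toy_signature_matrix)


@pytest.fixture(scope="session")
def small_reference():
    """200 kb toy genome with 20 x 5 kb genes and a full-gene panel."""
    reference, genes, footprint = make_reference(
        genome_length=200_000, gc_fraction=0.41, n_genes=20,
        gene_length=5_000, panel_fraction=1.0, seed=12345)
    return reference, genes, footprint


@pytest.fixture(scope="session")
def site_index(small_reference):
    reference, _, _ = small_reference
    return SiteIndex(reference)


@pytest.fixture(scope="session")
def signatures():
    return synthetic_signature_matrix()


@pytest.fixture(scope="session")
def toy_signatures():
    return toy_signature_matrix(("SIG_A", "SIG_B", "SIG_C"))
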