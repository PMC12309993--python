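import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import compshift as cs


@pytest.fixture(scope="session")
def fixture_reference():
    """Small clustered reference with planted markers (5 cardiac types)."""
    return cs.dedupe_genes(cs.make_fixture_reference(
        n_genes=500, n_cell_types=5, n_subjects=3, n_nuclei_per_type=150,
        marker_frac=0.05, seed=42))


@pytest.fixture(scope="session")
def marker_panel(fixture_reference):
    return cs.select_markers(fixture_reference, k=10, min_cluster_size=30)


@pytest.fixture(scope="session")
def signature(fixture_reference, marker_panel):
    return cs.build_signature(fixture_reference, marker_panel,
                              list(fixture_reference.gene_ids))


def make_reference(counts, genes, clusters, subjects):
    """Hand-rolled reference from dense arrays (tests only)."""
    meta = pd.DataFrame({"cluster": clusters, "subject": subjects})
    return cs.ClusteredReference(counts=sp.csr_matrix(np.asarray(counts)),
                                 gene_ids=np.asarray(genes, dtype=object),
                                 nucleus_meta=meta)
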