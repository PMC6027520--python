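import numpy as np
import pytest

import coremix as cm


@pytest.fixture(scope="session")
def two_ref_set():
    gene_sets = [
        cm.SpeciesGeneSet("spA", ("ACGTACGTACGT",)),
        cm.SpeciesGeneSet("spB", ("GGGCCCAAATTT", "ACACACACACACACACAC")),
    ]
    return cm.build_reference(gene_sets)


@pytest.fixture(scope="session")
def small_fixture():
    """Four species, ~5 kb references, 30% shared genes, 1,500 reads."""
    return cm.make_fixture(
        n_species=4,
        genes_per_species=10,
        gene_length=500,
        shared_fraction=0.3,
        n_reads=1500,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_profile(small_fixture):
    """(read_table, phi, refset, truth) for the small community."""
    fx = small_fixture
    hits = cm.filter_high_quality(
        cm.simulate_alignment(fx.reads, fx.refset, 0.1), 0.1
    )
    table = cm.build_read_table(fx.reads)
    phi = cm.estimate_phi(table, hits, fx.refset)
    return table, phi, fx.refset, fx.truth


def random_sparse_instance(rng, M, N):
    """Random tiny inference instance: read table + sparse phi matrix.

    Every distinct read keeps at least one candidate reference.
    """
    K = int(rng.integers(1, N + 1))
    phi = rng.random((K, M))
    mask = rng.random((K, M)) < 0.4
    keep = np.zeros_like(mask)
    keep[np.arange(K), rng.integers(0, M, K)] = True
    phi = np.where(mask | keep, phi, 0.0)
    col = phi.sum(axis=0)
    phi = phi / np.where(col > 0, col, 1.0)
    seqs = [f"seq{int(k)}" for k in rng.integers(0, K, N)]
    seqs[: K] = [f"seq{k}" for k in range(K)]  # make all K rows appear
    table = cm.ReadTable.from_sequences(seqs)
    return table, cm.PhiMatrix.from_dense(phi[: table.K])
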