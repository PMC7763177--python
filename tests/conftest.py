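import numpy as np
import pytest
import scipy.sparse as sp

import soupclean as scn


def make_matrix(dense, gene_prefix="G", barcode_prefix="d"):
    """DropletMatrix from a dense array with generated names."""
    dense = np.asarray(dense)
    n_genes, n_drops = dense.shape
    return scn.DropletMatrix(
        sp.csc_matrix(dense),
        gene_ids=[f"{gene_prefix}{i}" for i in range(n_genes)],
        gene_symbols=[f"{gene_prefix}{i}" for i in range(n_genes)],
        barcodes=[f"{barcode_prefix}{j}" for j in range(n_drops)],
    )


def soup_from_fractions(fractions, total=10_000):
    """A SoupProfile with exactly the given fractions."""
    fractions = np.asarray(fractions, dtype=float)
    return scn.SoupProfile(
        fractions=fractions,
        counts=fractions * total,
        umi_threshold=10,
        total_soup_umis=total,
        n_droplets_used=100,
    )


@pytest.fixture(scope="session")
def channel():
    """A standard 4-type channel at 10% contamination with known truth."""
    specs = [
        scn.CellTypeSpec(f"type{k}", 125, 1000.0, profile_seed=100 + k)
        for k in range(4)
    ]
    return scn.simulate_channel(2000, specs, rho=0.1, seed=1)


@pytest.fixture(scope="session")
def channel_soup(channel):
    raw, _, _, _ = channel
    return scn.estimate_soup(raw)


@pytest.fixture(scope="session")
def species():
    """Barnyard-style two-block channel at 2% contamination."""
    return scn.species_mix_fixture(rho=0.02, seed=3)
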