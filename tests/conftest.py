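import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crossova.synthetic import SpeciesConfig, generate_dataset

FOUR_TYPES = {"endothelial": 0.25, "granulosa": 0.25, "immune": 0.25, "theca": 0.25}


def make_adata(counts, cell_ids=None, gene_ids=None, **obs_cols) -> ad.AnnData:
    """AnnData from a dense cells x genes count array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    cell_ids = cell_ids or [f"c{i + 1}" for i in range(n)]
    gene_ids = gene_ids or [f"g{j + 1}" for j in range(g)]
    obs = pd.DataFrame(obs_cols, index=pd.Index(cell_ids, name="barcode"))
    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    return ad.AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs, var=var)


@pytest.fixture(scope="session")
def two_species_dataset():
    """Two species, four shared cell types, planted markers/regulons/pathways."""
    cfgs = [SpeciesConfig(s, 400, dict(FOUR_TYPES)) for s in ("spA", "spB")]
    return generate_dataset(cfgs, n_genes=400, n_regulons=4, n_pathways=6, seed=11)


@pytest.fixture(scope="session")
def normalized_pair(two_species_dataset):
    from crossova.qc import filter_cells_genes, normalize_log

    out = {}
    for s, adata in two_species_dataset.adatas.items():
        out[s] = normalize_log(filter_cells_genes(adata, min_genes=50))
    return out


@pytest.fixture(scope="session")
def harmonized(two_species_dataset, normalized_pair):
    from crossova.orthologs import filter_one2one, harmonize_datasets

    table = filter_one2one(two_species_dataset.ortholog_table, list(normalized_pair))
    return harmonize_datasets(normalized_pair, table)
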