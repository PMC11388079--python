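import numpy as np
import pandas as pd
import pytest

import oncofetal as of


@pytest.fixture(scope="session")
def sc_cohort():
    """Default synthetic single-cell cohort (seed 1) shared across tests."""
    ds, truth = of.generate_single_cell(seed=1)
    norm = of.normalize_log_cp10k(ds)
    return ds, truth, norm


@pytest.fixture()
def tiny_dataset():
    """Hand-built 4-cell × 5-gene dataset with positions on two chromosomes."""
    counts = np.array([
        [5, 0, 2, 1, 0],
        [0, 3, 0, 4, 1],
        [2, 2, 2, 2, 2],
        [0, 0, 0, 0, 0],
    ])
    cell_ids = ["c1", "c2", "c3", "c4"]
    gene_ids = ["g1", "g2", "g3", "g4", "g5"]
    meta = pd.DataFrame({
        "sample_id": ["s1", "s1", "s2", "s2"],
        "phenotype": ["normal", "normal", "tumor_HCC", "tumor_HCC"],
        "cell_type": ["epithelial", "endothelial", "epithelial", "epithelial"],
    }, index=pd.Index(cell_ids, name="cell_id"))
    gene_pos = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2", "chr2", "chr10"],
        "start": [100, 500, 100, 900, 1],
        "end": [199, 599, 199, 999, 100],
    }, index=pd.Index(gene_ids, name="gene_id"))
    return of.CellDataset(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids,
                          cell_meta=meta, gene_pos=gene_pos)
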