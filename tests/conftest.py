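import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from screpurpose import simulate_study

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def make_adata(counts, genes=None, condition=None, donor=None):
    """AnnData (cells x genes) from a dense array, with obs labels."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = list(genes) if genes is not None else [
        f"G{i + 1:03d}" for i in range(n_genes)
    ]
    condition = condition or ["case"] * n_cells
    donor = donor or ["d1"] * n_cells
    return ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(
            {"donor": donor, "condition": condition},
            index=pd.Index([f"C{i + 1:03d}" for i in range(n_cells)], name="barcode"),
        ),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def annotation_frame(adata, labels):
    return pd.DataFrame(
        {"label": list(labels), "margin": 1.0}, index=adata.obs_names.copy()
    )


@pytest.fixture(scope="session")
def small_study():
    """Reduced synthetic study for fast tests: 5 cell types, 20 pathways,
    80 cells per (type, condition)."""
    return simulate_study(
        7,
        n_pathways=20,
        genes_per_pathway=20,
        n_decoys=50,
        sig_size=30,
        n_genes=600,
        cells_per_type_per_donor=20,
        n_donors_case=2,
        n_donors_control=2,
        nb_mean=0.8,
    )
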