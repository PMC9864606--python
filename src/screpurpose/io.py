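"""Reading and writing the on-disk formats used by the pipeline.

Count matrices travel as a 10x-style MTX triplet (``matrix.mtx`` with genes
as rows and cells as columns, ``features.tsv``, ``barcodes.tsv``) plus a
cell-metadata TSV (``cell_meta.tsv`` with columns barcode, donor,
condition).  Gene identifiers are case-normalized to upper case on ingest
so that matrices, pathway sets, marker sets and drug banks all match on the
same key space.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConfigurationError

CONDITIONS = ("case", "control")


def normalize_gene_ids(genes) -> list[str]:
    """Upper-case gene symbols; raise if IDs collide after normalization."""
    upper = [str(g).strip().upper() for g in genes]
    if len(set(upper)) != len(upper):
        dupes = sorted({g for g in upper if upper.count(g) > 1})
        raise ConfigurationError(
            f"gene IDs not unique after case normalization: {dupes[:5]}"
        )
    return upper


def read_matrix_dir(path: str) -> ad.AnnData:
    """Load a count matrix directory into an AnnData (cells x genes).

    Expects ``matrix.mtx`` (genes x cells), ``features.tsv``,
    ``barcodes.tsv`` and ``cell_meta.tsv``.  Donor and condition labels are
    attached as ``obs['donor']`` / ``obs['condition']``.
    """
    mtx = scipy.io.mmread(os.path.join(path, "matrix.mtx"))
    genes = pd.read_csv(
        os.path.join(path, "features.tsv"), sep="\t", header=None
    )[0].tolist()
    barcodes = pd.read_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=None
    )[0].tolist()
    meta = pd.read_csv(os.path.join(path, "cell_meta.tsv"), sep="\t")
    meta = meta.set_index("barcode").loc[barcodes]

    bad = set(meta["condition"]) - set(CONDITIONS)
    if bad:
        raise ConfigurationError(f"unknown condition labels: {sorted(bad)}")

    x = sp.csr_matrix(mtx.T)  # cells x genes
    adata = ad.AnnData(
        X=x,
        obs=pd.DataFrame(
            {"donor": meta["donor"].values, "condition": meta["condition"].values},
            index=pd.Index(barcodes, name="barcode"),
        ),
        var=pd.DataFrame(index=pd.Index(normalize_gene_ids(genes), name="gene")),
    )
    if len(set(barcodes)) != len(barcodes):
        raise ConfigurationError("cell barcodes are not unique")
    return adata


def write_matrix_dir(adata: ad.AnnData, path: str) -> None:
    """Write an AnnData back out as the MTX triplet + metadata TSV."""
    os.makedirs(path, exist_ok=True)
    x = sp.coo_matrix(adata.X.T)  # genes x cells
    field = "integer" if np.issubdtype(x.dtype, np.integer) else "real"
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), x, field=field)
    pd.Series(adata.var_names).to_csv(
        os.path.join(path, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    meta = pd.DataFrame(
        {
            "barcode": adata.obs_names,
            "donor": adata.obs["donor"].values,
            "condition": adata.obs["condition"].values,
        }
    )
    meta.to_csv(os.path.join(path, "cell_meta.tsv"), sep="\t", index=False)


def read_marker_sets(path: str) -> dict[str, list[str]]:
    """Read marker sets from a two-column TSV (cell_type, gene) or a GMT.

    The format is chosen by extension: ``.gmt`` uses one line per cell type
    (name, description, genes...), anything else is parsed as the TSV.
    """
    markers: dict[str, list[str]] = {}
    if path.endswith(".gmt"):
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                markers[fields[0]] = [g.upper() for g in fields[2:] if g]
        return markers
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if str(df.iloc[0, 0]).lower() == "cell_type":  # optional header row
        df = df.iloc[1:]
    for ct, grp in df.groupby(0, sort=True):
        markers[str(ct)] = [str(g).upper() for g in grp[1]]
    return markers


def write_marker_sets(markers: dict[str, list[str]], path: str) -> None:
    rows = [(ct, g) for ct in sorted(markers) for g in markers[ct]]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path: str) -> None:
    """Deterministic TSV writer used for every report table."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
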