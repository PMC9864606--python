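"""Cell/gene quality control, normalization and pseudobulk aggregation.

The filters mirror the standard Seurat-style thresholds: cells must detect
between ``min_features`` and ``max_features`` genes and carry strictly less
than 10% mitochondrial and hemoglobin counts; genes must be detected in at
least ``min_cells`` cells.  Normalization is library-size scaling to a
fixed total followed by log1p — a documented stand-in for regularized
negative-binomial regression (SCTransform), adequate here because the
downstream pathway scores consume only case/control ratios of per-gene
aggregates.

Pseudobulk profiles are geometric means over all cells of one (cell type,
condition) group, computed on ``1 + value`` so that genes unexpressed in
the whole group aggregate to exactly 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, EmptyGroupError

MITO_PREFIX = "MT-"
HB_REGEX = re.compile(r"^HB[ABDEGMQZ]")


@dataclass(frozen=True)
class ExpressionProfile:
    """Geometric-mean pseudobulk profile of one (cell type, condition) group.

    ``gm[g] = exp(mean_c log(1 + value(g, c)))`` over the contributing
    cells, so ``gm[g] >= 1`` always and ``gm[g] == 1`` iff gene g is zero
    in every contributing cell.
    """

    cell_type: str
    condition: str
    gm: pd.Series  # gene -> geometric mean, >= 1
    n_cells: int


def mito_mask(genes) -> np.ndarray:
    """Boolean mask of mitochondrial genes (case-insensitive ``MT-`` prefix)."""
    return np.array([g.upper().startswith(MITO_PREFIX) for g in genes])


def hb_mask(genes) -> np.ndarray:
    """Boolean mask of hemoglobin genes (symbol matching ``^HB[ABDEGMQZ]``)."""
    return np.array([bool(HB_REGEX.match(g.upper())) for g in genes])


def _as_csr(adata: ad.AnnData) -> sp.csr_matrix:
    x = adata.X
    return x.tocsr() if sp.issparse(x) else sp.csr_matrix(x)


def filter_cells(
    adata: ad.AnnData,
    min_features: int = 200,
    max_features: int = 2500,
    max_mito_pct: float = 10.0,
    max_hb_pct: float = 10.0,
) -> ad.AnnData:
    """Keep cells with detected-gene count in [min_features, max_features]
    and mitochondrial / hemoglobin count percentages strictly below the
    thresholds.  The gene axis is unchanged.
    """
    if min_features > max_features:
        raise ConfigurationError(
            f"min_features ({min_features}) > max_features ({max_features})"
        )
    x = _as_csr(adata)
    detected = np.asarray((x > 0).sum(axis=1)).ravel()
    totals = np.asarray(x.sum(axis=1)).ravel().astype(float)
    safe = np.where(totals > 0, totals, 1.0)
    mito = np.asarray(x[:, mito_mask(adata.var_names)].sum(axis=1)).ravel()
    hb = np.asarray(x[:, hb_mask(adata.var_names)].sum(axis=1)).ravel()
    keep = (
        (detected >= min_features)
        & (detected <= max_features)
        & (100.0 * mito / safe < max_mito_pct)
        & (100.0 * hb / safe < max_hb_pct)
    )
    return adata[keep].copy()


def filter_genes(adata: ad.AnnData, min_cells: int = 3) -> ad.AnnData:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ConfigurationError("min_cells must be non-negative")
    x = _as_csr(adata)
    n_detected = np.asarray((x > 0).sum(axis=0)).ravel()
    return adata[:, n_detected >= min_cells].copy()


def normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Library-size normalization: value = log(1 + scale * count / total).

    Every cell must have a positive total count (filter first).  Raw counts
    are preserved in ``layers['counts']``.
    """
    x = _as_csr(adata).astype(np.float64)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise ConfigurationError(
            "cells with zero total count present; run filter_cells first"
        )
    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    scaled = sp.diags(scale / totals) @ x
    scaled.data = np.log1p(scaled.data)
    out.X = scaled.tocsr()
    return out


def pseudobulk_geomean(
    adata_norm: ad.AnnData,
    annotation: pd.DataFrame,
    cell_type: str,
    condition: str,
) -> ExpressionProfile:
    """Geometric-mean pseudobulk profile of one (cell type, condition) group.

    ``annotation`` is indexed by cell ID with a ``label`` column (as
    produced by :func:`screpurpose.celltyping.score_cell_types`).
    """
    labels = annotation.loc[adata_norm.obs_names, "label"].values
    mask = (labels == cell_type) & (adata_norm.obs["condition"].values == condition)
    if not mask.any():
        raise EmptyGroupError(f"no cells for ({cell_type}, {condition})")
    x = _as_csr(adata_norm)[np.flatnonzero(mask)]
    logs = x.copy()
    logs.data = np.log1p(logs.data)  # log(1 + value); zeros stay zero
    mean_log = np.asarray(logs.mean(axis=0)).ravel()
    gm = pd.Series(np.exp(mean_log), index=adata_norm.var_names, name="gm")
    return ExpressionProfile(cell_type, condition, gm, int(mask.sum()))


def profiles_by_group(
    adata_norm: ad.AnnData, annotation: pd.DataFrame
) -> dict[tuple[str, str], ExpressionProfile]:
    """All (cell type, condition) pseudobulk profiles with >= 1 cell.

    Cells labelled ``unassigned`` are excluded.
    """
    labels = annotation.loc[adata_norm.obs_names, "label"]
    out: dict[tuple[str, str], ExpressionProfile] = {}
    for ct in sorted(set(labels) - {"unassigned"}):
        for cond in ("case", "control"):
            mask = (labels.values == ct) & (
                adata_norm.obs["condition"].values == cond
            )
            if mask.any():
                out[(ct, cond)] = pseudobulk_geomean(adata_norm, annotation, ct, cond)
    return out


def write_profiles(
    profiles: dict[tuple[str, str], ExpressionProfile], path: str
) -> None:
    """Write per-cell-type case/control profiles as a TSV."""
    from .io import write_tsv

    cell_types = sorted({ct for ct, _ in profiles})
    rows = []
    for ct in cell_types:
        case = profiles.get((ct, "case"))
        ctrl = profiles.get((ct, "control"))
        if case is None or ctrl is None:
            continue
        for g in case.gm.index:
            rows.append(
                (ct, g, case.gm[g], ctrl.gm[g], case.n_cells, ctrl.n_cells)
            )
    write_tsv(
        pd.DataFrame(
            rows,
            columns=[
                "cell_type",
                "gene",
                "gm_case",
                "gm_control",
                "n_cells_case",
                "n_cells_control",
            ],
        ),
        path,
    )
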